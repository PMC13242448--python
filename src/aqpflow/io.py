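"""File formats: trace CSV + JSON sidecar, qPCR tables, results tables.

The dialect is tolerant-reader / strict-writer: unknown sidecar keys and
extra input columns are preserved, while outputs always follow the
documented schema. Traces are stored as a two-column CSV (time_s,
signal) with a JSON sidecar holding the experimental conditions.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .expression import AmplificationCurve
from .traces import ShockTrace, TraceMeta

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_qpcr_csv",
    "read_qpcr_csv",
    "write_table",
]

_META_FIELDS = ("strain", "treatment", "temperature_c", "osm_out_inf",
                "shock_type", "osm_in0", "gly_out", "alpha", "seed")
_REQUIRED_SIDECAR = ("osm_out_inf", "shock_type")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace_csv(trace: ShockTrace, path) -> Path:
    """Write time_s,signal CSV plus a JSON sidecar with all conditions."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s, "signal": trace.signal})
    df.to_csv(path, index=False, float_format="%.10g")
    meta = asdict(trace.meta)
    extra = dict(meta.pop("extra", {}) or {})
    meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_trace_csv(path) -> ShockTrace:
    """Read a trace written by :func:`write_trace_csv` (or hand-prepared in
    the same dialect). Validates monotone time and finite signal, and
    reports the offending row on failure; unknown sidecar keys are kept
    in ``meta.extra``."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"trace file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ParseError(f"missing JSON sidecar: {sidecar}")
    try:
        raw = json.loads(sidecar.read_text())
    except json.JSONDecodeError as err:
        raise ParseError(f"malformed sidecar {sidecar}: {err}") from err
    for key in _REQUIRED_SIDECAR:
        if key not in raw:
            raise ParseError(f"sidecar {sidecar} missing required field {key!r}")
    known = {k: raw[k] for k in _META_FIELDS if k in raw}
    extra = {k: v for k, v in raw.items() if k not in _META_FIELDS}
    meta = TraceMeta(**known, extra=extra)

    df = pd.read_csv(path)
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    s = df["signal"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ParseError(f"{path}: time_s not strictly increasing at row {int(bad[0]) + 2}")
    nan = np.nonzero(~np.isfinite(s))[0]
    if nan.size:
        raise ParseError(f"{path}: non-finite signal at row {int(nan[0]) + 2}")
    return ShockTrace(time_s=t, signal=s, meta=meta)


def write_qpcr_csv(curves, curves_path, samples_path) -> None:
    """Write per-cycle fluorescence and the sample sheet as two CSVs."""
    curve_rows = []
    sheet_rows = []
    for cv in curves:
        for c, f in zip(cv.cycles, cv.fluorescence):
            curve_rows.append({"well": cv.well, "cycle": int(c), "fluorescence": f})
        sheet_rows.append({"well": cv.well, "gene": cv.gene, "role": cv.role,
                           "condition": cv.condition, "bio_rep": cv.bio_rep,
                           "tech_rep": cv.tech_rep})
    pd.DataFrame(curve_rows).to_csv(curves_path, index=False, float_format="%.10g")
    pd.DataFrame(sheet_rows).to_csv(samples_path, index=False)


def read_qpcr_csv(curves_path, samples_path) -> "list[AmplificationCurve]":
    """Read curves + sample sheet back into :class:`AmplificationCurve`s."""
    curves_path, samples_path = Path(curves_path), Path(samples_path)
    for p in (curves_path, samples_path):
        if not p.exists():
            raise ParseError(f"qPCR file not found: {p}")
    fl = pd.read_csv(curves_path)
    sheet = pd.read_csv(samples_path)
    for col in ("well", "cycle", "fluorescence"):
        if col not in fl.columns:
            raise ParseError(f"{curves_path}: missing column {col!r}")
    for col in ("well", "gene", "role", "condition", "bio_rep", "tech_rep"):
        if col not in sheet.columns:
            raise ParseError(f"{samples_path}: missing column {col!r}")
    curves = []
    sheet = sheet.set_index("well")
    for well, grp in fl.groupby("well", sort=False):
        if well not in sheet.index:
            raise ParseError(f"{samples_path}: no sample-sheet row for well {well!r}")
        row = sheet.loc[well]
        grp = grp.sort_values("cycle")
        curves.append(AmplificationCurve(
            well=str(well), gene=str(row["gene"]), role=str(row["role"]),
            condition=str(row["condition"]), bio_rep=int(row["bio_rep"]),
            tech_rep=int(row["tech_rep"]),
            cycles=grp["cycle"].to_numpy(), fluorescence=grp["fluorescence"].to_numpy(),
        ))
    return curves


def write_table(df: pd.DataFrame, path, *, config_hash: str = "", seed: int | None = None) -> Path:
    """Write a results table with a provenance comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash or seed is not None:
            fh.write(f"# aqpflow config_sha256={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path
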