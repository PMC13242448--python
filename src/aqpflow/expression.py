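"""qPCR quantification-cycle calling, Delta-Delta-Cq expression, and WUE.

The drought-response stage mirrors standard real-time PCR practice: the
per-cycle fluorescence is baseline-corrected by subtracting the mean over
a pre-amplification window (cycles 5-17 inclusive by default), and the
quantification cycle Cq is the fractional cycle at which the corrected
signal (Delta-Rn) first crosses a fixed threshold (68 by default, an
instrument-scale-specific value that stays configurable). Interpolation
between the bracketing cycles is linear in log10(Delta-Rn), because
amplification is exponential in that region.

Relative expression uses the Delta-Delta-Cq method at 100% efficiency:
technical replicates are averaged first, Delta-Cq = Cq_target - Cq_ref
per biological replicate, Delta-Delta-Cq = mean(treated) - mean(control),
and log2 fold change = -Delta-Delta-Cq (fold change 2^-DDCq).

Intrinsic water-use efficiency is the gas-exchange ratio A/gs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InputError, PairingError

__all__ = [
    "AmplificationCurve",
    "CqValue",
    "ExpressionResult",
    "GasExchangeRecord",
    "call_cq",
    "cq_table",
    "delta_delta_cq",
    "intrinsic_wue",
]

DEFAULT_BASELINE_CYCLES = (5, 17)
DEFAULT_THRESHOLD = 68.0

#: Floor applied to non-positive Delta-Rn values, only inside the
#: interpolation logarithms, never for storage.
LOG_FLOOR = 1e-6


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's per-cycle fluorescence with its sample annotations."""

    well: str
    gene: str
    role: str  # "target" | "reference"
    condition: str
    bio_rep: int
    tech_rep: int
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cycles, dtype=int)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "cycles", c)
        object.__setattr__(self, "fluorescence", f)
        if c.size < 25:
            raise InputError(f"curve {self.well}: need >= 25 cycles, got {c.size}")
        if c[0] != 1 or not np.all(np.diff(c) == 1):
            raise InputError(f"curve {self.well}: cycles must be contiguous from 1")
        if f.shape != c.shape or not np.all(np.isfinite(f)):
            raise InputError(f"curve {self.well}: fluorescence must be finite and match cycles")
        if self.role not in ("target", "reference"):
            raise InputError(f"curve {self.well}: role must be target|reference")


@dataclass(frozen=True)
class CqValue:
    """Fractional quantification cycle; ``cq`` is None when the threshold
    is never crossed (undetermined, e.g. a non-amplifying gene)."""

    cq: float | None
    threshold_used: float
    baseline_window: tuple[int, int]

    @property
    def determined(self) -> bool:
        return self.cq is not None


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    comparison: tuple[str, str]  # (treated, control)
    delta_delta_cq: float
    log2_fold_change: float
    fold_change: float
    se: float
    p_value: float | None
    n_control: int
    n_treated: int
    n_excluded: int = 0
    test: str = "welch"


@dataclass(frozen=True)
class GasExchangeRecord:
    """One plant's gas-exchange measurements.

    A in umol CO2 m^-2 s^-1, gs and E in mmol H2O m^-2 s^-1.
    """

    a: float
    gs: float
    e: float
    plant_id: str = ""
    treatment: str = ""
    timepoint: str = ""

    @property
    def wue(self) -> float:
        return intrinsic_wue(self.a, self.gs)


def call_cq(
    curve: AmplificationCurve,
    baseline_cycles: tuple[int, int] = DEFAULT_BASELINE_CYCLES,
    threshold: float = DEFAULT_THRESHOLD,
) -> CqValue:
    """Fractional cycle at which Delta-Rn first crosses the threshold.

    Delta-Rn is the fluorescence minus its mean over the baseline window
    (endpoints inclusive). The crossing is interpolated log10-linearly
    between the bracketing cycles; adding any constant to the whole curve
    leaves the result unchanged. Returns an undetermined
    :class:`CqValue` (cq = None) when the threshold is never reached.
    """
    b0, b1 = baseline_cycles
    c = curve.cycles
    if not (c[0] <= b0 < b1 <= c[-1]):
        raise InputError(f"baseline window {baseline_cycles} outside cycles")
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    mask = (c >= b0) & (c <= b1)
    drn = curve.fluorescence - float(curve.fluorescence[mask].mean())
    above = np.nonzero(drn >= threshold)[0]
    if above.size == 0 or above[0] == 0:
        return CqValue(cq=None, threshold_used=threshold, baseline_window=(b0, b1))
    i = int(above[0])
    prev = max(float(drn[i - 1]), LOG_FLOOR)
    cur = max(float(drn[i]), LOG_FLOOR)
    frac = (math.log10(threshold) - math.log10(prev)) / (math.log10(cur) - math.log10(prev))
    cq = float(c[i - 1]) + frac * float(c[i] - c[i - 1])
    return CqValue(cq=cq, threshold_used=threshold, baseline_window=(b0, b1))


def cq_table(curves, **call_kwargs) -> pd.DataFrame:
    """Call Cq on every curve and tabulate; undetermined wells get NaN."""
    rows = []
    for cv in curves:
        q = call_cq(cv, **call_kwargs)
        rows.append({
            "well": cv.well, "gene": cv.gene, "role": cv.role,
            "condition": cv.condition, "bio_rep": cv.bio_rep,
            "tech_rep": cv.tech_rep,
            "cq": q.cq if q.determined else np.nan,
        })
    return pd.DataFrame(rows)


def delta_delta_cq(
    cq_records: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "GAPDH",
    control: str = "control",
    treated: str = "treated",
    *,
    welch: bool = True,
) -> ExpressionResult:
    """Relative expression of ``target_gene`` against ``reference_gene``.

    ``cq_records`` needs columns gene, condition, bio_rep, tech_rep, cq.
    Technical replicates are averaged first; each biological replicate
    contributes one Delta-Cq, and the two conditions are compared by a
    two-sample t-test (Welch by default; ``welch=False`` for the
    pooled-variance variant). Wells with an undetermined Cq (NaN) are
    excluded and counted. A biological replicate lacking its
    reference-gene wells raises :class:`PairingError`.
    """
    df = cq_records.copy()
    n_excluded = int(df["cq"].isna().sum())
    df = df.dropna(subset=["cq"])

    def _dcq_group(cond: str) -> np.ndarray:
        sub = df[df["condition"] == cond]
        tech_mean = (
            sub.groupby(["bio_rep", "gene"], sort=True)["cq"].mean().unstack()
        )
        for gene_name, label in ((target_gene, "target"), (reference_gene, "reference")):
            if gene_name not in tech_mean.columns or tech_mean[gene_name].isna().any():
                missing = (
                    tech_mean.index.tolist() if gene_name not in tech_mean.columns
                    else tech_mean.index[tech_mean[gene_name].isna()].tolist()
                )
                raise PairingError(
                    f"{label} gene {gene_name!r} missing for condition {cond!r}, "
                    f"biological replicate(s) {missing}"
                )
        return (tech_mean[target_gene] - tech_mean[reference_gene]).to_numpy()

    dcq_control = _dcq_group(control)
    dcq_treated = _dcq_group(treated)
    ddcq = float(dcq_treated.mean() - dcq_control.mean())
    nc, nt = dcq_control.size, dcq_treated.size
    if nc > 1 and nt > 1:
        se = math.sqrt(np.var(dcq_treated, ddof=1) / nt + np.var(dcq_control, ddof=1) / nc)
    else:
        se = 0.0
    p = None
    if nc >= 2 and nt >= 2 and (np.var(dcq_control, ddof=1) > 0 or np.var(dcq_treated, ddof=1) > 0):
        res = stats.ttest_ind(dcq_treated, dcq_control, equal_var=not welch)
        p = float(res.pvalue)
    return ExpressionResult(
        gene=target_gene, comparison=(treated, control),
        delta_delta_cq=ddcq, log2_fold_change=-ddcq,
        fold_change=2.0 ** (-ddcq), se=float(se), p_value=p,
        n_control=nc, n_treated=nt, n_excluded=n_excluded,
        test="welch" if welch else "student",
    )


def intrinsic_wue(a: float, gs: float) -> float:
    """Intrinsic water-use efficiency A/gs, in the input unit ratio."""
    if not gs > 0:
        raise DomainError(f"gs must be > 0, got {gs}")
    return a / gs
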