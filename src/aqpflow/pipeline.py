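"""Configuration-driven orchestration of the full analysis.

One YAML experiment configuration drives every stage in dependency
order: trace simulation (or reading trace files), kinetic fitting,
permeability aggregation, Arrhenius activation energies, treatment
effects, weak-acid intracellular pH, and qPCR relative expression. Every
output table carries the configuration hash and master seed, and a rerun
with an identical configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AqpflowError, ConfigurationError, PipelineError, WindowError
from .expression import cq_table, delta_delta_cq
from .io import read_trace_csv, write_table
from .permeability import (
    CellGeometry,
    aggregate_replicates,
    compute_pf,
    compute_pgly,
    estimate_ea,
)
from .regulation import compute_phin, significance_stars, treatment_effect
from .simulate import (
    SimulationConfig,
    generate_arrhenius_series,
    generate_qpcr_curves,
    generate_weak_acid_assay,
    simulate_glycerol_trace,
    simulate_shrinkage_trace,
)
from .traces import fit_reswell_slope, fit_single_exponential, locate_reswell_window, normalize_trace
from .constants import OSM_TO_MOL_PER_CM3, VW_CM3_PER_MOL

__all__ = ["ExperimentConfig", "ResultsBundle", "run_experiment", "write_report"]

#: Samples per simulated water (shrinkage) trace.
WATER_SAMPLES = 1200
#: Relaxation times of the linearized shrinkage covered by a water trace.
WATER_SPAN_TAUS = 10.0
#: Samples per simulated glycerol trace.
GLY_SAMPLES = 2000
#: Fraction of glycerol equilibration covered by a glycerol trace.
GLY_SPAN_FRACTION = 0.6


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment description (see the bundled demo YAML)."""

    raw: dict
    seed: int
    geometry: CellGeometry
    min_r2: float
    replicates: int
    shock_water: dict
    shock_glycerol: dict
    strains: list
    effects: list
    arrhenius: list
    weak_acid: list
    qpcr: list
    gas_exchange: list
    traces_dir: Path | None

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        seed = int(raw.get("seed", 0))
        geometry = CellGeometry(**raw.get("geometry", {}))
        qc = raw.get("qc", {})
        traces_dir = raw.get("traces_dir")
        if traces_dir is not None:
            traces_dir = Path(traces_dir)
            if not traces_dir.exists():
                raise ConfigurationError(f"traces_dir does not exist: {traces_dir}")
        return cls(
            raw=raw,
            seed=seed,
            geometry=geometry,
            min_r2=float(qc.get("min_r2", 0.9)),
            replicates=int(raw.get("replicates", 10)),
            shock_water=dict(raw.get("shock", {}).get("water", {})),
            shock_glycerol=dict(raw.get("shock", {}).get("glycerol", {})),
            strains=list(raw.get("strains", [])),
            effects=list(raw.get("effects", [])),
            arrhenius=list(raw.get("arrhenius", [])),
            weak_acid=list(raw.get("weak_acid", [])),
            qpcr=list(raw.get("qpcr", [])),
            gas_exchange=list(raw.get("gas_exchange", [])),
            traces_dir=traces_dir,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file does not exist: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ResultsBundle:
    permeability: pd.DataFrame
    arrhenius: pd.DataFrame
    effects: pd.DataFrame
    phin: pd.DataFrame
    expression: pd.DataFrame
    gas_exchange: pd.DataFrame | None
    replicate_values: dict
    log: list = field(default_factory=list)
    config_hash: str = ""
    seed: int = 0


def _seed_stream(seed: int):
    """Deterministic stream of independent child seeds below 2**31."""
    counter = 0
    while True:
        state = np.random.SeedSequence([seed, counter]).generate_state(1)[0]
        yield int(state) & 0x7FFFFFFF
        counter += 1


def _water_duration(pf: float, shock: dict, geometry: CellGeometry) -> tuple[float, float]:
    """Trace span covering WATER_SPAN_TAUS linearized relaxation times."""
    klin = pf * VW_CM3_PER_MOL * shock["osm_out_inf"] * OSM_TO_MOL_PER_CM3 / geometry.v0_over_a
    duration = WATER_SPAN_TAUS / klin
    return duration, duration / WATER_SAMPLES


def _gly_duration(pf: float, pgly: float, shock: dict, geometry: CellGeometry) -> tuple[float, float]:
    """Span covering the shrinkage phase plus GLY_SPAN_FRACTION of glycerol
    equilibration. The sampling interval is capped so the fast water phase
    decays by < 0.2% over one sample: the normalization anchor (mean of
    the first samples) must sit at relative volume ~1 for the re-swell
    gradient correction to read volumes on the right scale."""
    beta = shock["osm_in0"] / shock["osm_out_inf"]
    kw = pf * VW_CM3_PER_MOL * shock["osm_out_inf"] * OSM_TO_MOL_PER_CM3 / geometry.v0_over_a
    kg = (pgly / geometry.v0_over_a) / beta
    duration = 8.0 / kw + GLY_SPAN_FRACTION / kg
    dt = min(duration / GLY_SAMPLES, 0.002 / (kw * (1.0 - beta)))
    return duration, dt


def fit_water_trace(trace, geometry: CellGeometry):
    """normalize -> single-exponential fit -> Pf. Returns (pf, fit)."""
    norm = normalize_trace(trace)
    fit = fit_single_exponential(norm)
    return compute_pf(fit.k, geometry, trace.meta.osm_out_inf), fit


def fit_glycerol_trace(trace, geometry: CellGeometry):
    """normalize -> re-swell window -> corrected slope -> Pgly.

    Returns (pgly, slope_fit)."""
    norm = normalize_trace(trace)
    window = locate_reswell_window(norm)
    fit = fit_reswell_slope(norm, window, gradient_correction=True)
    return compute_pgly(fit.m, geometry), fit


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AqpflowError as err:
                raise PipelineError(f"stage '{name}': {err}") from err
        return wrapper
    return deco


@_stage("permeability")
def _run_permeability(config: ExperimentConfig, seeds, log):
    rows = []
    replicate_values: dict = {}
    jobs = []
    for strain in config.strains:
        name = strain["name"]
        for treatment, pf in strain.get("water", {}).items():
            jobs.append((name, treatment, "water", float(pf), None))
        for treatment, pgly in strain.get("glycerol", {}).items():
            water_map = strain.get("water", {})
            pf = float(water_map.get(treatment, water_map.get("none", 4.6e-4)))
            jobs.append((name, treatment, "glycerol", pf, float(pgly)))

    for name, treatment, kind, pf, pgly in jobs:
        values, r2s = [], []
        for _rep in range(config.replicates):
            child = next(seeds)
            if kind == "water":
                shock = config.shock_water
                duration, dt = _water_duration(pf, shock, config.geometry)
                sim = SimulationConfig(
                    pf_true=pf, osm_in0=shock["osm_in0"],
                    osm_out_inf=shock["osm_out_inf"],
                    duration_s=duration, dt_s=dt,
                    noise_sd=float(shock.get("noise_sd", 0.0)),
                    v0_over_a=config.geometry.v0_over_a,
                    seed=child, strain=name, treatment=treatment,
                )
                value, fit = fit_water_trace(simulate_shrinkage_trace(sim), config.geometry)
            else:
                shock = config.shock_glycerol
                duration, dt = _gly_duration(pf, pgly, shock, config.geometry)
                sim = SimulationConfig(
                    pf_true=pf, pgly_true=pgly, osm_in0=shock["osm_in0"],
                    osm_out_inf=shock["osm_out_inf"], gly_out=shock["gly_out"],
                    duration_s=duration, dt_s=dt,
                    noise_sd=float(shock.get("noise_sd", 0.0)),
                    v0_over_a=config.geometry.v0_over_a,
                    seed=child, strain=name, treatment=treatment,
                )
                try:
                    value, fit = fit_glycerol_trace(simulate_glycerol_trace(sim), config.geometry)
                except WindowError as err:
                    log.append(f"permeability: {name}/{treatment} glycerol replicate "
                               f"{_rep}: {err}")
                    continue
            values.append(value)
            r2s.append(fit.r2)
        est = aggregate_replicates(
            values, kind=kind, strain=name, treatment=treatment,
            r2_values=r2s, min_r2=config.min_r2,
        )
        if est.n_excluded:
            log.append(f"permeability: {name}/{treatment} [{kind}] excluded "
                       f"{est.n_excluded} trace(s) with r2 < {config.min_r2}")
        replicate_values[(name, treatment, kind)] = values
        rows.append({
            "strain": name, "treatment": treatment, "kind": kind,
            "value_cm_s": est.value, "sd_cm_s": est.sd, "n": est.n,
            "n_excluded": est.n_excluded, "temperature_c": est.temperature_c,
        })
    return pd.DataFrame(rows), replicate_values


@_stage("traces")
def _run_trace_files(config: ExperimentConfig, log):
    rows = []
    replicate_values: dict = {}
    groups: dict = {}
    for path in sorted(config.traces_dir.glob("*.csv")):
        trace = read_trace_csv(path)
        kind = trace.meta.shock_type
        key = (trace.meta.strain, trace.meta.treatment, kind)
        if kind == "water":
            value, fit = fit_water_trace(trace, config.geometry)
        else:
            value, fit = fit_glycerol_trace(trace, config.geometry)
        groups.setdefault(key, []).append((value, fit.r2))
    for (name, treatment, kind), pairs in groups.items():
        values = [v for v, _ in pairs]
        r2s = [r for _, r in pairs]
        est = aggregate_replicates(values, kind=kind, strain=name,
                                   treatment=treatment, r2_values=r2s,
                                   min_r2=config.min_r2)
        replicate_values[(name, treatment, kind)] = values
        rows.append({
            "strain": name, "treatment": treatment, "kind": kind,
            "value_cm_s": est.value, "sd_cm_s": est.sd, "n": est.n,
            "n_excluded": est.n_excluded, "temperature_c": est.temperature_c,
        })
    return pd.DataFrame(rows), replicate_values


@_stage("arrhenius")
def _run_arrhenius(config: ExperimentConfig):
    rows = []
    for entry in config.arrhenius:
        series = generate_arrhenius_series(
            float(entry["ea"]), float(entry["p_ref"]),
            float(entry.get("t_ref_c", 23.0)), list(entry["temperatures_c"]),
            kind=entry.get("kind", "water"), condition=entry.get("strain", ""),
        )
        est = estimate_ea(series)
        rows.append({
            "strain": entry.get("strain", ""), "kind": entry.get("kind", "water"),
            "ea_kcal_per_mol": est.ea_kcal_per_mol, "r2": est.r2,
            "n_temperatures": est.n_temperatures,
        })
    return pd.DataFrame(rows)


@_stage("effects")
def _run_effects(config: ExperimentConfig, perm: pd.DataFrame, replicate_values):
    from .permeability import PermeabilityEstimate

    def lookup(strain, treatment, kind) -> PermeabilityEstimate:
        row = perm[(perm.strain == strain) & (perm.treatment == treatment)
                   & (perm.kind == kind)]
        if row.empty:
            raise ConfigurationError(
                f"effects entry references missing condition "
                f"{strain}/{treatment} [{kind}]"
            )
        r = row.iloc[0]
        return PermeabilityEstimate(kind=kind, value=r.value_cm_s,
                                    sd=r.sd_cm_s, n=int(r.n), strain=strain,
                                    treatment=treatment)

    rows = []
    for entry in config.effects:
        strain, kind = entry["strain"], entry.get("kind", "water")
        c_treat, t_treat = entry.get("control", "none"), entry["treated"]
        control = lookup(strain, c_treat, kind)
        treated = lookup(strain, t_treat, kind)
        eff = treatment_effect(
            control, treated,
            control_values=replicate_values.get((strain, c_treat, kind)),
            treated_values=replicate_values.get((strain, t_treat, kind)),
        )
        rows.append({
            "strain": strain, "kind": kind, "control": c_treat, "treated": t_treat,
            "control_value": control.value, "treated_value": treated.value,
            "percent_change": eff.percent_change,
            "percent_change_rounded": eff.percent_change_rounded,
            "fold_change": eff.fold_change, "t": eff.t_stat, "df": eff.df,
            "p": eff.p_value, "stars": eff.stars,
        })
    return pd.DataFrame(rows)


@_stage("phin")
def _run_phin(config: ExperimentConfig):
    rows = []
    for entry in config.weak_acid:
        kwargs = {}
        if "pka" in entry:
            kwargs["pka"] = float(entry["pka"])
        assay = generate_weak_acid_assay(float(entry["ph_in_true"]),
                                         float(entry["ph_out"]), **kwargs)
        result = compute_phin(assay)
        rows.append({
            "label": entry.get("label", ""), "ph_out": assay.ph_out,
            "pka": assay.pka, "ratio_in_out": assay.ratio_in_out,
            "ph_in": result.ph_in,
        })
    return pd.DataFrame(rows)


@_stage("expression")
def _run_expression(config: ExperimentConfig, seeds, log):
    rows = []
    for entry in config.qpcr:
        gene = entry["gene"]
        curves = generate_qpcr_curves(
            float(entry["true_log2fc"]), float(entry.get("cq_ref", 24.0)),
            n_replicates=int(entry.get("n_replicates", 3)),
            noise_sd=float(entry.get("noise_sd", 0.0)),
            seed=next(seeds), gene=gene,
            reference_gene=entry.get("reference_gene", "GAPDH"),
            control_label=entry.get("control", "control"),
            treated_label=entry.get("treated", "treated"),
            bio_cq_sd=float(entry.get("bio_cq_sd", 0.0)),
        )
        table = cq_table(curves)
        result = delta_delta_cq(
            table, gene, reference_gene=entry.get("reference_gene", "GAPDH"),
            control=entry.get("control", "control"),
            treated=entry.get("treated", "treated"),
        )
        if result.n_excluded:
            log.append(f"expression: {gene}: {result.n_excluded} well(s) with "
                       "undetermined Cq excluded")
        rows.append({
            "gene": gene, "tissue": entry.get("tissue", ""),
            "comparison": f"{result.comparison[0]} vs {result.comparison[1]}",
            "log2fc": result.log2_fold_change, "se": result.se,
            "p": result.p_value, "stars": significance_stars(result.p_value),
            "n_excluded": result.n_excluded,
        })
    return pd.DataFrame(rows)


@_stage("gas_exchange")
def _run_gas_exchange(config: ExperimentConfig):
    if not config.gas_exchange:
        return None
    df = pd.DataFrame(config.gas_exchange)
    df["wue"] = df["A"] / df["gs"]
    return df


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Execute every configured stage in dependency order."""
    log: list[str] = [f"config sha256 {config.config_hash}", f"seed {config.seed}"]
    seeds = _seed_stream(config.seed)
    if config.traces_dir is not None:
        perm, replicate_values = _run_trace_files(config, log)
    else:
        perm, replicate_values = _run_permeability(config, seeds, log)
    arrhenius = _run_arrhenius(config)
    effects = _run_effects(config, perm, replicate_values) if len(perm) else pd.DataFrame()
    phin = _run_phin(config)
    expression = _run_expression(config, seeds, log)
    gas = _run_gas_exchange(config)
    return ResultsBundle(
        permeability=perm, arrhenius=arrhenius, effects=effects, phin=phin,
        expression=expression, gas_exchange=gas,
        replicate_values=replicate_values, log=log,
        config_hash=config.config_hash, seed=config.seed,
    )


def _fmt_perm(value: float) -> str:
    return f"{value:.3e}"


def write_report(bundle: ResultsBundle, output_dir) -> "list[Path]":
    """Write the CSV tables plus a human-readable summary and run log."""
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as err:
        raise PipelineError(f"output directory {out} is not writable: {err}") from err

    written = []
    tables = {
        "permeability.csv": bundle.permeability,
        "arrhenius.csv": bundle.arrhenius,
        "effects.csv": bundle.effects,
        "phin.csv": bundle.phin,
        "expression.csv": bundle.expression,
    }
    if bundle.gas_exchange is not None:
        tables["gas_exchange.csv"] = bundle.gas_exchange
    for name, df in tables.items():
        written.append(write_table(df if df is not None else pd.DataFrame(),
                                   out / name, config_hash=bundle.config_hash,
                                   seed=bundle.seed))

    lines = ["aqpflow run summary",
             f"config sha256: {bundle.config_hash}  seed: {bundle.seed}", ""]
    lines.append("Permeability")
    if len(bundle.permeability):
        for _, r in bundle.permeability.iterrows():
            label = "Pf" if r.kind == "water" else "Pgly"
            lines.append(f"  {r.strain:<12} {r.treatment:<10} [{r.kind}] "
                         f"{label} = {_fmt_perm(r.value_cm_s)} ± {_fmt_perm(r.sd_cm_s)} cm/s (n={int(r.n)})")
    else:
        lines.append("  none computed")
    lines.append("")
    lines.append("Activation energies")
    if len(bundle.arrhenius):
        for _, r in bundle.arrhenius.iterrows():
            lines.append(f"  {r.strain:<12} [{r.kind}] Ea = {r.ea_kcal_per_mol:.2f} "
                         f"kcal/mol (r2={r.r2:.4f}, {int(r.n_temperatures)} T)")
    else:
        lines.append("  none computed")
    lines.append("")
    lines.append("Treatment effects")
    if len(bundle.effects):
        for _, r in bundle.effects.iterrows():
            p_txt = f", p={r.p:.2e} {r.stars}".rstrip() if pd.notna(r.p) else ""
            lines.append(f"  {r.strain:<12} [{r.kind}] {r.treated} vs {r.control}: "
                         f"{int(r.percent_change_rounded):+d}% "
                         f"(fold {r.fold_change:.2f}{p_txt})")
    else:
        lines.append("  none computed")
    lines.append("")
    lines.append("Intracellular pH")
    if len(bundle.phin):
        for _, r in bundle.phin.iterrows():
            lines.append(f"  {r.label}: pH_in = {r.ph_in:.2f} "
                         f"(pH_out {r.ph_out:.2f}, ratio {r.ratio_in_out:.3f})")
    else:
        lines.append("  none computed")
    lines.append("")
    lines.append("Relative expression")
    if len(bundle.expression):
        for _, r in bundle.expression.iterrows():
            p_txt = f", p={r.p:.2e} {r.stars}".rstrip() if pd.notna(r.p) else ""
            lines.append(f"  {r.gene:<12} {r.tissue:<12} {r.comparison}: "
                         f"log2FC = {r.log2fc:+.2f} ± {r.se:.2f}{p_txt}")
    else:
        lines.append("  none computed")
    lines.append("")

    summary = out / "summary.txt"
    summary.write_text("\n".join(lines))
    written.append(summary)
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(bundle.log) + "\n")
    written.append(log_path)
    return written
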