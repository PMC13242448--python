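"""Seeded synthetic data with the statistical structure the analysis assumes.

The stopped-flow generator integrates the osmotic volume-flux model for a
cell of constant membrane area A (fixed at its initial value, consistent
with using a single V0/A in the permeability formulas):

    dV/dt  = -Pf * A * Vw * (osm_out - N_s / V)          (water efflux)
    dN_g/dt =  Pgly * A * (gly_out - N_g / V)            (glycerol influx)

with N_s the conserved amount of impermeant internal solute, so that the
internal osmolarity is (N_s + N_g)/V. In relative volume v = V/V0 this
closes to a two-state ODE driven by Pf and Pgly alone. A hyperosmotic
sorbitol shock (gly_out = 0) gives a monotone shrinkage to the
Boyle-van 't Hoff equilibrium v(inf) = osm_in0/osm_out_inf; a glycerol
shock adds re-swelling as glycerol equilibrates and water follows.

The fluorescence of the volume-sensitive dye is taken linear in relative
volume, signal = 1 + alpha (v - 1), with additive Gaussian noise; any
monotone calibration yields the same fitted rate after normalization.

The module also generates exactly ln-linear Arrhenius series, weak-acid
accumulation ratios from equilibrium partitioning of the neutral species,
and sigmoid qPCR amplification curves whose threshold crossings encode a
chosen expression fold change under the perfect-efficiency (doubling per
cycle) model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .constants import (
    OSM_TO_MOL_PER_CM3,
    PKA_PROPIONIC,
    R_KCAL_PER_MOL_K,
    VW_CM3_PER_MOL,
    celsius_to_kelvin,
)
from .errors import ConfigurationError, DomainError
from .expression import AmplificationCurve
from .permeability import ArrheniusSeries
from .regulation import WeakAcidAssay
from .traces import ShockTrace, TraceMeta

__all__ = [
    "SimulationConfig",
    "simulate_shrinkage_trace",
    "simulate_glycerol_trace",
    "generate_arrhenius_series",
    "generate_weak_acid_assay",
    "generate_qpcr_curves",
]

#: Relative tolerance of the stiff-capable adaptive integrator.
ODE_RTOL = 1e-8
ODE_ATOL = 1e-12


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated hyperosmotic shock.

    Units: v0_over_a cm; permeabilities cm/s; osmolarities osmol/L;
    gly_out mol/L (its osmotic contribution is already included in
    ``osm_out_inf``); times s. ``alpha`` couples relative fluorescence to
    relative volume; ``noise_sd`` is the SD of additive Gaussian noise on
    the relative signal.
    """

    pf_true: float
    osm_in0: float
    osm_out_inf: float
    duration_s: float
    dt_s: float
    pgly_true: float = 0.0
    gly_out: float = 0.0
    v0_over_a: float = 8.33e-5
    temperature_c: float = 23.0
    alpha: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    strain: str = ""
    treatment: str = "none"

    def __post_init__(self) -> None:
        checks = [
            (self.v0_over_a > 0, "v0_over_a > 0"),
            (self.osm_in0 > 0, "osm_in0 > 0"),
            (self.osm_out_inf >= self.osm_in0, "osm_out_inf >= osm_in0 (hyperosmotic shock)"),
            (self.dt_s > 0, "dt_s > 0"),
            (self.duration_s >= 10 * self.dt_s, "duration_s >= 10 * dt_s"),
            (self.noise_sd >= 0, "noise_sd >= 0"),
            (self.pf_true >= 0, "pf_true >= 0"),
            (self.pgly_true >= 0, "pgly_true >= 0"),
            (self.gly_out >= 0, "gly_out >= 0"),
            (self.alpha != 0, "alpha != 0"),
        ]
        for ok, name in checks:
            if not ok:
                raise ConfigurationError(f"invalid SimulationConfig: violates {name}")


def _time_axis(config: SimulationConfig) -> np.ndarray:
    n = int(math.floor(config.duration_s / config.dt_s)) + 1
    return np.arange(n) * config.dt_s


def _trace_from_volume(config: SimulationConfig, t: np.ndarray, v: np.ndarray,
                       shock_type: str) -> ShockTrace:
    signal = 1.0 + config.alpha * (v - 1.0)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    meta = TraceMeta(
        strain=config.strain, treatment=config.treatment,
        temperature_c=config.temperature_c, osm_out_inf=config.osm_out_inf,
        shock_type=shock_type, osm_in0=config.osm_in0,
        gly_out=config.gly_out if shock_type == "glycerol" else 0.0,
        alpha=config.alpha, seed=config.seed,
    )
    return ShockTrace(time_s=t, signal=signal, meta=meta)


def simulate_shrinkage_trace(config: SimulationConfig) -> ShockTrace:
    """Water-only hyperosmotic shock (sorbitol): monotone shrinkage.

    The noiseless relative volume solves
    dv/dt = -(Pf Vw / (V0/A)) (osm_out - osm_in0 / v), v(0) = 1,
    with osmolarities in mol/cm^3; the impermeant solute amount is
    conserved exactly (it enters only as the constant osm_in0).
    """
    if config.gly_out != 0:
        raise ConfigurationError("invalid SimulationConfig: violates gly_out == 0 for a sorbitol shock")
    t = _time_axis(config)
    ci = config.osm_in0 * OSM_TO_MOL_PER_CM3
    co = config.osm_out_inf * OSM_TO_MOL_PER_CM3
    c = config.pf_true * VW_CM3_PER_MOL / config.v0_over_a
    if config.pf_true == 0 or config.osm_in0 == config.osm_out_inf:
        v = np.ones_like(t)
    else:
        sol = solve_ivp(
            lambda _t, y: [-c * (co - ci / y[0])],
            (0.0, t[-1]), [1.0], t_eval=t, method="LSODA",
            rtol=ODE_RTOL, atol=ODE_ATOL,
        )
        v = sol.y[0]
    return _trace_from_volume(config, t, v, "water")


def simulate_glycerol_trace(config: SimulationConfig) -> ShockTrace:
    """Glycerol hyperosmotic shock: fast shrinkage then re-swelling.

    Adds the internal glycerol state n = N_g/V0 (mol/cm^3):
    dn/dt = (Pgly / (V0/A)) (gly_out - n / v), with the internal
    osmolarity (osm_in0 + n)/v. With pgly_true = 0 this reduces exactly
    to the water-only model; with pgly_true > 0 the noiseless trace is
    biphasic with a single minimum.
    """
    if not config.gly_out > 0:
        raise ConfigurationError("invalid SimulationConfig: violates gly_out > 0 for a glycerol shock")
    t = _time_axis(config)
    ci = config.osm_in0 * OSM_TO_MOL_PER_CM3
    g = config.gly_out * OSM_TO_MOL_PER_CM3
    co = config.osm_out_inf * OSM_TO_MOL_PER_CM3
    cw = config.pf_true * VW_CM3_PER_MOL / config.v0_over_a
    cg = config.pgly_true / config.v0_over_a

    def rhs(_t, y):
        v, n = y
        return [-cw * (co - (ci + n) / v), cg * (g - n / v)]

    if config.pf_true == 0 and config.pgly_true == 0:
        v = np.ones_like(t)
    else:
        sol = solve_ivp(rhs, (0.0, t[-1]), [1.0, 0.0], t_eval=t,
                        method="LSODA", rtol=ODE_RTOL, atol=ODE_ATOL)
        v = sol.y[0]
    return _trace_from_volume(config, t, v, "glycerol")


def generate_arrhenius_series(
    ea_kcal_per_mol: float,
    p_ref: float,
    t_ref_c: float,
    temperatures_c: "list[float]",
    *,
    kind: str = "water",
    condition: str = "",
) -> ArrheniusSeries:
    """Exactly ln-linear permeability-vs-temperature series.

    P(T) = p_ref * exp[-Ea/R (1/T - 1/T_ref)], T in kelvin. Feeding the
    result to the Arrhenius estimator recovers ``ea_kcal_per_mol``.
    """
    if not temperatures_c:
        raise DomainError("temperatures list is empty")
    if not p_ref > 0:
        raise DomainError("p_ref must be > 0")
    t_ref_k = celsius_to_kelvin(t_ref_c)
    points = []
    for tc in temperatures_c:
        tk = celsius_to_kelvin(tc)
        if tk <= 0:
            raise DomainError(f"non-physical temperature {tc} C")
        p = p_ref * math.exp(-(ea_kcal_per_mol / R_KCAL_PER_MOL_K) * (1.0 / tk - 1.0 / t_ref_k))
        points.append((tk, p))
    return ArrheniusSeries(points=tuple(points), kind=kind, condition=condition)


def generate_weak_acid_assay(
    ph_in_true: float, ph_out: float, pka: float = PKA_PROPIONIC
) -> WeakAcidAssay:
    """Equilibrium accumulation ratio of a membrane-permeant weak acid.

    Only the neutral species equilibrates across the membrane, so the
    total (neutral + anion) in/out concentration ratio is
    R = (1 + 10^(pH_in - pKa)) / (1 + 10^(pH_out - pKa)).
    """
    for name, ph in (("ph_in_true", ph_in_true), ("ph_out", ph_out)):
        if not 0 < ph < 14:
            raise DomainError(f"{name} = {ph} outside (0, 14)")
    if not pka > 0:
        raise DomainError("pka must be > 0")
    ratio = (1.0 + 10.0 ** (ph_in_true - pka)) / (1.0 + 10.0 ** (ph_out - pka))
    return WeakAcidAssay(ratio_in_out=ratio, ph_out=ph_out, pka=pka)


def generate_qpcr_curves(
    true_log2fc: float,
    cq_ref: float,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    gene: str = "target",
    reference_gene: str = "GAPDH",
    control_label: str = "control",
    treated_label: str = "treated",
    tech_replicates: int = 2,
    delta_cq_control: float = 0.0,
    bio_cq_sd: float = 0.0,
    baseline_level: float = 10.0,
    plateau: float = 1000.0,
    sigmoid_width: float = 0.8,
    threshold: float = 68.0,
    n_cycles: int = 40,
) -> "list[AmplificationCurve]":
    """Sigmoid-onset amplification curves encoding a chosen log2 fold change.

    Fluorescence per well: baseline level plus plateau/(1 + exp(-(c -
    c50)/w)), with c50 placed so that the baseline-subtracted signal
    crosses ``threshold`` at the intended Cq. Under the
    perfect-efficiency model the target gene's Cq is offset from the
    reference gene by -true_log2fc in the treated condition (plus
    ``delta_cq_control`` in both conditions). ``noise_sd`` is Gaussian
    noise on the fluorescence; ``bio_cq_sd`` adds a per-biological-
    replicate Cq shift shared by the target and reference wells of that
    sample (it cancels in the Delta-Cq and models pipetting/loading
    scatter between samples).
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if not 17 < cq_ref < 35:
        raise ConfigurationError(
            f"cq_ref = {cq_ref} outside (17, 35): baseline window (cycles 5-17) "
            "must precede amplification"
        )
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1)
    c50_offset = sigmoid_width * math.log(plateau / threshold - 1.0)
    curves: list[AmplificationCurve] = []
    well_idx = 0
    for condition in (control_label, treated_label):
        fc_shift = -true_log2fc if condition == treated_label else 0.0
        for bio in range(1, n_replicates + 1):
            loading = rng.normal(0.0, bio_cq_sd) if bio_cq_sd > 0 else 0.0
            for gene_name, role, cq0 in (
                (gene, "target", cq_ref + delta_cq_control + fc_shift),
                (reference_gene, "reference", cq_ref),
            ):
                for tech in range(1, tech_replicates + 1):
                    well_idx += 1
                    cq = cq0 + loading
                    c50 = cq + c50_offset
                    fl = baseline_level + plateau / (1.0 + np.exp(-(cycles - c50) / sigmoid_width))
                    if noise_sd > 0:
                        fl = fl + rng.normal(0.0, noise_sd, size=fl.shape)
                    curves.append(AmplificationCurve(
                        well=f"W{well_idx:03d}", gene=gene_name, role=role,
                        condition=condition, bio_rep=bio, tech_rep=tech,
                        cycles=cycles.copy(), fluorescence=fl,
                    ))
    return curves


def water_config_for_temperature(config: SimulationConfig, pf: float,
                                 temperature_c: float) -> SimulationConfig:
    """Helper: same shock conditions at another temperature/permeability,
    with the duration rescaled to keep ~the same number of relaxation
    times in the trace."""
    scale = config.pf_true / pf if pf > 0 else 1.0
    return replace(config, pf_true=pf, temperature_c=temperature_c,
                   duration_s=config.duration_s * scale,
                   dt_s=config.dt_s * scale)
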