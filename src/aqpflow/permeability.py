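"""Permeability coefficients, replicate aggregation, Arrhenius analysis.

Kinetic primitives from the trace fits convert to membrane permeability
coefficients through the cell geometry:

* water:    Pf   = k * (V0/A) / (Vw * (osm_out)inf)
* glycerol: Pgly = m * (V0/A)

with Vw = 18 cm^3/mol and osmolarities converted from osmol/L to
mol/cm^3. Activation energies come from ordinary least squares of
ln P on 1/T (kelvin): Ea = -R * slope, R in kcal mol^-1 K^-1, so a low
Ea (below roughly 5-8 kcal/mol) is the classic signature of
channel-mediated transport as opposed to diffusion across the lipid
bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import (
    OSM_TO_MOL_PER_CM3,
    R_KCAL_PER_MOL_K,
    VW_CM3_PER_MOL,
)
from .errors import AggregationError, DomainError

__all__ = [
    "CellGeometry",
    "PermeabilityEstimate",
    "ArrheniusSeries",
    "EaEstimate",
    "compute_pf",
    "compute_pgly",
    "aggregate_replicates",
    "estimate_ea",
]

#: Default r2 floor for a trace fit to enter an aggregate.
DEFAULT_MIN_R2 = 0.9


@dataclass(frozen=True)
class CellGeometry:
    """Initial volume-to-area ratio of the cell, cm.

    The default corresponds to a sphere of radius 2.5 um (V0/A = r/3),
    a typical budding-yeast cell.
    """

    v0_over_a: float = 8.33e-5

    def __post_init__(self) -> None:
        if not 1e-6 < self.v0_over_a < 1e-2:
            raise DomainError(
                f"v0_over_a = {self.v0_over_a} cm outside sane microbial range (1e-6, 1e-2)"
            )


@dataclass(frozen=True)
class PermeabilityEstimate:
    """Aggregated water or glycerol permeability for one condition."""

    kind: str  # "water" | "glycerol"
    value: float  # cm/s
    sd: float  # cm/s, sample SD (n-1)
    n: int
    strain: str = ""
    treatment: str = "none"
    ph: float | None = None
    temperature_c: float = 23.0
    n_excluded: int = 0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("water", "glycerol"):
            raise DomainError(f"unknown permeability kind {self.kind!r}")
        if not self.value > 0:
            raise DomainError("permeability value must be > 0")
        if self.sd < 0 or self.n < 1:
            raise DomainError("sd must be >= 0 and n >= 1")


@dataclass(frozen=True)
class ArrheniusSeries:
    """(temperature K, permeability cm/s) pairs for one condition."""

    points: tuple[tuple[float, float], ...]
    kind: str = "water"
    condition: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(p)) for t, p in self.points)
        object.__setattr__(self, "points", pts)
        if any(p <= 0 for _, p in pts):
            raise DomainError("all permeabilities in an Arrhenius series must be > 0")
        if any(t <= 0 for t, _ in pts):
            raise DomainError("temperatures must be positive kelvin")

    @property
    def temperatures_k(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def permeabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.points])


@dataclass(frozen=True)
class EaEstimate:
    ea_kcal_per_mol: float
    slope_k: float  # slope of ln P vs 1/T, kelvin
    r2: float
    n_temperatures: int = 0
    flags: tuple[str, ...] = field(default=())


def compute_pf(k: float, geometry: CellGeometry, osm_out_inf: float) -> float:
    """Water permeability Pf = k (V0/A) / (Vw (osm_out)inf), cm/s.

    ``k`` in s^-1, ``osm_out_inf`` in osmol/L.
    """
    if not k > 0:
        raise DomainError(f"rate constant must be > 0, got {k}")
    if not osm_out_inf > 0:
        raise DomainError(f"osm_out_inf must be > 0, got {osm_out_inf}")
    return k * geometry.v0_over_a / (VW_CM3_PER_MOL * osm_out_inf * OSM_TO_MOL_PER_CM3)


def invert_pf(pf: float, geometry: CellGeometry, osm_out_inf: float) -> float:
    """Rate constant k (s^-1) that yields the given Pf; algebraic inverse of
    :func:`compute_pf`."""
    if not pf > 0:
        raise DomainError(f"pf must be > 0, got {pf}")
    return pf * VW_CM3_PER_MOL * osm_out_inf * OSM_TO_MOL_PER_CM3 / geometry.v0_over_a


def compute_pgly(m: float, geometry: CellGeometry) -> float:
    """Glycerol permeability Pgly = m (V0/A), cm/s; ``m`` in s^-1."""
    if not m > 0:
        raise DomainError(f"re-swell slope must be > 0, got {m}")
    return m * geometry.v0_over_a


def aggregate_replicates(
    values: "list[float] | np.ndarray",
    *,
    kind: str = "water",
    strain: str = "",
    treatment: str = "none",
    ph: float | None = None,
    temperature_c: float = 23.0,
    r2_values: "list[float] | None" = None,
    min_r2: float = DEFAULT_MIN_R2,
) -> PermeabilityEstimate:
    """Mean and sample SD over replicate shocks, after quality control.

    Traces whose fit r2 falls below ``min_r2`` are excluded and counted
    in ``n_excluded``. A single surviving value is reported with sd = 0
    and flagged.
    """
    vals = np.asarray(values, dtype=float)
    n_excluded = 0
    if r2_values is not None:
        r2 = np.asarray(r2_values, dtype=float)
        if r2.shape != vals.shape:
            raise AggregationError("r2_values must match values in length")
        keep = r2 >= min_r2
        n_excluded = int((~keep).sum())
        vals = vals[keep]
    if vals.size == 0:
        raise AggregationError("no replicates survive quality control")
    flags: tuple[str, ...] = ()
    if vals.size == 1:
        sd = 0.0
        flags = ("single_replicate",)
    else:
        sd = float(np.std(vals, ddof=1))
    return PermeabilityEstimate(
        kind=kind, value=float(np.mean(vals)), sd=sd, n=int(vals.size),
        strain=strain, treatment=treatment, ph=ph, temperature_c=temperature_c,
        n_excluded=n_excluded, flags=flags,
    )


def estimate_ea(series: ArrheniusSeries) -> EaEstimate:
    """Activation energy from OLS of ln P on 1/T: Ea = -R * slope.

    A flat series (equal permeability at every temperature) gives Ea = 0.
    """
    t_k = series.temperatures_k
    p = series.permeabilities
    if np.unique(t_k).size < 3:
        raise DomainError(f"need >= 3 distinct temperatures, got {np.unique(t_k).size}")
    x = 1.0 / t_k
    y = np.log(p)
    if np.ptp(x) == 0:
        raise DomainError("zero temperature spread")
    if np.ptp(y) == 0:  # flat series: zero slope, exact fit
        return EaEstimate(ea_kcal_per_mol=0.0, slope_k=0.0, r2=1.0,
                          n_temperatures=int(np.unique(t_k).size))
    res = stats.linregress(x, y)
    return EaEstimate(
        ea_kcal_per_mol=float(-R_KCAL_PER_MOL_K * res.slope),
        slope_k=float(res.slope),
        r2=float(res.rvalue**2),
        n_temperatures=int(np.unique(t_k).size),
    )
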