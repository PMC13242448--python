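"""Treatment-effect quantification and weak-acid intracellular pH.

Mercury inhibition/activation, beta-mercaptoethanol reversal and pH
gating all reduce to the same comparison: a control and a treated
permeability estimate for the same strain and transport kind, summarized
as a signed percent change, a fold change, and a Welch's t-test on the
replicate values (the test of choice for stopped-flow data, which
accounts for unequal variances between conditions).

Intracellular pH is obtained by inverting the equilibrium distribution
of a membrane-permeant weak acid (propionic acid, pKa 4.87): only the
neutral species crosses the membrane, so the measured in/out
accumulation ratio R determines

    pH_in = pKa + log10[ R (1 + 10^(pH_out - pKa)) - 1 ].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import PKA_PROPIONIC
from .errors import AssayError, ComparisonError, DomainError, InputError, StatisticalTestError
from .permeability import PermeabilityEstimate

__all__ = [
    "WeakAcidAssay",
    "PhinResult",
    "TreatmentEffect",
    "DoseResponse",
    "welch_t_test",
    "treatment_effect",
    "dose_response",
    "compute_phin",
    "significance_stars",
    "round_half_away",
]


@dataclass(frozen=True)
class WeakAcidAssay:
    """In/out total weak-acid concentration ratio at a known external pH."""

    ratio_in_out: float
    ph_out: float
    pka: float = PKA_PROPIONIC

    def __post_init__(self) -> None:
        if not self.ratio_in_out > 0:
            raise DomainError("ratio_in_out must be > 0")
        if not 0 < self.ph_out < 14:
            raise DomainError("ph_out outside (0, 14)")
        if not self.pka > 0:
            raise DomainError("pka must be > 0")


@dataclass(frozen=True)
class PhinResult:
    ph_in: float

    def __post_init__(self) -> None:
        if not 0 < self.ph_in < 14:
            raise AssayError(f"ph_in = {self.ph_in} outside (0, 14)")


@dataclass(frozen=True)
class TreatmentEffect:
    """Control-vs-treated comparison of one permeability kind."""

    control: PermeabilityEstimate
    treated: PermeabilityEstimate
    percent_change: float  # signed; negative = inhibition
    percent_change_rounded: int  # half-away-from-zero, report convention
    fold_change: float
    t_stat: float | None = None
    df: float | None = None
    p_value: float | None = None
    stars: str = ""


@dataclass(frozen=True)
class DoseResponse:
    table: pd.DataFrame  # columns dose, value, sd, n, sorted by dose
    flag: str  # strictly-increasing | strictly-decreasing | non-monotone


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def significance_stars(p: float | None) -> str:
    """Asterisk convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t_stat, df, p_value) with the Welch-Satterthwaite degrees
    of freedom. Requires n >= 2 per group and positive variance in at
    least one group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticalTestError(f"each group needs n >= 2, got {a.size} and {b.size}")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise StatisticalTestError("both groups have zero variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def treatment_effect(
    control: PermeabilityEstimate,
    treated: PermeabilityEstimate,
    control_values=None,
    treated_values=None,
) -> TreatmentEffect:
    """Quantify a treatment as percent change, fold change and Welch test.

    ``percent_change`` = (treated - control)/control * 100 on the means,
    reported both raw and rounded half-away-from-zero to the nearest
    integer. The Welch test runs when per-replicate values are supplied
    for both groups.
    """
    if control.kind != treated.kind:
        raise ComparisonError(
            f"kind mismatch: control is {control.kind!r}, treated is {treated.kind!r}"
        )
    if control.strain and treated.strain and control.strain != treated.strain:
        raise ComparisonError(
            f"strain mismatch: {control.strain!r} vs {treated.strain!r}"
        )
    percent = (treated.value - control.value) / control.value * 100.0
    fold = treated.value / control.value
    t = df = p = None
    stars = ""
    if control_values is not None and treated_values is not None:
        # group order (treated, control): positive t for an increase
        t, df, p = welch_t_test(treated_values, control_values)
        stars = significance_stars(p)
    return TreatmentEffect(
        control=control, treated=treated,
        percent_change=float(percent),
        percent_change_rounded=round_half_away(percent),
        fold_change=float(fold),
        t_stat=t, df=df, p_value=p, stars=stars,
    )


def dose_response(doses, estimates: "list[PermeabilityEstimate]") -> DoseResponse:
    """Order estimates by dose and classify monotonicity of the means."""
    doses = [float(d) for d in doses]
    if len(doses) < 2:
        raise InputError(f"need >= 2 doses, got {len(doses)}")
    if len(doses) != len(estimates):
        raise InputError("doses and estimates must match in length")
    if len(set(doses)) != len(doses):
        raise InputError("duplicate doses")
    order = np.argsort(doses)
    rows = [
        {"dose": doses[i], "value": estimates[i].value, "sd": estimates[i].sd,
         "n": estimates[i].n}
        for i in order
    ]
    table = pd.DataFrame(rows)
    diffs = np.diff(table["value"].to_numpy())
    if np.all(diffs > 0):
        flag = "strictly-increasing"
    elif np.all(diffs < 0):
        flag = "strictly-decreasing"
    else:
        flag = "non-monotone"
    return DoseResponse(table=table, flag=flag)


def compute_phin(assay: WeakAcidAssay) -> PhinResult:
    """Invert the weak-acid distribution for the intracellular pH.

    pH_in = pKa + log10[ R (1 + 10^(pH_out - pKa)) - 1 ]; a ratio for
    which the bracketed argument is <= 0 is inconsistent with any pH and
    raises :class:`AssayError`.
    """
    arg = assay.ratio_in_out * (1.0 + 10.0 ** (assay.ph_out - assay.pka)) - 1.0
    if arg <= 0:
        raise AssayError(
            f"accumulation ratio {assay.ratio_in_out} inconsistent with any "
            f"intracellular pH at ph_out={assay.ph_out}, pKa={assay.pka}"
        )
    return PhinResult(ph_in=assay.pka + math.log10(arg))
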