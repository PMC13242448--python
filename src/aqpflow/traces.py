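"""Stopped-flow trace containers and kinetic fitting.

A :class:`ShockTrace` is one osmotic-shock relaxation record: a strictly
increasing time axis, the fluorescence of the volume-sensitive dye, and
the experimental conditions. Two kinetic primitives are extracted from
normalized traces:

* the shrinkage rate constant ``k`` (s^-1) from a single-exponential fit
  of the water-efflux phase, and
* the re-swelling slope ``m`` (s^-1) from a linear regression of the
  glycerol-influx phase.

The single exponential is only an approximation to the nonlinear osmotic
relaxation: the late tail of a hyperosmotic shrinkage relaxes faster than
the initial-gradient rate by the factor osm_out/osm_in. The default fit
window therefore stops where the smoothed signal has completed 90% of its
decay, which keeps the fitted ``k`` within a few percent of the
initial-gradient (linearized) rate constant that the Pf formula assumes,
for shock osmolarity ratios up to 2.

Likewise, glycerol taken up before and during the re-swell window lowers
the driving gradient below its nominal value; :func:`fit_reswell_slope`
can correct for this using only quantities measurable from the trace
(see ``gradient_correction``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .errors import FitError, InputError, NormalizationError, WindowError

__all__ = [
    "TraceMeta",
    "ShockTrace",
    "ExpFit",
    "SlopeFit",
    "normalize_trace",
    "fit_single_exponential",
    "locate_reswell_window",
    "fit_reswell_slope",
]

#: Width of the centered moving average used for minimum/plateau detection.
SMOOTH_WINDOW = 5

#: Fraction of the decay amplitude remaining at the shrinkage fit-window end.
SHRINK_WINDOW_BAND = 0.10

#: Bounds on the exponential rate constant, s^-1.
K_BOUNDS = (1e-4, 1e3)


@dataclass(frozen=True)
class TraceMeta:
    """Experimental conditions attached to a trace.

    ``osm_in0`` / ``gly_out`` / ``alpha`` are populated by the simulator
    (or a sidecar file) and are optional for hand-prepared data; ``extra``
    preserves unknown sidecar keys (tolerant reader).
    """

    strain: str = ""
    treatment: str = "none"
    temperature_c: float = 23.0
    osm_out_inf: float = 0.0
    shock_type: str = "water"
    osm_in0: float | None = None
    gly_out: float | None = None
    alpha: float = 1.0
    seed: int | None = None
    extra: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class ShockTrace:
    time_s: np.ndarray
    signal: np.ndarray
    meta: TraceMeta

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise InputError("time_s and signal must be 1-D arrays of equal length")
        if t.size < 20:
            raise InputError(f"trace too short: {t.size} samples (need >= 20)")
        if not np.all(np.diff(t) > 0):
            row = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 1
            raise InputError(f"time_s not strictly increasing at row {row}")
        if not np.all(np.isfinite(s)):
            row = int(np.nonzero(~np.isfinite(s))[0][0])
            raise InputError(f"non-finite signal at row {row}")
        if not self.meta.osm_out_inf > 0:
            raise InputError("osm_out_inf must be > 0")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class ExpFit:
    """Single-exponential fit s(t) = offset + amplitude * exp(-k t)."""

    k: float
    amplitude: float
    offset: float
    r2: float
    window: tuple[float, float]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SlopeFit:
    """Normalized re-swell slope from an OLS line over the influx window."""

    m: float
    intercept: float
    r2: float
    window: tuple[float, float]
    flags: tuple[str, ...] = ()


def _smooth(x: np.ndarray, width: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; edges use the available shorter window."""
    half = width // 2
    c = np.cumsum(np.concatenate(([0.0], x)))
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def normalize_trace(trace: ShockTrace) -> ShockTrace:
    """Rescale the signal to relative units: 1 at t = 0.

    The scale is the mean of the first three samples; the transform is a
    pure rescaling, so it is idempotent and leaves fitted rate constants
    unchanged.
    """
    s0 = float(np.mean(trace.signal[:3]))
    if not np.isfinite(s0) or abs(s0) < 1e-12:
        raise NormalizationError("initial signal is zero; cannot normalize")
    if s0 < 0:
        raise NormalizationError("initial signal is negative; cannot normalize")
    return replace(trace, signal=trace.signal / s0)


def _shrink_window(trace: ShockTrace, band: float) -> tuple[float, float]:
    """Default shrinkage fit window: t=0 until the smoothed signal is within
    ``band`` of the decay amplitude above the plateau (mean of the last
    decile of smoothed samples; the mean is unbiased under noise where a
    minimum would sit systematically low)."""
    s = _smooth(trace.signal)
    t = trace.time_s
    tail = s[int(0.9 * s.size):]
    plateau = float(tail.mean()) if tail.size else float(s[-1])
    amp = s[0] - plateau
    if amp <= 0:
        raise FitError("no decay detected (signal does not fall below its start)")
    below = np.nonzero(s <= plateau + band * amp)[0]
    i_end = int(below[0]) if below.size else s.size - 1
    i_end = max(i_end, 10)  # never fit fewer than ~10 samples
    return float(t[0]), float(t[min(i_end, t.size - 1)])


def fit_single_exponential(
    trace: ShockTrace,
    window: tuple[float, float] | None = None,
    *,
    band: float = SHRINK_WINDOW_BAND,
) -> ExpFit:
    """Least-squares fit of s(t) = offset + amplitude * exp(-k t).

    Parameters
    ----------
    trace
        A normalized trace (see :func:`normalize_trace`).
    window
        (start_s, end_s) span to fit; defaults to the shrinkage phase,
        from t = 0 until the smoothed signal has completed ``1 - band``
        of its decay.
    band
        Fraction of the decay amplitude remaining at the default window
        end. The default (0.10) keeps the fitted rate close to the
        initial-gradient rate constant of the underlying osmotic ODE.

    Raises
    ------
    FitError
        For degenerate input (no decay) or non-convergence. A rate
        estimate at a parameter bound is flagged, not silently returned.
    """
    if window is None:
        window = _shrink_window(trace, band)
    t0, t1 = window
    if not (trace.time_s[0] <= t0 < t1 <= trace.time_s[-1] + 1e-12):
        raise FitError(f"fit window {window} outside trace span")
    sel = (trace.time_s >= t0) & (trace.time_s <= t1)
    tw = trace.time_s[sel] - t0
    sw = trace.signal[sel]
    if tw.size < 5:
        raise FitError(f"only {tw.size} samples in fit window (need >= 5)")

    # data-derived starting values
    n_tail = max(1, tw.size // 10)
    offset0 = float(np.mean(sw[-n_tail:]))
    amp0 = float(sw[0] - offset0)
    if amp0 <= 0:
        raise FitError("no decay in fit window")
    target = sw[0] - 0.63 * amp0
    i63 = int(np.argmin(np.abs(sw - target)))
    t63 = tw[i63] if tw[i63] > 0 else tw[-1] / 2
    k0 = float(np.clip(1.0 / t63, *K_BOUNDS))

    def model(t, offset, amplitude, k):
        return offset + amplitude * np.exp(-k * t)

    lo = [-np.inf, 0.0, K_BOUNDS[0]]
    hi = [np.inf, np.inf, K_BOUNDS[1]]
    last_err: Exception | None = None
    for factor in (1.0, 0.3, 3.0):
        try:
            popt, _ = optimize.curve_fit(
                model, tw, sw,
                p0=[offset0, amp0, float(np.clip(k0 * factor, *K_BOUNDS))],
                bounds=(lo, hi), maxfev=20000,
            )
            break
        except RuntimeError as err:  # non-convergence; bounded restarts
            last_err = err
    else:
        raise FitError(f"exponential fit did not converge: {last_err}")

    offset, amplitude, k = (float(v) for v in popt)
    resid = sw - model(tw, *popt)
    ss_tot = float(np.sum((sw - sw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    flags: tuple[str, ...] = ()
    if k <= K_BOUNDS[0] * (1 + 1e-6) or k >= K_BOUNDS[1] * (1 - 1e-6):
        flags = ("k_at_bound",)
    return ExpFit(k=k, amplitude=amplitude, offset=offset, r2=r2,
                  window=(t0, t1), flags=flags)


def locate_reswell_window(
    trace: ShockTrace,
    *,
    recovery_fraction: float = 0.40,
    skip_water_taus: float = 4.0,
    k_water: float | None = None,
    min_points: int = 20,
) -> tuple[float, float]:
    """Locate the glycerol re-swell window of a biphasic trace.

    The window starts after the smoothed-signal minimum, once the fast
    water phase has re-equilibrated: ``skip_water_taus`` relaxation times
    of the shrinkage rate constant past the minimum (the rate is fitted
    from the trace's own shrinkage phase when ``k_water`` is not given;
    if neither is available the start falls back to one sampling
    interval). It ends where the signal has recovered
    ``recovery_fraction`` of the shrinkage amplitude, or at the trace end
    if that level is never reached. Ties in the minimum location break
    toward the earliest time.

    Raises
    ------
    WindowError
        If no minimum followed by a re-swell is detectable (water-only,
        i.e. glycerol-impermeable behaviour).
    """
    s = _smooth(trace.signal)
    t = trace.time_s
    i_min = int(np.argmin(s))  # argmin takes the earliest tie
    shrink_amp = s[0] - s[i_min]
    if i_min >= s.size - 2 or shrink_amp <= 0:
        raise WindowError("no re-swell phase: trace is monotone (glycerol-impermeable)")
    reswell_amp = float(np.max(s[i_min:]) - s[i_min])
    if reswell_amp < 0.02 * shrink_amp:
        raise WindowError("no re-swell phase: recovery below detection (glycerol-impermeable)")

    if k_water is None:
        # fit the trace's own shrinkage phase for the water relaxation rate
        try:
            if i_min >= 10:
                k_water = fit_single_exponential(trace, (t[0], t[i_min])).k
        except FitError:
            k_water = None
    skip = skip_water_taus / k_water if k_water and k_water > 0 else trace.dt_s
    start = float(t[i_min] + max(skip, trace.dt_s))

    rec = s - s[i_min]
    after = (t > start) & (rec >= recovery_fraction * shrink_amp)
    idx = np.nonzero(after)[0]
    i_end = int(idx[0]) if idx.size else t.size - 1
    i_start = int(np.searchsorted(t, start))
    if i_end - i_start < min_points:  # fast influx: keep enough points anyway
        i_end = min(i_start + min_points, t.size - 1)
    if i_start >= i_end:
        raise WindowError("re-swell window is empty (trace ends before recovery)")
    return start, float(t[i_end])


def fit_reswell_slope(
    trace: ShockTrace,
    window: tuple[float, float],
    *,
    gradient_correction: bool = False,
) -> SlopeFit:
    """OLS line over the re-swell window; slope normalized to the glycerol
    gradient so that Pgly = m * (V0/A).

    By default the raw slope (in volume units per second; the fluorescence
    coupling ``alpha`` is divided out) is normalized by the glycerol shock
    fraction g = gly_out / osm_out_inf, which reduces to the bare slope
    for a pure-glycerol shock.

    With ``gradient_correction=True`` the normalization instead uses the
    gradient still present over the window, measured from the trace
    itself: under fast-water quasi-equilibrium the internal glycerol
    content is osm_out * v - osm_in0, so the remaining gradient fraction
    is (gly_out - osm_out + osm_in0 / v̄) / osm_out with v̄ the mean
    relative volume over the window. This removes the systematic
    underestimate caused by glycerol taken up before and during the
    window and equals the plain g-normalization when no glycerol has
    entered yet. It requires ``osm_in0`` and ``gly_out`` in the metadata.
    """
    t0, t1 = window
    sel = (trace.time_s >= t0) & (trace.time_s <= t1)
    tw = trace.time_s[sel]
    sw = trace.signal[sel]
    if tw.size < 5:
        raise FitError(f"only {tw.size} samples in re-swell window (need >= 5)")
    res = stats.linregress(tw, sw)
    alpha = trace.meta.alpha if trace.meta.alpha else 1.0
    slope_v = res.slope / alpha

    osm_out = trace.meta.osm_out_inf
    gly = trace.meta.gly_out
    flags: tuple[str, ...] = ()
    if gradient_correction:
        osm_in0 = trace.meta.osm_in0
        if gly is None or osm_in0 is None:
            raise FitError("gradient correction requires osm_in0 and gly_out metadata")
        v_mean = float(np.mean(1.0 + (sw - 1.0) / alpha))
        grad_fraction = (gly - osm_out + osm_in0 / v_mean) / osm_out
        if grad_fraction <= 0:
            raise FitError("glycerol gradient exhausted over window; cannot normalize")
    else:
        grad_fraction = (gly / osm_out) if gly else 1.0
    m = slope_v / grad_fraction
    if m <= 0:
        flags = ("non_positive_slope",)
    return SlopeFit(m=float(m), intercept=float(res.intercept),
                    r2=float(res.rvalue**2), window=(float(t0), float(t1)),
                    flags=flags)
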