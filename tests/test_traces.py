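"""Trace normalization and kinetic fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aqpflow import (
    compute_pgly,
    fit_reswell_slope,
    fit_single_exponential,
    locate_reswell_window,
    normalize_trace,
    simulate_glycerol_trace,
    simulate_shrinkage_trace,
)
from aqpflow.errors import FitError, NormalizationError, WindowError
from aqpflow.traces import ShockTrace, TraceMeta
from conftest import linearized_rate


def exp_trace(k=0.8, offset=0.6, amplitude=0.4, scale=1.0, duration=None,
              n=500, noise_sd=0.0, seed=0, **meta):
    duration = duration if duration is not None else 10.0 / k
    t = np.linspace(0.0, duration, n)
    s = scale * (offset + amplitude * np.exp(-k * t))
    if noise_sd:
        s = s + np.random.default_rng(seed).normal(0, noise_sd, n)
    return ShockTrace(time_s=t, signal=s, meta=TraceMeta(osm_out_inf=0.42, **meta))


class TestNormalize:
    def test_constant_signal_maps_to_one(self):
        t = np.linspace(0, 10, 50)
        trace = ShockTrace(t, np.full(50, 3.7), TraceMeta(osm_out_inf=0.42))
        assert np.allclose(normalize_trace(trace).signal, 1.0)

    def test_idempotent(self):
        trace = exp_trace(scale=10.0)
        once = normalize_trace(trace)
        twice = normalize_trace(once)
        assert np.allclose(once.signal, twice.signal)

    def test_zero_initial_signal_raises(self):
        t = np.linspace(0, 10, 50)
        trace = ShockTrace(t, np.zeros(50), TraceMeta(osm_out_inf=0.42))
        with pytest.raises(NormalizationError):
            normalize_trace(trace)

    def test_fitted_rate_unchanged_by_normalization(self):
        raw = exp_trace(k=0.5, scale=10.0)
        k_raw = fit_single_exponential(raw).k
        k_norm = fit_single_exponential(normalize_trace(raw)).k
        assert k_norm == pytest.approx(k_raw, rel=1e-9)
        assert k_norm == pytest.approx(0.5, rel=1e-6)

    def test_metadata_preserved(self):
        trace = exp_trace(strain="X", treatment="HgCl2")
        assert normalize_trace(trace).meta == trace.meta


class TestSingleExponentialFit:
    def test_exact_model_recovery(self):
        fit = fit_single_exponential(exp_trace(k=0.8, offset=0.6, amplitude=0.4))
        assert fit.k == pytest.approx(0.8, abs=1e-6)
        assert fit.offset == pytest.approx(0.6, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.4, abs=1e-6)
        assert fit.r2 > 0.999999

    def test_noisy_recovery_within_two_percent(self):
        fit = fit_single_exponential(exp_trace(k=0.8, noise_sd=0.005, seed=42, n=1000))
        assert fit.k == pytest.approx(0.8, rel=0.02)

    def test_constant_trace_is_a_fit_error(self):
        t = np.linspace(0, 10, 100)
        trace = ShockTrace(t, np.ones(100), TraceMeta(osm_out_inf=0.42))
        with pytest.raises(FitError):
            fit_single_exponential(trace)

    def test_window_start_shift_leaves_rate_unchanged(self):
        trace = exp_trace(k=0.8)
        full = fit_single_exponential(trace, (0.0, 10.0))
        shifted = fit_single_exponential(trace, (1.5, 10.0))
        assert shifted.k == pytest.approx(full.k, rel=1e-6)
        # amplitude re-parameterizes by exp(k * shift)
        assert shifted.amplitude == pytest.approx(full.amplitude * np.exp(-0.8 * 1.5), rel=1e-4)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_rate_scale_invariance(self, scale):
        fit = fit_single_exponential(exp_trace(k=1.2, scale=scale, n=200))
        assert fit.k == pytest.approx(1.2, rel=1e-5)

    @pytest.mark.parametrize("ratio", [1.2, 1.5, 2.0])
    @pytest.mark.parametrize("pf", [2e-4, 7e-4, 20e-4])
    def test_fitted_k_matches_linearized_prediction(self, water_config, geometry, pf, ratio):
        """On simulator output the fitted rate tracks k = Pf Vw osm_out (A/V0)
        to within 3% for shock ratios up to 2."""
        cfg = water_config(pf=pf, osm_in0=0.35, osm_out_inf=0.35 * ratio)
        trace = normalize_trace(simulate_shrinkage_trace(cfg))
        fit = fit_single_exponential(trace)
        k_lin = linearized_rate(pf, cfg.osm_out_inf, geometry)
        assert fit.k == pytest.approx(k_lin, rel=0.03)


class TestReswellWindow:
    def test_window_follows_minimum_of_biphasic_trace(self, glycerol_config):
        trace = normalize_trace(simulate_glycerol_trace(glycerol_config()))
        start, end = locate_reswell_window(trace)
        t_min = trace.time_s[int(np.argmin(trace.signal))]
        assert t_min < start < end <= trace.time_s[-1]

    def test_monotone_trace_raises_window_error(self, water_config):
        cfg = water_config()
        trace = simulate_shrinkage_trace(cfg)
        # present it as a (failed) glycerol shock
        trace = ShockTrace(trace.time_s, trace.signal,
                           TraceMeta(osm_out_inf=cfg.osm_out_inf, shock_type="glycerol"))
        with pytest.raises(WindowError, match="impermeable"):
            locate_reswell_window(normalize_trace(trace))

    def test_saturating_recovery_falls_back_to_trace_end(self, glycerol_config):
        # very slow glycerol: 40% recovery is never reached
        cfg = glycerol_config(pgly=1e-8, span_fraction=0.15)
        trace = normalize_trace(simulate_glycerol_trace(cfg))
        _, end = locate_reswell_window(trace)
        assert end == trace.time_s[-1]


class TestReswellSlope:
    def test_exact_line_recovers_slope(self):
        t = np.linspace(0, 100, 200)
        s = 0.5 + 0.01 * t
        # pure-glycerol shock: g = gly_out / osm_out = 1
        meta = TraceMeta(osm_out_inf=0.70, gly_out=0.70, shock_type="glycerol")
        fit = fit_reswell_slope(ShockTrace(t, s, meta), (10.0, 90.0))
        assert fit.m == pytest.approx(0.0100, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_window_with_too_few_points_raises(self):
        t = np.linspace(0, 100, 200)
        meta = TraceMeta(osm_out_inf=0.70, gly_out=0.70, shock_type="glycerol")
        trace = ShockTrace(t, 0.5 + 0.01 * t, meta)
        with pytest.raises(FitError, match="samples"):
            fit_reswell_slope(trace, (10.0, 11.0))

    @pytest.mark.parametrize("pgly", [0.5e-8, 4.38e-8])
    def test_simulator_round_trip_recovers_pgly(self, glycerol_config, geometry, pgly):
        """normalize -> window -> gradient-corrected slope -> Pgly within 5%."""
        trace = normalize_trace(simulate_glycerol_trace(glycerol_config(pgly=pgly)))
        window = locate_reswell_window(trace)
        fit = fit_reswell_slope(trace, window, gradient_correction=True)
        assert compute_pgly(fit.m, geometry) == pytest.approx(pgly, rel=0.05)
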