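"""Synthetic-data generator: osmotic physics, determinism, and the
analytic generators (Arrhenius, weak acid, qPCR)."""

import math

import numpy as np
import pytest

from aqpflow import (
    call_cq,
    generate_arrhenius_series,
    generate_qpcr_curves,
    generate_weak_acid_assay,
    simulate_glycerol_trace,
    simulate_shrinkage_trace,
)
from aqpflow.constants import R_KCAL_PER_MOL_K
from aqpflow.errors import ConfigurationError, DomainError
from aqpflow.simulate import SimulationConfig


class TestShrinkage:
    def test_zero_permeability_gives_flat_trace(self, water_config):
        trace = simulate_shrinkage_trace(water_config(pf=0.0))
        assert np.allclose(trace.signal, 1.0)

    def test_zero_gradient_gives_flat_trace(self, water_config):
        trace = simulate_shrinkage_trace(water_config(osm_in0=0.42, osm_out_inf=0.42))
        assert np.allclose(trace.signal, 1.0)

    def test_terminal_volume_is_boyle_vant_hoff_equilibrium(self, water_config):
        # doubling the external osmolarity halves the equilibrium volume
        trace = simulate_shrinkage_trace(water_config(osm_in0=0.35, osm_out_inf=0.70))
        assert trace.signal[-1] == pytest.approx(0.5, rel=5e-3)

    def test_noiseless_trace_is_monotone_nonincreasing(self, water_config):
        trace = simulate_shrinkage_trace(water_config())
        assert np.all(np.diff(trace.signal) <= 1e-12)

    def test_same_seed_bit_identical_different_seed_differs(self, water_config):
        a = simulate_shrinkage_trace(water_config(noise_sd=0.01, seed=7))
        b = simulate_shrinkage_trace(water_config(noise_sd=0.01, seed=7))
        c = simulate_shrinkage_trace(water_config(noise_sd=0.01, seed=8))
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_glycerol_shock_rejected(self, glycerol_config):
        with pytest.raises(ConfigurationError, match="gly_out"):
            simulate_shrinkage_trace(glycerol_config())

    @pytest.mark.parametrize(
        "override, violated",
        [
            ({"osm_in0": -0.1}, "osm_in0"),
            ({"osm_in0": 0.5, "osm_out_inf": 0.42}, "osm_out_inf"),
            ({"dt_s": 0.0}, "dt_s"),
            ({"duration_s": 0.1, "dt_s": 0.05}, "duration_s"),
            ({"noise_sd": -1.0}, "noise_sd"),
            ({"pf_true": -1e-4}, "pf_true"),
        ],
    )
    def test_invalid_config_names_violated_invariant(self, override, violated):
        base = dict(pf_true=1e-3, osm_in0=0.35, osm_out_inf=0.42,
                    duration_s=10.0, dt_s=0.01)
        base.update(override)
        with pytest.raises(ConfigurationError, match=violated):
            SimulationConfig(**base)


class TestGlycerolShock:
    def test_impermeable_reduces_to_water_only_model(self, glycerol_config, water_config):
        gly = simulate_glycerol_trace(glycerol_config(pgly=0.0))
        cfg = glycerol_config(pgly=0.0)
        water = simulate_shrinkage_trace(SimulationConfig(
            pf_true=cfg.pf_true, osm_in0=cfg.osm_in0, osm_out_inf=cfg.osm_out_inf,
            duration_s=cfg.duration_s, dt_s=cfg.dt_s,
        ))
        assert np.allclose(gly.signal, water.signal, atol=1e-7)

    def test_biphasic_with_single_minimum(self, glycerol_config):
        trace = simulate_glycerol_trace(glycerol_config(pgly=25.84e-8, pf=7.8e-4))
        d = np.diff(trace.signal)
        sign = np.sign(np.where(np.abs(d) < 1e-12, 0.0, d))
        sign = sign[sign != 0]
        flips = np.nonzero(np.diff(sign) != 0)[0]
        assert len(flips) == 1  # one decreasing->increasing turn only
        i_min = int(np.argmin(trace.signal))
        assert 0 < i_min < trace.signal.size - 1

    def test_pure_glycerol_shock_reswells_to_initial_volume(self, glycerol_config):
        # impermeant balance is restored once glycerol equilibrates
        cfg = glycerol_config(pgly=25.84e-8, pf=7.8e-4, span_fraction=16.0)
        trace = simulate_glycerol_trace(cfg)
        assert trace.signal[-1] == pytest.approx(1.0, rel=2e-2)

    def test_initial_reswell_slope_proportional_to_pgly(self, glycerol_config):
        def initial_slope(pgly):
            trace = simulate_glycerol_trace(glycerol_config(pgly=pgly))
            s = trace.signal
            i_min = int(np.argmin(s))
            # quasi-steady slope shortly after the minimum
            i0 = i_min + int(60.0 / trace.dt_s)
            i1 = i0 + int(60.0 / trace.dt_s)
            return (s[i1] - s[i0]) / (trace.time_s[i1] - trace.time_s[i0])

        ratio = initial_slope(2e-8) / initial_slope(1e-8)
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestArrheniusGenerator:
    def test_zero_activation_energy_is_flat(self):
        series = generate_arrhenius_series(0.0, 5e-4, 23.0, [10, 15, 20, 25, 30, 35])
        assert np.allclose(series.permeabilities, 5e-4)

    def test_hand_computed_ea_for_unit_log_step(self):
        # Ea such that ln P rises by exactly 1 from 283.15 K to 308.15 K
        ea = -R_KCAL_PER_MOL_K * 1.0 / (1.0 / 308.15 - 1.0 / 283.15)
        assert ea == pytest.approx(6.934, abs=5e-3)
        series = generate_arrhenius_series(ea, 1e-4, 10.0, [10.0, 35.0])
        lnp = np.log(series.permeabilities)
        assert lnp[1] - lnp[0] == pytest.approx(1.0, abs=1e-12)

    def test_nonphysical_temperature_rejected(self):
        with pytest.raises(DomainError):
            generate_arrhenius_series(5.0, 1e-4, 23.0, [-300.0])
        with pytest.raises(DomainError):
            generate_arrhenius_series(5.0, -1e-4, 23.0, [10.0])


class TestWeakAcidGenerator:
    def test_no_gradient_gives_unit_ratio(self):
        assert generate_weak_acid_assay(5.5, 5.5).ratio_in_out == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "ph_in, expected",
        [(6.1, 7.654), (4.8, 0.7881)],
    )
    def test_accumulation_ratio_against_direct_evaluation(self, ph_in, expected):
        assay = generate_weak_acid_assay(ph_in, 5.0, 4.87)
        direct = (1 + 10 ** (ph_in - 4.87)) / (1 + 10 ** (5.0 - 4.87))
        assert assay.ratio_in_out == pytest.approx(direct, rel=1e-12)
        assert assay.ratio_in_out == pytest.approx(expected, abs=2e-3)

    def test_out_of_range_ph_rejected(self):
        with pytest.raises(DomainError):
            generate_weak_acid_assay(15.0, 5.0)


class TestQpcrGenerator:
    def test_null_effect_gives_equal_cq(self):
        curves = generate_qpcr_curves(0.0, 24.0, n_replicates=1, noise_sd=0.0, seed=0)
        cqs = {(c.role, c.condition): call_cq(c).cq for c in curves}
        assert cqs[("target", "control")] == pytest.approx(cqs[("reference", "control")], abs=0.02)
        assert cqs[("target", "treated")] == pytest.approx(cqs[("reference", "treated")], abs=0.02)

    def test_log2fc_shifts_target_cq_by_minus_fc(self):
        curves = generate_qpcr_curves(2.0, 24.0, n_replicates=1, noise_sd=0.0, seed=0)
        cqs = {(c.role, c.condition): call_cq(c).cq for c in curves}
        # doubling per cycle: 4-fold upregulation crosses threshold 2 cycles sooner
        shift = cqs[("target", "treated")] - cqs[("reference", "treated")]
        assert shift == pytest.approx(-2.0, abs=0.03)

    def test_cq_ref_outside_window_rejected(self):
        with pytest.raises(ConfigurationError, match="cq_ref"):
            generate_qpcr_curves(0.0, 12.0)

    def test_seeded_noise_is_reproducible(self):
        a = generate_qpcr_curves(1.0, 24.0, noise_sd=1.0, seed=3)
        b = generate_qpcr_curves(1.0, 24.0, noise_sd=1.0, seed=3)
        assert all(np.array_equal(x.fluorescence, y.fluorescence) for x, y in zip(a, b))


def test_trace_metadata_records_conditions(self=None, **_):
    cfg = SimulationConfig(pf_true=1e-3, osm_in0=0.35, osm_out_inf=0.42,
                           duration_s=10.0, dt_s=0.01, strain="QsTIP2;1",
                           treatment="HgCl2", seed=11)
    trace = simulate_shrinkage_trace(cfg)
    assert trace.meta.strain == "QsTIP2;1"
    assert trace.meta.treatment == "HgCl2"
    assert trace.meta.seed == 11
    assert trace.meta.shock_type == "water"
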