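import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aqpflow import CellGeometry, SimulationConfig
from aqpflow.constants import OSM_TO_MOL_PER_CM3, VW_CM3_PER_MOL

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def geometry() -> CellGeometry:
    return CellGeometry()


def linearized_rate(pf: float, osm_out_inf: float, geometry: CellGeometry) -> float:
    """Initial-gradient rate constant k = Pf Vw (osm_out)inf (A/V0)."""
    return pf * VW_CM3_PER_MOL * osm_out_inf * OSM_TO_MOL_PER_CM3 / geometry.v0_over_a


@pytest.fixture
def water_config():
    """Factory for a mild sorbitol-shock simulation spanning ~10 relaxation
    times of the linearized shrinkage rate."""

    def make(pf=18.7e-4, osm_in0=0.35, osm_out_inf=0.42, noise_sd=0.0,
             seed=0, n_samples=1200, span_taus=10.0, **kw) -> SimulationConfig:
        klin = linearized_rate(pf, osm_out_inf, CellGeometry(**{k: v for k, v in kw.items() if k == "v0_over_a"}))
        duration = span_taus / klin if klin > 0 else 60.0
        return SimulationConfig(
            pf_true=pf, osm_in0=osm_in0, osm_out_inf=osm_out_inf,
            duration_s=duration, dt_s=duration / n_samples,
            noise_sd=noise_sd, seed=seed, **kw,
        )

    return make


@pytest.fixture
def glycerol_config():
    """Factory for a glycerol shock (external osmolarity doubled entirely by
    glycerol) sampled densely enough to resolve the fast water phase."""

    def make(pf=4.6e-4, pgly=4.38e-8, osm_in0=0.35, gly_out=0.35,
             osm_out_inf=0.70, noise_sd=0.0, seed=0,
             span_fraction=0.6, **kw) -> SimulationConfig:
        geo = CellGeometry(**{k: v for k, v in kw.items() if k == "v0_over_a"})
        beta = osm_in0 / osm_out_inf
        kw_rate = linearized_rate(pf, osm_out_inf, geo)
        kg = (pgly / geo.v0_over_a) / beta
        duration = 8.0 / kw_rate + (span_fraction / kg if kg > 0 else 0.0)
        dt = min(duration / 2000, 0.002 / (kw_rate * (1.0 - beta)))
        return SimulationConfig(
            pf_true=pf, pgly_true=pgly, osm_in0=osm_in0, gly_out=gly_out,
            osm_out_inf=osm_out_inf, duration_s=duration, dt_s=dt,
            noise_sd=noise_sd, seed=seed, **kw,
        )

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
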