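import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmescan import simpop

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_state_config():
    """Half active / half decommissioned: the canonical heterogeneous mixture."""
    return simpop.StateConfig.two_state(0.5, meth_active=0.02, meth_decom=0.8)


@pytest.fixture(scope="session")
def small_annotation():
    return simpop.make_annotation(
        n_chrom=2, chrom_len=500_000, n_enhancers=20, n_genes=40, seed=11
    )


@pytest.fixture(scope="session")
def het_population(small_annotation, two_state_config):
    return simpop.make_population(small_annotation, two_state_config, 2000, seed=12)


@pytest.fixture(scope="session")
def chip_records(het_population):
    """One modest pull-down per mark, shared by downstream tests."""
    err = simpop.ErrorModel()
    return {
        mark: simpop.simulate_chip_bs(het_population, mark, depth=120, err=err, seed=13 + i)
        for i, mark in enumerate(simpop.MARKS)
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
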