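"""Shared fixtures: small simulated cohorts reused across test modules."""

import pytest

from triodnm.calling import FilterConfig
from triodnm.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free cohort with enough planted DNMs for recovery checks."""
    cfg = SimConfig(
        n_families=2,
        n_offspring_per_family=4,
        callable_length=150_000,
        n_chromosomes=2,
        mu_true=1e-5,
        seq_error_rate=0.0,
        shared_fraction=0.15,
        fp_per_offspring=0.7,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Same design with sequencing error switched on."""
    cfg = SimConfig(
        n_families=2,
        n_offspring_per_family=4,
        callable_length=150_000,
        n_chromosomes=2,
        mu_true=1e-5,
        seq_error_rate=1e-3,
        shared_fraction=0.15,
        fp_per_offspring=0.7,
        seed=12,
    )
    return simulate(cfg)


@pytest.fixture()
def default_filters():
    return FilterConfig()
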