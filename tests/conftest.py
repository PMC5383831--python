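import numpy as np
import pytest

from radgsd import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A fast, fully-sexed XY cohort used across tests."""
    base = dict(
        system="XY",
        n_populations=2,
        n_per_population=15,
        n_autosomal_snps=300,
        n_gametolog_snps=40,
        n_sexspecific_loci=30,
        n_autosomal_loci_presence=100,
        fst=0.05,
        leakage_rate=0.05,
        dropout_rate=0.05,
        missing_rate=0.02,
        phenotype_error_rate=0.0,
        sexed_fraction=1.0,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def clean_xy_dataset():
    """Noise-free XY cohort: r=d=m=rho=0, everyone phenotyped."""
    cfg = small_config(
        leakage_rate=0.0, dropout_rate=0.0, missing_rate=0.0, seed=11
    )
    return simulate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def noisy_xy_dataset():
    """XY cohort with the default small-scale noise levels."""
    cfg = small_config()
    return simulate_dataset(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20170301)
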