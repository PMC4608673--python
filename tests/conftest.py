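import numpy as np
import pytest

from eqtlprio import SimConfig, pipeline


@pytest.fixture(scope="session")
def small_config():
    """A compact 2-cohort study used across unit tests."""
    return SimConfig(
        n_cohorts=2,
        n_samples=(60, 80),
        n_genes=30,
        n_snps_per_gene=8,
        cis_radius=50_000,
        eqtl_fraction=0.3,
        beta_dist=(0.8, 0.05),
        seed=123,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return pipeline.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_meta(small_study):
    return pipeline.run_meta_pipeline(
        small_study["genos"], small_study["exprs"],
        radius=small_study["config"].cis_radius, k=3, seed=123,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
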