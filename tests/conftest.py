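import numpy as np
import pytest

import omnikernel as ok


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with planted signal, shared across tests."""
    cfg = ok.SimulationConfig(
        n_samples=150,
        n_cpg=300,
        n_mrna=250,
        n_mirna=120,
        n_causal={"cpg": 20, "mrna": 15, "mirna": 10},
        effect_size_sd={"cpg": 0.8, "mrna": 0.5, "mirna": 0.5},
        latent_effect=0.8,
        outcome_noise_sd=0.6,
        seed=7,
    )
    return ok.generate_cohort(cfg)


@pytest.fixture(scope="session")
def cov_design(small_cohort):
    return small_cohort.phenotypes.covariate_design(add_intercept=False)


@pytest.fixture(scope="session")
def srs(small_cohort):
    return small_cohort.phenotypes.outcome("SRS").to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
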