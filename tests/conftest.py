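import numpy as np
import pytest

from strdose import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact family cohort shared by relatedness/GWAS/BLUP tests."""
    cfg = SimConfig(seed=11, n_families=30, offspring_per_family=5, n_loci=400)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
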