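import numpy as np
import pytest

from kiv2cn import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with families, CN and SNP effects, for shared use."""
    cfg = SimConfig(n_samples=600, n_variants=120, sib_pair_fraction=0.1,
                    snp_h2=0.2, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions at n=2000 (African-ancestry distribution)."""
    cfg = SimConfig(seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
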