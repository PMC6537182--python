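import numpy as np
import pandas as pd
import pytest

from whogem.containers import GenotypeMatrix, QMatrix
from whogem.synthetic_data import LandscapeConfig, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured landscape: 3 populations, 60 samples, 300 loci."""
    cfg = LandscapeConfig(K=3, n_per_pop=20, n_loci=300, fst_f=0.25,
                          decay_rho=1.5, seed=11)
    return make_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_genotypes(rng):
    """Unstructured genotypes: 50 samples x 120 independent loci."""
    p = rng.uniform(0.1, 0.9, 120)
    dosage = rng.binomial(2, p, (50, 120)).astype(float)
    return GenotypeMatrix([f"s{i}" for i in range(50)],
                          [f"v{j}" for j in range(120)], dosage)


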