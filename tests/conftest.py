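import numpy as np
import pytest

from lhspectra.phylo import PhyloCov, phylo_vcv
from lhspectra.synthetic import SimConfig, simulate_dataset, simulate_tree


@pytest.fixture(scope="session")
def tree20():
    return simulate_tree(SimConfig(n_species=20, seed=42))


@pytest.fixture(scope="session")
def cov20(tree20):
    return phylo_vcv(tree20)


@pytest.fixture(scope="session")
def world100():
    """A 100-species synthetic study: (tree, gappy traits, meta, complete)."""
    return simulate_dataset(SimConfig(n_species=100, seed=7))


@pytest.fixture(scope="session")
def star_cov60():
    """Identity covariance = star phylogeny with unit depths, 60 tips."""
    labels = tuple(f"s{i:02d}" for i in range(60))
    return PhyloCov(np.eye(60), labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
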