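import numpy as np
import pandas as pd
import pytest

import evoregion as ev


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); -- ultrametric, depths all 2."""
    return ev.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def toy_distances(toy_tree):
    return ev.patristic_distances(toy_tree)


@pytest.fixture(scope="session")
def small_fauna():
    """A compact 3-region fauna reused by slower tests."""
    cfg = ev.ScenarioConfig(n_regions=3, grid_shape=(9, 9), n_species=60,
                            seed=7)
    return ev.simulate_regional_fauna(cfg)


def random_tree_and_presence(rng, n_species=None, n_cells=None):
    """Random Yule tree plus a random presence matrix with no empty
    rows/columns (helper for invariant tests)."""
    n_species = n_species or int(rng.integers(4, 31))
    n_cells = n_cells or int(rng.integers(5, 51))
    tree = ev.simulate_tree(n_species, seed=int(rng.integers(2 ** 31)))
    pres = (rng.random((n_cells, n_species)) < 0.3).astype(int)
    pres[np.arange(n_cells), rng.integers(0, n_species, n_cells)] = 1
    pres[rng.integers(0, n_cells, n_species), np.arange(n_species)] = 1
    presence = pd.DataFrame(pres, index=np.arange(n_cells),
                            columns=ev.tip_labels(tree))
    return tree, presence
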