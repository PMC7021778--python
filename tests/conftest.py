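import numpy as np
import pandas as pd
import pytest

from divsignal import synthetic
from divsignal.data_model import OccurrenceMatrix, SiteMetadata


@pytest.fixture(scope="session")
def tree10():
    return synthetic.simulate_tree(10, depth_ma=300.0, seed=11)


@pytest.fixture(scope="session")
def tree20():
    return synthetic.simulate_tree(20, depth_ma=300.0, seed=42)


@pytest.fixture(scope="session")
def study():
    """Standard small synthetic study: 12 families x 300 sites."""
    tree, truth, meta, occ = synthetic.make_study(
        n_families=12, n_sites=300, species_per_family=12, seed=7
    )
    return dict(tree=tree, truth=truth, meta=meta, occ=occ)


@pytest.fixture()
def toy_occurrence():
    """4 species in 2 families over 6 sites, hand-countable."""
    inc = pd.DataFrame(
        {
            "sp1": [1, 1, 0, 0, 1, 0],
            "sp2": [0, 1, 1, 0, 0, 0],
            "sp3": [0, 0, 0, 1, 1, 1],
            "sp4": [0, 0, 0, 0, 1, 1],
        },
        index=[f"s{i}" for i in range(1, 7)],
    )
    tax = pd.Series(
        {"sp1": "famA", "sp2": "famA", "sp3": "famB", "sp4": "famB"}, name="family"
    )
    return OccurrenceMatrix(inc, tax)


@pytest.fixture()
def toy_metadata():
    rng = np.random.default_rng(0)
    tab = pd.DataFrame(
        {
            "x": rng.uniform(0, 10, 6),
            "y": rng.uniform(0, 10, 6),
            "elevation": [100.0, 400.0, 800.0, 1200.0, 1600.0, 2000.0],
            "habitat_forest": [0.2, 0.4, 0.6, 0.8, 0.5, 0.3],
            "habitat_grass": [0.8, 0.6, 0.4, 0.2, 0.5, 0.7],
        },
        index=[f"s{i}" for i in range(1, 7)],
    )
    return SiteMetadata(tab)
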