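import warnings

import numpy as np
import pytest

from rgcfate import synthdata as sd
from rgcfate.config import RunConfig

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_tree():
    return sd.make_fate_tree(12, 4, (0, 1, 3, 6, 11, 20), seed=1)


@pytest.fixture(scope="session")
def small_truth(small_tree):
    return sd.simulate_fates(small_tree, 200, sharpness=0.5, seed=2)


@pytest.fixture(scope="session")
def small_dataset():
    """Compact six-age time course with counts, reused across read-only tests."""
    return sd.simulate_dataset(
        n_types=8, n_subclasses=3, n_cells_per_age=150, n_genes=600, seed=5
    )


@pytest.fixture()
def desk_config():
    """Thresholds scaled to the small synthetic matrices used in tests."""
    return RunConfig(min_genes_per_cell=50, min_cells_per_gene=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
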