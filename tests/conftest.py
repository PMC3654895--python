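import numpy as np
import pytest

from annbm.contacts import ContactGrid, load_default_grid
from annbm.encoding import AlleleSequence, PairEncoder


@pytest.fixture(scope="session")
def grid_a():
    return load_default_grid("A")


@pytest.fixture(scope="session")
def grid_b():
    return load_default_grid("B")


@pytest.fixture(scope="session")
def encoder_a(grid_a):
    return PairEncoder(grid=grid_a)


@pytest.fixture(scope="session")
def tiny_grid():
    """Three-cell grid small enough for hand-checked encodings."""
    return ContactGrid(locus="A", cells={(7, 2): 6, (9, 2): 8, (116, 9): 5},
                       n_complexes=10)


@pytest.fixture(scope="session")
def allele_poly():
    """Deterministic 200-residue synthetic allele sequence."""
    rng = np.random.default_rng(123)
    from annbm.matrices import AA_ORDER
    return AlleleSequence("A*TEST01", "".join(rng.choice(list(AA_ORDER), 200)))
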