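import numpy as np
import pytest

from pollicolor.spectra import ReflectanceSpectrum
from pollicolor.trees import PhyloTree, read_newick


@pytest.fixture
def grid():
    return np.arange(300.0, 701.0)


@pytest.fixture
def flat_spectrum(grid):
    return ReflectanceSpectrum(
        wavelengths=grid, reflectance=np.full(grid.size, 50.0),
        species="flat", individual="f1",
    )


@pytest.fixture
def cherry_tree():
    """((A:1,B:1):1,C:2); height 2, ultrametric."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    """5-tip star with unit branches."""
    n = 5
    labels = [f"t{i}" for i in range(n)]
    parent = np.array([n] * n + [-1])
    blen = np.array([1.0] * n + [0.0])
    children = [[] for _ in range(n)] + [list(range(n))]
    return PhyloTree(tip_labels=labels, parent=parent, blen=blen, children=children)


@pytest.fixture
def two_tip_tree():
    return read_newick("(A:1.5,B:1.5);")
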