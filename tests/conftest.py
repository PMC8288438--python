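import numpy as np
import pandas as pd
import pytest

import psmphylo as pp
from psmphylo.dstat import ArrayTree
from psmphylo.traitkit import ABSENT, PRESENT, UNKNOWN, TraitMatrix
from psmphylo.treekit import binarize


@pytest.fixture
def balanced4():
    """((A,B),(C,D)) with unit branch lengths."""
    return pp.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def balanced8():
    return pp.read_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
    )


@pytest.fixture(scope="session")
def yule200():
    return pp.simulate_yule_tree(200, seed=3)


@pytest.fixture(scope="session")
def at200(yule200):
    return ArrayTree(binarize(yule200))


@pytest.fixture
def small_matrix():
    """4 families x 3 classes with known richness rows 0,1,1,3."""
    cells = pd.DataFrame(
        {
            "alkaloids": [UNKNOWN, PRESENT, ABSENT, PRESENT],
            "flavonoids": [ABSENT, UNKNOWN, PRESENT, PRESENT],
            "quinones": [UNKNOWN, ABSENT, UNKNOWN, PRESENT],
        },
        index=["FamW", "FamX", "FamY", "FamZ"],
        dtype=np.int8,
    )
    return TraitMatrix(cells)
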