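import numpy as np
import pytest

from phylorma import parse_newick


@pytest.fixture
def three_tip_tree():
    """Ultrametric 3-tip tree of depth 2: ((A:1,B:1):1,C:2)."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star4():
    """Unit-depth 4-tip star tree (no phylogenetic structure)."""
    return parse_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def quartet_xy():
    """Toy quartet with hand-computed SMA: slope 1, intercept 0, r2 0.64."""
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([0.0, 2.0, 1.0, 3.0])
    return x, y


@pytest.fixture
def five_tip_tree():
    return parse_newick(
        "(((A:0.4,B:0.4):0.6,(C:0.7,D:0.7):0.3):0.5,E:1.5);"
    )
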