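import numpy as np
import pytest

from areacast.graph import build_graph_from_edgelist, grid_graph
from areacast.model import PanelData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_graph():
    """Three areas in a line: a - b - c."""
    return build_graph_from_edgelist(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def grid4():
    return grid_graph(2, 2, rule="rook")


@pytest.fixture
def toy_panel():
    """2 areas x 2 years with simple numbers."""
    return PanelData(
        area_ids=["a", "b"],
        years=[2010, 2011],
        deaths=[[1.0, 2.0], [0.0, 3.0]],
        population=[[100.0, 100.0], [50.0, 60.0]],
        urban=[1, 0],
    )
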