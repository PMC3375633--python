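import numpy as np
import pytest

from voxsim.mask import GridMask
from voxsim.ontology import OntologyGraph


@pytest.fixture
def full_6x8_mask():
    """Fully occupied 6x8 grid; half-grid (6,4) supports a level-3 DWT."""
    return GridMask.full(6, 8)


@pytest.fixture
def holed_5x5_mask():
    """5x5 grid with the four corners and the center missing."""
    occupied = [
        (r, c)
        for r in range(1, 6)
        for c in range(1, 6)
        if (r, c) not in {(1, 1), (1, 5), (5, 1), (5, 5), (3, 3)}
    ]
    return GridMask.from_cells(5, 5, occupied)


@pytest.fixture
def toy_dag():
    """root(10 genes) -> X(5) -> {Y(2), Z(2)}; one gene directly on X."""
    parents = {"root": set(), "X": {"root"}, "Y": {"X"}, "Z": {"X"}}
    annotations = {
        "gy0": {"Y"},
        "gy1": {"Y"},
        "gz0": {"Z"},
        "gz1": {"Z"},
        "gx0": {"X"},
        **{f"gr{i}": {"root"} for i in range(5)},
    }
    return OntologyGraph(parents, "biological_process", annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
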