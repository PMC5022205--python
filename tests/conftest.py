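import numpy as np
import pytest

from regcap.intervals import BinGrid
from regcap.panel import CapturePanel


@pytest.fixture
def small_grid() -> BinGrid:
    return BinGrid({"chr1": 10_000, "chr2": 5_000}, bin_size=100)


@pytest.fixture
def twelve_level_panel() -> CapturePanel:
    """A panel with 300 bins at each sharing level 1..12, evenly spaced."""
    grid = BinGrid({"chr1": 1_000_000}, bin_size=100)
    sharing = {}
    b = 0
    for level in range(1, 13):
        for _ in range(300):
            sharing[b] = level
            b += 2
    return CapturePanel(grid=grid, sharing=sharing,
                        cell_types=[f"ct{i}" for i in range(12)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_926)
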