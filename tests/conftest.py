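import numpy as np
import pytest

from ringmorph.maskio import InstanceMasks


@pytest.fixture
def nested_square_masks() -> InstanceMasks:
    """A 9x9 cell containing a centred 3x3 nucleus (SC=81, SN=9, NCR=1/9)."""
    cell = np.zeros((13, 13), np.uint16)
    nuc = np.zeros((13, 13), np.uint16)
    cell[2:11, 2:11] = 1
    nuc[5:8, 5:8] = 1
    return InstanceMasks(cell, nuc)


@pytest.fixture
def overlap_masks() -> InstanceMasks:
    """One cell overlapped by two nuclei: 30 px with nucleus 1, 50 px with
    nucleus 2 (largest-intersection assignment must pick nucleus 2)."""
    cell = np.zeros((20, 30), np.uint16)
    nuc = np.zeros((20, 30), np.uint16)
    cell[5:15, 5:15] = 1   # 10x10 = 100 px cell
    nuc[5:10, 5:11] = 1    # 5 rows x 6 cols = 30 px, inside the cell
    nuc[10:15, 5:15] = 2   # 5 rows x 10 cols = 50 px, inside the cell
    return InstanceMasks(cell, nuc)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
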