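import numpy as np
import pytest

from recastate.foci import _cell_masks
from recastate.synthetic import (
    CellFieldConfig,
    StorageStructureParams,
    simulate_cell_field,
)


@pytest.fixture(scope="session")
def small_field():
    """A 30-cell field with foci and storage structures, fixed seed."""
    config = CellFieldConfig(
        n_cells=30,
        colocalized_fraction=0.4,
        storage_structure_params=StorageStructureParams(),
        seed=11,
    )
    return simulate_cell_field(config)


@pytest.fixture(scope="session")
def small_field_labels(small_field):
    polys = [c.polygon_px for c in small_field.cells]
    return _cell_masks(polys, small_field.shape)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
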