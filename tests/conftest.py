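import numpy as np
import pytest

from radialcell.segmentation import CellObject
from radialcell.synthetic import SceneParams, generate_scene


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


@pytest.fixture
def disk_cell():
    """Concentric-disk phantom: nucleus radius 5, cell radius 15."""
    shape = (41, 41)
    center = (20, 20)
    return CellObject(
        cell_id=1,
        cell_mask=disk_mask(shape, center, 15),
        nucleus_masks=[disk_mask(shape, center, 5)],
    )


@pytest.fixture
def small_scene():
    """10 well-separated cells, moderate irregularity, fixed seed."""
    params = SceneParams(
        image_height_px=300, image_width_px=300, n_cells=10, seed=3, dead_prob=0.0
    )
    morph, drug, truth = generate_scene(params)
    return params, morph, drug, truth
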