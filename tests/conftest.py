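import numpy as np
import pytest

from cortifilo import SceneParams, make_cell_scene, max_project, segment_cells
from cortifilo.segment import partition_cortex


def noiseless(**kw):
    """SceneParams with noise off and a single slice."""
    kw.setdefault("poisson_scale", 0.0)
    kw.setdefault("gaussian_sd", 0.0)
    kw.setdefault("n_slices", 1)
    return SceneParams(**kw)


@pytest.fixture(scope="session")
def uniform_cell():
    """Noiseless cell with no enrichment or polarity, segmented."""
    params = noiseless(enrichment_factor=1.0, seed=3)
    stack, truth = make_cell_scene(params)
    img = max_project(stack)
    cells = segment_cells(img)
    assert len(cells) == 1
    part = partition_cortex(cells[0], 0.8)
    return params, img, truth, cells[0], part


@pytest.fixture(scope="session")
def enriched_cell():
    """Noiseless cell with 50% cortical enrichment, segmented."""
    params = noiseless(enrichment_factor=1.5, seed=3)
    stack, truth = make_cell_scene(params)
    img = max_project(stack)
    cells = segment_cells(img)
    assert len(cells) == 1
    part = partition_cortex(cells[0], 0.8)
    return params, img, truth, cells[0], part


def random_blob_mask(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """A random simply-connected blob mask (largest smoothed-noise component)."""
    from scipy import ndimage
    from skimage import measure

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=6)
    mask = field > np.percentile(field, 65)
    labels = measure.label(mask)
    if labels.max() == 0:
        return random_blob_mask(rng, shape)
    largest = max(measure.regionprops(labels), key=lambda r: r.area)
    blob = ndimage.binary_fill_holes(labels == largest.label)
    return blob
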