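"""Canned simulation studies used for validation and reproduction.

Each function generates synthetic scenes under the package's default
imaging conditions, runs the full quantification chain on them, and
returns the recovered statistics alongside the ground truth.  They are
deliberately deterministic given a base seed: per-cell seeds are drawn
from a hierarchical seed sequence so the studies reproduce bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .cortical import cortex_cyto_ratio
from .filopodia import radial_tip_search
from .imgio import max_project
from .profiles import cytofluorogram
from .segment import partition_cortex, segment_cells
from .simulate import SceneParams, make_cell_scene, make_two_channel_scene

__all__ = [
    "ratio_recovery_study",
    "filopodia_count_study",
    "colocalization_study",
    "cell_seed",
]


def cell_seed(base_seed: int, index: int) -> int:
    """Deterministic per-cell seed below 2**31 from a base seed."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def ratio_recovery_study(
    enrichment: float,
    n_cells: int = 30,
    base_seed: int = 1,
    noiseless: bool = False,
    band_width_um: float = 0.8,
) -> np.ndarray:
    """Cortex:cytoplasm ratios recovered by the full pipeline.

    Renders ``n_cells`` single-cell scenes at the given enrichment factor
    (no polarity), segments each maximum projection, partitions the
    cortex at ``band_width_um`` and measures the ratio.
    """
    overrides = {}
    if noiseless:
        overrides = {"poisson_scale": 0.0, "gaussian_sd": 0.0, "n_slices": 1}
    ratios = []
    for i in range(1, n_cells + 1):
        params = SceneParams(
            enrichment_factor=enrichment,
            polarity_amplitude=0.0,
            seed=cell_seed(base_seed, i),
            **overrides,
        )
        stack, _ = make_cell_scene(params)
        img = max_project(stack)
        cells = segment_cells(img)
        if len(cells) != 1:
            raise RuntimeError(f"expected 1 segmented cell, got {len(cells)}")
        part = partition_cortex(cells[0], band_width_um)
        ratios.append(cortex_cyto_ratio(img, part))
    return np.asarray(ratios)


def filopodia_count_study(
    n_cells: int = 200,
    base_seed: int = 1,
    max_count: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Detected versus true filopodium counts over synthetic cells.

    Counts are drawn uniformly from 0..max_count; protrusion geometry uses
    the generator defaults (lengths 2.5-4 um, >= 20 deg separation).
    Returns ``(true_counts, detected_counts)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 99]))
    true_counts = []
    detected = []
    for i in range(n_cells):
        k = int(rng.integers(0, max_count + 1))
        params = SceneParams(
            n_filopodia=k,
            filopodium_length_um=float(rng.uniform(2.5, 4.0)),
            image_shape=(300, 300),
            seed=cell_seed(base_seed, 1000 + i),
        )
        stack, truth = make_cell_scene(params)
        img = max_project(stack)
        cells = segment_cells(img)
        if len(cells) != 1:
            raise RuntimeError("segmentation failed on a filopodia study cell")
        tips = radial_tip_search(img, cells[0])
        true_counts.append(k)
        detected.append(len(tips))
    return np.asarray(true_counts), np.asarray(detected)


def colocalization_study(rho: float, base_seed: int = 1) -> float:
    """Sample Pearson r of a two-channel scene with >= 1e5 in-mask pixels."""
    params = SceneParams(
        image_shape=(480, 480),
        pixel_size_um=0.1,
        cell_radius_um=19.0,
        nucleus_radius_um=3.0,
        nucleus_offset_um=2.0,
        n_slices=1,
        seed=cell_seed(base_seed, 7),
    )
    (sa, sb), truth = make_two_channel_scene(params, rho=rho)
    a, b = max_project(sa), max_project(sb)
    res = cytofluorogram(a, b, truth.cells[0].body_mask)
    if res.n_pixels < 1e5:
        raise RuntimeError("colocalization study mask too small")
    return res.pearson_r
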