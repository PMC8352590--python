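"""Filopodium detection by radial tip search, tip registration and counts.

Filopodia are thin actin-filled protrusions whose tips are enriched in the
fluorescent marker.  Detection casts rays outward from the cell centroid
at a fixed angular step; along each ray the intensity is sampled from the
cell boundary out to ``max_length_um``, lightly smoothed, and the
*outermost* local maximum exceeding a noise floor (background median plus
``k_sigma`` robust SDs) becomes a tip candidate.  Candidates from adjacent
rays that belong to one protrusion are merged by greedy non-maximum
suppression: candidates are visited in descending peak intensity and a
candidate is suppressed when it falls within ``merge_angle_deg`` or
``merge_radius_um`` of an already accepted tip.  Greedy-by-intensity
suppression makes the detected count monotone non-increasing in
``k_sigma``.

Tip positions are refined to sub-pixel precision by a quadratic fit around
the 1-D ray peak (a ±1 px error is material at 0.212 µm pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy import ndimage

from .imgio import Micrograph
from .segment import CellRecord

__all__ = [
    "FilopodiumTip",
    "FilopodiaSummary",
    "TipSearchConfig",
    "estimate_background",
    "radial_tip_search",
    "register_tips_to_cells",
    "summarize_filopodia",
]


class TipSearchConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dtheta_deg: float = 1.0
    max_length_um: float = 15.0
    k_sigma: float = 4.0
    merge_angle_deg: float = 5.0
    merge_radius_um: float = 1.0
    step_px: float = 0.5  # radial sampling step along each ray
    smooth_sigma_samples: float = 1.0  # 1-D Gaussian smoothing of ray profiles


@dataclass
class FilopodiumTip:
    position: tuple[float, float]  # (row, col), sub-pixel
    angle: float  # ray angle, radians about the parent centroid
    distance_um: float  # radial distance of the tip from the body boundary
    peak_intensity: float
    cell_id: int | None = None


@dataclass
class FilopodiaSummary:
    """Summary-table row: percentage of cells with filopodia and the mean
    count among those cells (cells without any protrusion excluded)."""

    n_cells: int
    n_positive: int
    percent_with_filopodia: float
    mean_count_positive: float  # 0 when no cell has a filopodium
    sem_count_positive: float
    n_experiments: int | None = None


def estimate_background(
    img: Micrograph, body_masks: list[np.ndarray], clearance_um: float = 3.0
) -> tuple[float, float]:
    """Robust background location/scale from pixels well outside all cells.

    Uses the median and 1.4826×MAD so that stray filopodium pixels (which
    lie outside every body mask) do not inflate the noise floor.
    """
    union = np.zeros(img.shape, dtype=bool)
    for m in body_masks:
        union |= m
    far = ndimage.distance_transform_edt(~union) * img.pixel_size_um > clearance_um
    vals = img.pixels[far] if far.any() else img.pixels[~union]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, 1.4826 * mad


def _boundary_radius_px(filled: np.ndarray, center, angle, max_r_px: float, step: float) -> float:
    """Outermost body pixel along a ray (in px from the centroid)."""
    radii = np.arange(0.0, max_r_px, step)
    rr = center[0] + radii * np.sin(angle)
    cc = center[1] + radii * np.cos(angle)
    inside = ndimage.map_coordinates(
        filled.astype(np.uint8), np.stack([rr, cc]), order=0, mode="constant", cval=0
    ).astype(bool)
    idx = np.flatnonzero(inside)
    return float(radii[idx[-1]]) if idx.size else 0.0


def radial_tip_search(
    img: Micrograph,
    cell: CellRecord,
    config: TipSearchConfig | None = None,
    background: tuple[float, float] | None = None,
) -> list[FilopodiumTip]:
    """Detect filopodium tips of one cell by radial search.

    ``background`` is (median, robust SD) of the image noise floor; when
    omitted it is estimated from pixels >3 µm outside this cell's body.
    """
    config = config or TipSearchConfig()
    px = img.pixel_size_um
    filled = cell.filled_mask
    center = cell.centroid
    # centroid must be inside the body; fall back to the interior point
    # farthest from the boundary (pole of inaccessibility) if not
    if not filled[int(round(center[0])), int(round(center[1]))]:
        dt = ndimage.distance_transform_edt(filled)
        center = tuple(float(v) for v in np.unravel_index(np.argmax(dt), dt.shape))

    if background is None:
        background = estimate_background(img, [filled])
    bg_med, bg_sd = background
    threshold = bg_med + config.k_sigma * bg_sd

    step = config.step_px
    max_search_px = config.max_length_um / px
    angles = np.deg2rad(np.arange(0.0, 360.0, config.dtheta_deg))
    diag_px = float(np.hypot(*img.shape))

    candidates: list[FilopodiumTip] = []
    for ang in angles:
        r_boundary = _boundary_radius_px(filled, center, ang, diag_px, step)
        radii = np.arange(r_boundary + step, r_boundary + max_search_px, step)
        if radii.size < 3:
            continue
        rr = center[0] + radii * np.sin(ang)
        cc = center[1] + radii * np.cos(ang)
        ok = (rr >= 0) & (rr <= img.shape[0] - 1) & (cc >= 0) & (cc <= img.shape[1] - 1)
        if ok.sum() < 3:
            continue
        radii, rr, cc = radii[ok], rr[ok], cc[ok]
        prof = ndimage.map_coordinates(img.pixels, np.stack([rr, cc]), order=1)
        if config.smooth_sigma_samples > 0:
            prof = ndimage.gaussian_filter1d(prof, config.smooth_sigma_samples)
        above = prof > threshold
        is_peak = np.zeros_like(above)
        is_peak[1:-1] = above[1:-1] & (prof[1:-1] >= prof[:-2]) & (prof[1:-1] >= prof[2:])
        peaks = np.flatnonzero(is_peak)
        if peaks.size == 0:
            continue
        i = peaks[-1]  # outermost local maximum
        # sub-pixel quadratic refinement of the radial position
        denom = prof[i - 1] - 2 * prof[i] + prof[i + 1]
        delta = 0.0 if denom == 0 else 0.5 * (prof[i - 1] - prof[i + 1]) / denom
        delta = float(np.clip(delta, -1.0, 1.0))
        r_tip = radii[i] + delta * step
        pos = (center[0] + r_tip * np.sin(ang), center[1] + r_tip * np.cos(ang))
        candidates.append(
            FilopodiumTip(
                position=pos,
                angle=float(ang),
                distance_um=float((r_tip - r_boundary) * px),
                peak_intensity=float(prof[i]),
                cell_id=cell.cell_id,
            )
        )

    # greedy non-maximum suppression, strongest first
    candidates.sort(key=lambda t: -t.peak_intensity)
    merged: list[FilopodiumTip] = []
    merge_angle = np.deg2rad(config.merge_angle_deg)
    for cand in candidates:
        dup = False
        for acc in merged:
            dang = np.abs(np.angle(np.exp(1j * (cand.angle - acc.angle))))
            dist_um = (
                np.hypot(
                    cand.position[0] - acc.position[0], cand.position[1] - acc.position[1]
                )
                * px
            )
            if dang <= merge_angle or dist_um <= config.merge_radius_um:
                dup = True
                break
        if not dup:
            merged.append(cand)
    merged.sort(key=lambda t: t.angle)
    return merged


def register_tips_to_cells(
    tips: list[FilopodiumTip],
    cells: list[CellRecord],
    max_length_um: float = 15.0,
) -> list[FilopodiumTip]:
    """Assign each tip to the cell with the nearest body boundary.

    Ties go to the smaller ``cell_id``; tips farther than ``max_length_um``
    from every boundary are dropped.
    """
    if not cells:
        return []
    px = cells[0].pixel_size_um
    dts = []
    for cell in sorted(cells, key=lambda c: c.cell_id):
        dt = ndimage.distance_transform_edt(~cell.filled_mask) * px
        dts.append((cell.cell_id, dt))
    out: list[FilopodiumTip] = []
    for tip in tips:
        r = int(round(tip.position[0]))
        c = int(round(tip.position[1]))
        best_id, best_d = None, np.inf
        for cid, dt in dts:
            d = dt[r, c]
            if d < best_d:  # strict: earlier (smaller) cell_id wins ties
                best_d, best_id = d, cid
        if best_d <= max_length_um:
            tip.cell_id = best_id
            out.append(tip)
    return out


def summarize_filopodia(
    counts,
    experiments=None,
) -> FilopodiaSummary:
    """Table-style summary of per-cell filopodium counts.

    Percent is taken over *all* analyzed cells; the mean ± SEM only over
    cells with at least one filopodium.  When no cell has a filopodium the
    mean is reported as 0 with ``n_positive=0`` (the "0 ± 0" convention).
    """
    counts = np.asarray(list(counts), dtype=int)
    if counts.size == 0:
        raise ValueError("need at least one analyzed cell")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    positive = counts[counts > 0]
    percent = 100.0 * positive.size / counts.size
    if positive.size:
        mean_pos = float(positive.mean())
        sem_pos = float(positive.std(ddof=1) / np.sqrt(positive.size)) if positive.size > 1 else 0.0
    else:
        mean_pos, sem_pos = 0.0, 0.0
    n_exp = len(set(experiments)) if experiments is not None else None
    return FilopodiaSummary(
        n_cells=int(counts.size),
        n_positive=int(positive.size),
        percent_with_filopodia=percent,
        mean_count_positive=mean_pos,
        sem_count_positive=sem_pos,
        n_experiments=n_exp,
    )
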