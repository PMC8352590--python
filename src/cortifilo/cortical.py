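"""Cortex:cytoplasm enrichment and cortical-asymmetry statistics.

Two per-cell headline numbers:

* **cortex:cytoplasm ratio** — mean intensity over the 0.8 µm cortical
  band divided by mean intensity over the interior cytoplasm (nucleus
  excluded).  A value of ~1 means no cortical enrichment; ~1.2 means 20 %
  enrichment.  The ratio is invariant to a global intensity gain.
* **cortical SD (asymmetry)** — band pixels are binned by angular
  position about the centroid (default 360 bins), and the standard
  deviation across bin means is reported.  A uniformly decorated cortex
  gives SD ≈ 0; intensity concentrated at one edge (leading-edge
  polarity) gives a high SD.  For a cosine-modulated band
  ``M·(1 + A·cos(φ − θ0))`` the population value is ``M·A/√2``.

Binning across angular means (rather than taking the SD over raw band
pixels) decouples the statistic from band thickness; the raw-pixel
reduction is available via ``over="pixels"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import Micrograph
from .segment import CellRecord, CorticalPartition

__all__ = [
    "CorticalProfile",
    "CellMetrics",
    "cortex_cyto_ratio",
    "cortical_asymmetry",
    "peripheral_profile",
]


@dataclass
class CorticalProfile:
    """Mean band intensity versus angular position about the centroid."""

    angles: np.ndarray  # bin-center angles, radians in [0, 2pi)
    mean_intensity: np.ndarray  # NaN where a bin is empty
    n_pixels: np.ndarray
    normalization: str = "raw"  # "raw" | "cytoplasm_mean"

    @property
    def n_bins(self) -> int:
        return self.angles.size

    @property
    def empty_fraction(self) -> float:
        return float(np.isnan(self.mean_intensity).mean())


@dataclass
class CellMetrics:
    """The per-cell statistics reported in the summary tables."""

    cell_id: int
    cortex_cyto_ratio: float | None
    cortical_sd: float | None
    filopodia_count: int | None
    flags: set[str]


def cortex_cyto_ratio(img: Micrograph, part: CorticalPartition) -> float:
    """Mean band intensity divided by mean cytoplasm intensity."""
    if "unmeasurable" in part.flags or not part.cytoplasm_mask.any():
        raise ValueError("cell flagged unmeasurable: empty cytoplasm")
    if not part.band_mask.any():
        raise ValueError("empty cortical band")
    band_mean = float(img.pixels[part.band_mask].mean())
    cyto_mean = float(img.pixels[part.cytoplasm_mask].mean())
    if cyto_mean == 0:
        raise ZeroDivisionError("zero cytoplasm mean intensity")
    return band_mean / cyto_mean


def _bin_band(
    img: Micrograph,
    part: CorticalPartition,
    cell: CellRecord,
    n_bins: int,
) -> CorticalProfile:
    rows, cols = np.nonzero(part.band_mask)
    r0, c0 = cell.centroid
    phi = np.mod(np.arctan2(rows - r0, cols - c0), 2 * np.pi)
    idx = np.minimum((phi / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    vals = img.pixels[rows, cols]
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    angles = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    return CorticalProfile(angles=angles, mean_intensity=means, n_pixels=counts)


def cortical_asymmetry(
    img: Micrograph,
    part: CorticalPartition,
    cell: CellRecord,
    n_bins: int = 360,
    normalized: bool = False,
    over: str = "bin_means",
) -> tuple[float, CorticalProfile]:
    """Cortical-asymmetry SD plus the underlying peripheral profile.

    With ``normalized=True`` intensities are divided by the cytoplasm mean
    first (gain-invariant); the default reports raw intensity units.
    ``over="pixels"`` takes the SD over raw band pixels instead of bin
    means.  More than 25 % empty bins flags the profile (highly concave
    cell); the SD is still computed over the non-empty bins.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if not part.band_mask.any():
        raise ValueError("empty cortical band")
    profile = _bin_band(img, part, cell, n_bins)
    scale = 1.0
    if normalized:
        cyto_mean = float(img.pixels[part.cytoplasm_mask].mean())
        if cyto_mean == 0:
            raise ZeroDivisionError("zero cytoplasm mean intensity")
        scale = 1.0 / cyto_mean
        profile.mean_intensity = profile.mean_intensity * scale
        profile.normalization = "cytoplasm_mean"
    if profile.empty_fraction > 0.25:
        cell.flags.add("concave_profile")
    if over == "pixels":
        sd = float(np.std(img.pixels[part.band_mask] * scale, ddof=1))
    elif over == "bin_means":
        valid = profile.mean_intensity[~np.isnan(profile.mean_intensity)]
        if valid.size < 2:
            raise ValueError("fewer than 2 non-empty angular bins")
        sd = float(np.std(valid, ddof=1))
    else:
        raise ValueError(f"unknown reduction {over!r}")
    return sd, profile


def peripheral_profile(
    img: Micrograph,
    part: CorticalPartition,
    cell: CellRecord,
    n_bins: int = 360,
    normalize: bool = False,
) -> CorticalProfile:
    """The binned peripheral intensity profile itself (for plots and QC)."""
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    profile = _bin_band(img, part, cell, n_bins)
    if normalize:
        cyto_mean = float(img.pixels[part.cytoplasm_mask].mean())
        if cyto_mean == 0:
            raise ZeroDivisionError("zero cytoplasm mean intensity")
        profile.mean_intensity = profile.mean_intensity / cyto_mean
        profile.normalization = "cytoplasm_mean"
    return profile
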