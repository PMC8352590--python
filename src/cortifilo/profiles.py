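"""Pixel-wise colocalization (cytofluorograms) and linescan analyses.

* :func:`cytofluorogram` pairs the in-mask pixel intensities of two
  channels and reports their Pearson correlation, the standard pixel-wise
  colocalization readout for a field of cells.
* :func:`extract_linescan` samples intensity along an arbitrary segment
  (bilinear interpolation, optional perpendicular averaging) — the
  programmatic version of a manually drawn linescan.
* :func:`longest_axis_profile` draws that line through the centroid along
  the body mask's principal axis.
* :func:`average_profiles_spline` averages several normalized profiles by
  fitting a restricted cubic spline (natural cubic basis, linear beyond
  the boundary knots, knots at fixed quantiles) to the pooled points, with
  pointwise SD and SEM bands taken across the per-profile values
  interpolated to a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .imgio import Micrograph
from .segment import CellRecord

__all__ = [
    "Cytofluorogram",
    "LinescanProfile",
    "SplineSummary",
    "cytofluorogram",
    "extract_linescan",
    "longest_axis_profile",
    "normalize_profile",
    "rcs_basis",
    "average_profiles_spline",
    "pseudopod_costaining_correlation",
]

#: Boundary/interior knot quantiles (percent) per knot count — the standard
#: placement used for restricted cubic splines.
KNOT_QUANTILES = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
    6: (5.0, 23.0, 41.0, 59.0, 77.0, 95.0),
    7: (2.5, 18.33, 34.17, 50.0, 65.83, 81.67, 97.5),
}


@dataclass
class Cytofluorogram:
    intensities_a: np.ndarray
    intensities_b: np.ndarray
    pearson_r: float
    n_pixels: int
    mask_kind: str = "field"
    unstable: bool = False  # mask smaller than 100 pixels

    def histogram2d(self, bins: int = 128):
        return np.histogram2d(self.intensities_a, self.intensities_b, bins=bins)


@dataclass
class LinescanProfile:
    positions_um: np.ndarray
    intensities: np.ndarray
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    width_px: int
    normalized: bool = False


@dataclass
class SplineSummary:
    grid: np.ndarray
    mean_curve: np.ndarray
    sd_band: np.ndarray
    sem_band: np.ndarray
    n_profiles: int
    knots: np.ndarray


def cytofluorogram(
    cha: Micrograph, chb: Micrograph, mask: np.ndarray, mask_kind: str = "field"
) -> Cytofluorogram:
    """Pair in-mask pixels of two aligned channels; Pearson r."""
    if cha.shape != chb.shape or mask.shape != cha.shape:
        raise ValueError("channels and mask must share the same geometry")
    if not mask.any():
        raise ValueError("empty mask")
    a = cha.pixels[mask]
    b = chb.pixels[mask]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant channel inside mask: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return Cytofluorogram(
        intensities_a=a,
        intensities_b=b,
        pearson_r=r,
        n_pixels=int(a.size),
        mask_kind=mask_kind,
        unstable=a.size < 100,
    )


def extract_linescan(
    img: Micrograph,
    p0: tuple[float, float],
    p1: tuple[float, float],
    width_px: int = 1,
) -> LinescanProfile:
    """Sample intensity along the segment p0→p1 ((row, col) endpoints).

    Samples are pixel-spaced along the line and averaged over ``width_px``
    perpendicular offsets (centered on the line).  Axis-aligned width-1
    lines at integer coordinates reproduce the raster values exactly.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length_px = float(np.hypot(*(p1 - p0)))
    if length_px == 0:
        raise ValueError("zero-length linescan")
    n = int(np.floor(length_px)) + 1
    t = np.linspace(0.0, length_px, n)
    u = (p1 - p0) / length_px
    v = np.array([-u[1], u[0]])  # unit normal
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    prof = np.zeros(n)
    for off in offsets:
        pts = p0[None, :] + t[:, None] * u[None, :] + off * v[None, :]
        prof += ndimage.map_coordinates(img.pixels, pts.T, order=1, mode="nearest")
    prof /= offsets.size
    return LinescanProfile(
        positions_um=t * img.pixel_size_um,
        intensities=prof,
        endpoints=(tuple(p0), tuple(p1)),
        width_px=width_px,
    )


def longest_axis_profile(
    img: Micrograph,
    cell: CellRecord,
    width_px: int = 1,
    margin_um: float = 0.5,
) -> LinescanProfile:
    """Linescan through the centroid along the body's principal axis.

    The line is clipped to the mask extent along that axis plus
    ``margin_um`` on each side.  Near-circular cells (axis ratio < 1.05)
    keep a defined principal axis but are flagged on the cell record.
    """
    filled = cell.filled_mask
    props = measure.regionprops(filled.astype(int))[0]
    if props.axis_minor_length > 0 and (
        props.axis_major_length / props.axis_minor_length < 1.05
    ):
        cell.flags.add("near_circular")
    theta = props.orientation  # angle of major axis vs row axis (skimage)
    # unit vector along the major axis in (row, col); skimage's orientation
    # is measured from the row axis toward the negative column axis
    u = np.array([np.cos(theta), np.sin(theta)])
    r0 = np.array(cell.centroid)
    pts = np.argwhere(filled) - r0
    proj = pts @ u
    m = margin_um / img.pixel_size_um
    p0 = r0 + (proj.min() - m) * u
    p1 = r0 + (proj.max() + m) * u
    p0 = np.clip(p0, 0, np.array(img.shape) - 1)
    p1 = np.clip(p1, 0, np.array(img.shape) - 1)
    return extract_linescan(img, tuple(p0), tuple(p1), width_px=width_px)


def normalize_profile(profile: LinescanProfile) -> LinescanProfile:
    """Rescale intensities to [0, 1]; idempotent; order preserving."""
    lo = float(profile.intensities.min())
    hi = float(profile.intensities.max())
    if hi == lo:
        raise ValueError("constant profile cannot be normalized")
    return LinescanProfile(
        positions_um=profile.positions_um.copy(),
        intensities=(profile.intensities - lo) / (hi - lo),
        endpoints=profile.endpoints,
        width_px=profile.width_px,
        normalized=True,
    )


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline design matrix, Harrell form.

    Columns: intercept, x, and k−2 truncated-cubic terms constrained so
    the fit is linear beyond the boundary knots; scaled by the squared
    boundary-knot span for conditioning.
    """
    knots = np.sort(np.asarray(knots, dtype=float))
    k = knots.size
    if k < 3:
        raise ValueError("restricted cubic spline needs at least 3 knots")
    x = np.asarray(x, dtype=float)
    t1, tk1, tk = knots[0], knots[-2], knots[-1]
    scale = (tk - t1) ** 2

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [np.ones_like(x), x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def average_profiles_spline(
    profiles: list[LinescanProfile],
    n_knots: int = 5,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> SplineSummary:
    """Average several normalized profiles with a restricted cubic spline.

    Each profile is linearly resampled to a common grid spanning the
    overlap of all position ranges; the spline is fit by least squares to
    the pooled (position, intensity) points, with knots at the standard
    quantiles of the pooled positions.  The SD band is the pointwise
    standard deviation across resampled profiles and SEM = SD/√n.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to average")
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    lo = max(float(p.positions_um.min()) for p in profiles)
    hi = min(float(p.positions_um.max()) for p in profiles)
    if hi <= lo:
        raise ValueError("profiles have non-overlapping position ranges")
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)

    resampled = np.stack(
        [np.interp(grid, p.positions_um, p.intensities) for p in profiles]
    )
    pooled_x = np.concatenate([p.positions_um for p in profiles])
    pooled_y = np.concatenate([p.intensities for p in profiles])
    q = KNOT_QUANTILES.get(n_knots)
    if q is None:  # even spacing of interior quantiles for other counts
        q = tuple(np.linspace(5.0, 95.0, n_knots))
    knots = np.percentile(pooled_x, q)
    X = rcs_basis(pooled_x, knots)
    beta, *_ = np.linalg.lstsq(X, pooled_y, rcond=None)
    mean_curve = rcs_basis(grid, knots) @ beta
    sd = resampled.std(axis=0, ddof=1)
    return SplineSummary(
        grid=grid,
        mean_curve=mean_curve,
        sd_band=sd,
        sem_band=sd / np.sqrt(len(profiles)),
        n_profiles=len(profiles),
        knots=knots,
    )


def pseudopod_costaining_correlation(
    profiles_a: list[LinescanProfile],
    profiles_b: list[LinescanProfile],
    n_knots: int = 5,
    grid: np.ndarray | None = None,
) -> dict:
    """Per-line Pearson correlation of paired two-channel profiles plus the
    spline-averaged curve of each channel.

    Profiles must be paired (same lines, same order); each pair is
    correlated on the positions of channel A after interpolating channel B
    to those positions.
    """
    if len(profiles_a) != len(profiles_b):
        raise ValueError("unpaired inputs: need one channel-B profile per channel-A profile")
    if len(profiles_a) < 2:
        raise ValueError("need at least 2 paired lines")
    rs = []
    for pa, pb in zip(profiles_a, profiles_b):
        yb = np.interp(pa.positions_um, pb.positions_um, pb.intensities)
        rs.append(float(np.corrcoef(pa.intensities, yb)[0, 1]))
    return {
        "per_line_r": np.asarray(rs),
        "mean_r": float(np.mean(rs)),
        "spline_a": average_profiles_spline(profiles_a, n_knots=n_knots, grid=grid),
        "spline_b": average_profiles_spline(profiles_b, n_knots=n_knots, grid=grid),
    }
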