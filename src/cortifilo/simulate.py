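"""Synthetic fluorescence scenes with exact ground truth.

Every downstream stage of this package (segmentation, cortical metrics,
filopodia counting, colocalization) is validated against scenes rendered
here, because the live-cell micrographs the method was developed on are not
public.  A scene emulates a vegetative amoeba imaged by spinning-disk
confocal microscopy:

* a roughly circular cell body (low-order cosine perturbation of a circle),
* a dark nucleus displaced from the centroid,
* a cortical band of configurable width whose mean intensity exceeds the
  cytoplasm by an enrichment factor ``E``, optionally modulated around the
  periphery as ``E·(1 + A·cos(φ − θ0))`` to mimic leading-edge polarity,
* thin filopodial protrusions with Gaussian cross-section and a brighter
  terminal punctum,
* shot (Poisson) plus read (Gaussian) camera noise, independent per
  z-slice; slices share the same ideal image so the maximum projection is
  the analysis substrate, as in the real acquisitions.

The cortical band is rendered with the *same* definition the measurement
side uses — body pixels whose Euclidean distance to the nearest
outside-body pixel is at most ``band_width_um`` — so the photometric truth
(band mean = E × cytoplasm mean on the truth masks) holds exactly at pixel
level, not just asymptotically.

The angular position φ of a pixel is measured about the body centroid as
``atan2(row − r0, col − c0)``, i.e. from the +x (column) axis toward +row;
one fixed convention shared with the cortical and filopodia modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy import ndimage

from .imgio import Micrograph, ZStack

__all__ = [
    "SceneParams",
    "CellTruth",
    "SceneTruth",
    "make_cell_scene",
    "make_two_channel_scene",
    "make_field",
]


class SceneParams(BaseModel):
    """Parameters of one synthetic cell scene.

    Defaults describe the imaging conditions the package models: 0.212 µm
    pixels, 4–6 z-sections (5 by default), a 0.8 µm cortical band, cells of
    ~8 µm radius with a 2 µm nucleus, cytoplasm at 100 a.u. over a 10 a.u.
    background, unit-gain shot noise plus 3 a.u. read noise.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.212
    cell_radius_um: float = 8.0
    boundary_roughness: float = 0.06
    nucleus_radius_um: float = 2.0
    nucleus_offset_um: float = 1.0
    cytoplasm_level: float = 100.0
    enrichment_factor: float = 1.2
    polarity_amplitude: float = 0.0
    polarity_angle: float = 0.0
    band_width_um: float = 0.8
    n_filopodia: int = 0
    filopodium_length_um: float = 3.0
    filopodium_width_um: float = 0.25
    tip_gain: float = 3.0
    filopodium_angles: tuple[float, ...] | None = None
    background_level: float = 10.0
    poisson_scale: float = 1.0
    gaussian_sd: float = 3.0
    n_slices: int = 5
    channel_correlation: float = 0.0
    seed: int = 0

    @field_validator("pixel_size_um", "cell_radius_um", "cytoplasm_level")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("must be positive")
        return v

    @field_validator("enrichment_factor")
    @classmethod
    def _nonneg_e(cls, v: float) -> float:
        if v < 0:
            raise ValueError("enrichment_factor must be >= 0")
        return v

    @field_validator("polarity_amplitude")
    @classmethod
    def _amp(cls, v: float) -> float:
        if not abs(v) < 1:
            raise ValueError("|polarity_amplitude| must be < 1 so band intensity stays positive")
        return v

    @field_validator("channel_correlation")
    @classmethod
    def _rho(cls, v: float) -> float:
        if not -1.0 <= v <= 1.0:
            raise ValueError("channel_correlation must lie in [-1, 1]")
        return v

    @field_validator("n_slices", "n_filopodia")
    @classmethod
    def _counts(cls, v: int) -> int:
        if v < 0 or (v == 0 and False):
            raise ValueError("must be non-negative")
        return v

    @model_validator(mode="after")
    def _geometry(self) -> "SceneParams":
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_filopodia > 0 and self.filopodium_length_um <= 0:
            raise ValueError("filopodium_length_um must be > 0")
        inner = self.cell_radius_um * (1 - self.boundary_roughness)
        if self.nucleus_offset_um + self.nucleus_radius_um >= inner - self.band_width_um:
            raise ValueError("nucleus (radius + offset) must sit strictly inside the cell body, clear of the band")
        return self


@dataclass
class CellTruth:
    """Ground truth for one rendered cell."""

    cell_id: int
    center: tuple[float, float]  # (row, col), pixels
    body_mask: np.ndarray  # filled cell body (band + cytoplasm + nucleus)
    nucleus_mask: np.ndarray
    band_mask: np.ndarray
    enrichment_factor: float
    polarity_amplitude: float
    polarity_angle: float
    tip_coords: np.ndarray  # (k, 2) (row, col), pixels
    tip_angles: np.ndarray  # (k,) radians about the centroid
    radius_um: float

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.body_mask & ~self.band_mask & ~self.nucleus_mask


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene (one or more cells)."""

    cells: list[CellTruth]
    pixel_size_um: float
    channel_correlation: float | None
    noise: dict
    seed: int
    ideal: np.ndarray = field(repr=False, default=None)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def body_union(self) -> np.ndarray:
        out = np.zeros_like(self.cells[0].body_mask)
        for c in self.cells:
            out |= c.body_mask
        return out


def _boundary_radius(params: SceneParams, rng: np.random.Generator):
    """Return r(φ) in µm as a callable; low-order cosine perturbation."""
    orders = np.arange(2, 6)
    amp = rng.uniform(-1.0, 1.0, size=orders.size)
    s = np.abs(amp).sum()
    if s > 0:
        amp = amp / s * params.boundary_roughness
    phase = rng.uniform(0, 2 * np.pi, size=orders.size)
    R = params.cell_radius_um

    def r_of_phi(phi: np.ndarray) -> np.ndarray:
        pert = sum(a * np.cos(m * phi + p) for a, m, p in zip(amp, orders, phase))
        return R * (1.0 + pert)

    return r_of_phi


def _draw_filopodium_angles(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    if params.filopodium_angles is not None:
        angles = np.asarray(params.filopodium_angles, dtype=float)
        if angles.size != params.n_filopodia:
            raise ValueError("filopodium_angles length must equal n_filopodia")
        return np.mod(angles, 2 * np.pi)
    # rejection-sample angles with >= 20 deg pairwise circular separation so
    # protrusions are individually resolvable (the documented default geometry)
    min_sep = np.deg2rad(20.0)
    for _ in range(500):
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=params.n_filopodia))
        if params.n_filopodia < 2:
            return angles
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        if gaps.min() >= min_sep:
            return angles
    raise RuntimeError("could not place filopodia with the required angular separation")


def _render_cell(
    params: SceneParams,
    center: tuple[float, float],
    shape: tuple[int, int],
    rng: np.random.Generator,
    cell_id: int = 1,
) -> tuple[np.ndarray, CellTruth]:
    """Render one cell's noiseless contribution (above background) + truth."""
    px = params.pixel_size_um
    r0, c0 = center
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rows - r0
    dx = cols - c0
    rad_um = np.hypot(dy, dx) * px
    phi = np.mod(np.arctan2(dy, dx), 2 * np.pi)

    r_of_phi = _boundary_radius(params, rng)
    body = rad_um <= r_of_phi(phi)

    # nucleus: disk displaced from the centroid in a seeded direction
    nuc_dir = rng.uniform(0, 2 * np.pi)
    nr = r0 + params.nucleus_offset_um / px * np.sin(nuc_dir)
    nc = c0 + params.nucleus_offset_um / px * np.cos(nuc_dir)
    nucleus = (np.hypot(rows - nr, cols - nc) * px) <= params.nucleus_radius_um
    nucleus &= body

    # cortical band via the exact Euclidean distance transform, matching the
    # measurement-side definition (incl. the sub-pixel boundary offset)
    from .segment import BAND_EDGE_OFFSET_PX

    dt_um = ndimage.distance_transform_edt(body) * px
    band = body & (dt_um <= params.band_width_um + BAND_EDGE_OFFSET_PX * px) & ~nucleus

    E = params.enrichment_factor
    A = params.polarity_amplitude
    img = np.zeros(shape, dtype=float)
    img[body] = params.cytoplasm_level
    img[nucleus] = 0.0  # nucleus devoid of signal
    img[band] = params.cytoplasm_level * E * (1.0 + A * np.cos(phi[band] - params.polarity_angle))

    # filopodia: thin rays from the boundary outward with a bright tip punctum
    k = params.n_filopodia
    tip_coords = np.zeros((k, 2))
    tip_angles = np.zeros(k)
    if k > 0:
        angles = _draw_filopodium_angles(params, rng)
        sigma_px = params.filopodium_width_um / px
        shaft_level = params.cytoplasm_level * E
        fil = np.zeros(shape, dtype=float)
        for i, ang in enumerate(angles):
            base_um = r_of_phi(np.array([ang]))[0]
            u = np.array([np.sin(ang), np.cos(ang)])  # (drow, dcol)
            base = np.array([r0, c0]) + u * base_um / px
            tip = base + u * params.filopodium_length_um / px
            tip_coords[i] = tip
            tip_angles[i] = ang
            # distance of each pixel to the [base, tip] segment
            p = np.stack([rows - base[0], cols - base[1]], axis=-1).astype(float)
            seg = tip - base
            seg_len2 = float(seg @ seg)
            t = np.clip((p @ seg) / seg_len2, 0.0, 1.0)
            d2 = (p[..., 0] - t * seg[0]) ** 2 + (p[..., 1] - t * seg[1]) ** 2
            shaft = shaft_level * np.exp(-d2 / (2 * (sigma_px / 2) ** 2))
            d2tip = (rows - tip[0]) ** 2 + (cols - tip[1]) ** 2
            punct = params.tip_gain * shaft_level * np.exp(-d2tip / (2 * sigma_px**2))
            fil = np.maximum(fil, np.maximum(shaft, punct))
        img[~body] = fil[~body]  # protrusions live outside the body mask

    truth = CellTruth(
        cell_id=cell_id,
        center=(r0, c0),
        body_mask=body,
        nucleus_mask=nucleus,
        band_mask=band,
        enrichment_factor=E,
        polarity_amplitude=A,
        polarity_angle=params.polarity_angle,
        tip_coords=tip_coords,
        tip_angles=tip_angles,
        radius_um=params.cell_radius_um,
    )
    return img, truth


def _apply_noise(ideal: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """One noisy z-slice: scaled Poisson shot noise plus Gaussian read noise.

    Per-pixel variance is ``poisson_scale * mean + gaussian_sd**2``.
    """
    out = ideal
    if params.poisson_scale > 0:
        out = params.poisson_scale * rng.poisson(ideal / params.poisson_scale).astype(float)
    if params.gaussian_sd > 0:
        out = out + rng.normal(0.0, params.gaussian_sd, size=ideal.shape)
    return np.clip(out, 0.0, None)


def make_cell_scene(params: SceneParams) -> tuple[ZStack, SceneTruth]:
    """Render a single-cell z-stack with ground truth.

    Slices share one ideal image and differ only in their noise
    realization; identical ``params`` (including seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    shape = tuple(params.image_shape)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    cell_img, truth_cell = _render_cell(params, center, shape, rng)
    # background only outside the body: in-cell levels are absolute, so the
    # rendered band/cytoplasm mean ratio equals the enrichment factor exactly
    ideal = np.where(truth_cell.body_mask, cell_img, params.background_level + cell_img)
    slices = np.stack([_apply_noise(ideal, params, rng) for _ in range(params.n_slices)])
    stack = ZStack(data=slices, pixel_size_um=params.pixel_size_um, channel="chA")
    truth = SceneTruth(
        cells=[truth_cell],
        pixel_size_um=params.pixel_size_um,
        channel_correlation=None,
        noise={"poisson_scale": params.poisson_scale, "gaussian_sd": params.gaussian_sd},
        seed=params.seed,
        ideal=ideal,
    )
    return stack, truth


def make_two_channel_scene(
    params: SceneParams, rho: float | None = None
) -> tuple[tuple[ZStack, ZStack], SceneTruth]:
    """Render a two-channel scene with a known in-mask pixel correlation.

    Within the cell body mask, channel-B fluctuations are built as
    ``rho * zA + sqrt(1 - rho^2) * zN`` where ``zA`` is the standardized
    channel-A fluctuation field and ``zN`` an independent standard-normal
    field, then rescaled to channel-A intensity levels, so the population
    Pearson correlation of the two channels inside the mask equals ``rho``.
    Outside the mask channel B carries background plus read noise.
    """
    if rho is None:
        rho = params.channel_correlation
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    stack_a, truth = make_cell_scene(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    mask = truth.cells[0].body_mask
    b_slices = np.empty_like(stack_a.data)
    for z in range(params.n_slices):
        a = stack_a.data[z]
        vals = a[mask]
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            raise ValueError("channel A is constant inside the mask; correlation undefined")
        za = (a - mu) / sd
        zn = rng.normal(0.0, 1.0, size=a.shape)
        zb = rho * za + np.sqrt(max(0.0, 1.0 - rho**2)) * zn
        b = np.full(a.shape, params.background_level, dtype=float)
        if params.gaussian_sd > 0:
            b += rng.normal(0.0, params.gaussian_sd, size=a.shape)
        b[mask] = mu + sd * zb[mask]
        b_slices[z] = np.clip(b, 0.0, None)
    stack_b = ZStack(data=b_slices, pixel_size_um=params.pixel_size_um, channel="chB")
    truth.channel_correlation = rho
    return (stack_a, stack_b), truth


def make_field(
    n_cells: int,
    params: SceneParams | Sequence[SceneParams],
    image_shape: tuple[int, int] | None = None,
    seed: int | None = None,
    min_gap_um: float = 2.0,
    max_attempts: int = 2000,
) -> tuple[ZStack, SceneTruth]:
    """Render a multi-cell field with non-overlapping cell bodies.

    ``params`` may be one parameter set shared by every cell or a sequence
    of per-cell sets.  Placement is rejection sampling of centers; bodies
    (plus ``min_gap_um``) must not overlap and must clear the image border
    by each cell's filopodium reach.  Failure after ``max_attempts`` raises
    rather than silently overlapping.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(params, SceneParams):
        plist = [params.model_copy(update={"seed": params.seed + i}) for i in range(n_cells)]
    else:
        plist = list(params)
        if len(plist) != n_cells:
            raise ValueError("need one SceneParams per cell")
    px = plist[0].pixel_size_um
    if any(p.pixel_size_um != px for p in plist):
        raise ValueError("all cells in a field must share pixel_size_um")
    if image_shape is None:
        side = int(np.ceil(np.sqrt(n_cells)) * 2 * (plist[0].cell_radius_um + plist[0].filopodium_length_um + 4) / px)
        image_shape = (side, side)
    seed = plist[0].seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    centers: list[tuple[float, float]] = []
    reach = [
        p.cell_radius_um * (1 + p.boundary_roughness)
        + (p.filopodium_length_um + 3 * p.filopodium_width_um if p.n_filopodia else 0.0)
        for p in plist
    ]
    for i, p in enumerate(plist):
        placed = False
        for _ in range(max_attempts):
            margin = reach[i] / px + 2
            r = rng.uniform(margin, image_shape[0] - 1 - margin)
            c = rng.uniform(margin, image_shape[1] - 1 - margin)
            ok = True
            for j, (rj, cj) in enumerate(centers):
                d_um = np.hypot(r - rj, c - cj) * px
                min_d = (
                    plist[i].cell_radius_um * (1 + plist[i].boundary_roughness)
                    + plist[j].cell_radius_um * (1 + plist[j].boundary_roughness)
                    + min_gap_um
                )
                if d_um < min_d:
                    ok = False
                    break
            if ok:
                centers.append((r, c))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1} without overlap after {max_attempts} attempts"
            )

    ideal = np.full(image_shape, plist[0].background_level, dtype=float)
    fil_total = np.zeros(image_shape, dtype=float)
    truths: list[CellTruth] = []
    for i, (p, ctr) in enumerate(zip(plist, centers)):
        cell_rng = np.random.default_rng(np.random.SeedSequence([seed, 3, i]))
        img, t = _render_cell(p, ctr, image_shape, cell_rng, cell_id=i + 1)
        t.cell_id = i + 1
        ideal[t.body_mask] = img[t.body_mask]
        fil_total += np.where(t.body_mask, 0.0, img)
        truths.append(t)
    union = np.zeros(image_shape, dtype=bool)
    for t in truths:
        union |= t.body_mask
    ideal[~union] += fil_total[~union]

    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    slices = np.stack([_apply_noise(ideal, plist[0], noise_rng) for _ in range(plist[0].n_slices)])
    stack = ZStack(data=slices, pixel_size_um=px, channel="chA")
    truth = SceneTruth(
        cells=truths,
        pixel_size_um=px,
        channel_correlation=None,
        noise={"poisson_scale": plist[0].poisson_scale, "gaussian_sd": plist[0].gaussian_sd},
        seed=seed,
        ideal=ideal,
    )
    return stack, truth


def truth_to_cell_record(cell: CellTruth, pixel_size_um: float):
    """Build a CellRecord/CorticalPartition pair directly from ground truth.

    Bypasses segmentation; used to validate the intensity metrics in
    isolation from the mask-finding stage.
    """
    from .segment import CellRecord, CorticalPartition

    record = CellRecord(
        cell_id=cell.cell_id,
        body_mask=cell.body_mask & ~cell.nucleus_mask,
        nucleus_mask=cell.nucleus_mask,
        centroid=cell.center,
        boundary=np.empty((0, 2)),
        area_um2=float(cell.body_mask.sum()) * pixel_size_um**2,
        expression_mean=float("nan"),
        pixel_size_um=pixel_size_um,
    )
    part = CorticalPartition(
        band_mask=cell.band_mask,
        cytoplasm_mask=cell.cytoplasm_mask,
        nucleus_mask=cell.nucleus_mask,
        band_width_um=0.8,
    )
    return record, part


def write_truth_sidecar(truth: SceneTruth, path) -> None:
    """Write a JSON sidecar with per-cell parameters, tips and RLE masks."""
    import json
    from pathlib import Path

    def rle(mask: np.ndarray) -> dict:
        flat = mask.ravel(order="C").astype(np.int8)
        change = np.flatnonzero(np.diff(flat)) + 1
        starts = np.concatenate([[0], change])
        lengths = np.diff(np.concatenate([starts, [flat.size]]))
        return {
            "shape": list(mask.shape),
            "first": int(flat[0]),
            "lengths": lengths.tolist(),
        }

    payload = {
        "pixel_size_um": truth.pixel_size_um,
        "seed": truth.seed,
        "channel_correlation": truth.channel_correlation,
        "noise": truth.noise,
        "cells": [
            {
                "cell_id": c.cell_id,
                "center": list(c.center),
                "enrichment_factor": c.enrichment_factor,
                "polarity_amplitude": c.polarity_amplitude,
                "polarity_angle": c.polarity_angle,
                "tip_coords": c.tip_coords.tolist(),
                "tip_angles": c.tip_angles.tolist(),
                "body_rle": rle(c.body_mask),
                "nucleus_rle": rle(c.nucleus_mask),
                "band_rle": rle(c.band_mask),
            }
            for c in truth.cells
        ],
    }
    Path(path).write_text(json.dumps(payload))
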