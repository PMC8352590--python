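"""Image containers and file I/O.

All analysis in this package runs on 2-D maximum-intensity projections of
short confocal z-stacks.  The two containers here — :class:`ZStack` and
:class:`Micrograph` — carry the pixel grid together with the physical pixel
size in micrometres, which every downstream metric needs to convert the
0.8 µm cortical band, filopodium lengths etc. into pixels.

Conventions
-----------
* Image coordinates are row-major with the origin at the top-left pixel
  center; ``row`` increases downward, ``col`` to the right.
* µm ↔ pixel conversion always goes through ``pixel_size_um`` with no
  implicit rounding.
* Pixel-size precedence on read: file metadata > caller override > error
  (in strict mode) or the common spinning-disk default 0.212 µm with a
  warning (lenient mode).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ZStack",
    "Micrograph",
    "read_stack",
    "write_stack",
    "max_project",
    "write_results",
    "RESULT_COLUMNS",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: Pixel size of the camera setup the defaults were modelled on (µm/pixel).
DEFAULT_PIXEL_SIZE_UM = 0.212

#: Canonical per-cell results schema.
RESULT_COLUMNS = [
    "field_id",
    "cell_id",
    "experiment_id",
    "cortex_cyto_ratio",
    "cortical_sd",
    "filopodia_count",
    "qc_flags",
]


@dataclass
class ZStack:
    """An ordered stack of equally shaped intensity slices (z, rows, cols)."""

    data: np.ndarray
    pixel_size_um: float
    channel: str = ""
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("ZStack needs at least one 2-D slice")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class Micrograph:
    """A single 2-D fluorescence image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Micrograph pixels must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Micrograph intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("Micrograph intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def max_project(stack: ZStack) -> Micrograph:
    """Per-pixel maximum-intensity projection over z."""
    if stack.n_slices < 1:
        raise ValueError("cannot project an empty stack")
    proj = stack.data.max(axis=0)
    return Micrograph(
        pixels=np.clip(proj, 0, None),
        pixel_size_um=stack.pixel_size_um,
        channel=stack.channel,
        provenance={"projection": "max", "n_slices": stack.n_slices},
    )


def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF with a JSON description sidecar tag.

    Float data is written as float32-compatible (actually float64 preserved
    via tifffile) so round-trips are lossless; pixel size and channel are
    stored in the page description as JSON.
    """
    path = Path(path)
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "channel": stack.channel,
        "z_step_um": stack.z_step_um,
        "axes": "ZYX",
    }
    tifffile.imwrite(path, stack.data, description=json.dumps(meta))
    return path


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    desc = tf.pages[0].description
    if desc:
        try:
            meta = json.loads(desc)
            if isinstance(meta, dict) and meta.get("pixel_size_um"):
                return float(meta["pixel_size_um"])
        except (json.JSONDecodeError, TypeError, ValueError):
            pass
    # fall back to TIFF resolution tags (pixels per unit)
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags.get("ResolutionUnit")
        num, den = xres
        if num and den and unit is not None and unit.value == 3:  # centimetre
            return 1e4 * den / num
    except (KeyError, TypeError, ZeroDivisionError):
        pass
    return None


def read_stack(
    path: str | Path,
    axis_spec: str | None = None,
    pixel_size_um: float | None = None,
    strict: bool = True,
    channel_names: Sequence[str] | None = None,
) -> list[ZStack]:
    """Read a TIFF/OME-TIFF into one :class:`ZStack` per channel.

    Parameters
    ----------
    axis_spec
        Axis order of the on-disk array, e.g. ``"ZYX"`` or ``"CZYX"``.
        Defaults to the axes tifffile reports; required when the file's
        layout is ambiguous (an error names the ambiguity).
    pixel_size_um
        Override used only when the file carries no pixel size.
    strict
        If True, a missing pixel size with no override is an error;
        otherwise 0.212 µm is assumed with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = axis_spec or series.axes
        px = _pixel_size_from_tiff(tf)

    if px is None:
        px = pixel_size_um
    if px is None:
        if strict:
            raise ValueError(
                f"{path}: no pixel size in metadata and none supplied "
                "(strict mode)"
            )
        warnings.warn(
            f"{path}: missing pixel size, assuming {DEFAULT_PIXEL_SIZE_UM} um",
            stacklevel=2,
        )
        px = DEFAULT_PIXEL_SIZE_UM

    axes = axes.upper().replace("S", "C").replace("Q", "Z")
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
        axes = "ZYX" if axes in ("YX", "ZYX") else axes
    if data.ndim == 3:
        if axes not in ("ZYX", "CYX", "IYX", "TYX"):
            raise ValueError(
                f"{path}: ambiguous 3-D axes {axes!r}; pass axis_spec "
                "('ZYX' or 'CYX')"
            )
        if axes == "CYX":
            stacks = [data[i][None] for i in range(data.shape[0])]
        else:
            stacks = [data]
    elif data.ndim == 4:
        if axes == "CZYX":
            stacks = [data[i] for i in range(data.shape[0])]
        elif axes == "ZCYX":
            stacks = [data[:, i] for i in range(data.shape[1])]
        else:
            raise ValueError(
                f"{path}: ambiguous 4-D axes {axes!r}; pass axis_spec "
                "('CZYX' or 'ZCYX')"
            )
    else:
        raise ValueError(f"{path}: unsupported dimensionality {data.ndim}")

    out = []
    for i, arr in enumerate(stacks):
        name = (
            channel_names[i]
            if channel_names is not None and i < len(channel_names)
            else (f"ch{i}" if len(stacks) > 1 else "")
        )
        out.append(ZStack(data=arr, pixel_size_um=px, channel=name))
    return out


def write_results(
    records: Sequence[dict] | pd.DataFrame,
    csv_path: str | Path,
    summary_path: str | Path | None = None,
    config_hash: str | None = None,
    version: str | None = None,
) -> pd.DataFrame:
    """Write the per-cell metrics CSV plus an optional JSON run summary.

    The CSV dialect is fixed: UTF-8, comma separators, '.' decimal, header
    row always present (even for zero records).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records), columns=RESULT_COLUMNS if not records else None)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    df = df[RESULT_COLUMNS + [c for c in df.columns if c not in RESULT_COLUMNS]]
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False, encoding="utf-8")
    if summary_path is not None:
        from . import __version__

        summary = {
            "n_cells": int(len(df)),
            "n_fields": int(df["field_id"].nunique()) if len(df) else 0,
            "config_hash": config_hash,
            "version": version or __version__,
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2))
    return df
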