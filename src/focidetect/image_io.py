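"""Image, mask and report I/O with physical pixel-size metadata.

All pipeline stages consume :class:`ChannelImage` objects: a 2-D float
intensity grid normalized to [0, 1] plus an :class:`ImageMeta` carrying the
pixel size in micrometres. Images may arrive as 8- or 16-bit TIFF or PNG;
integer data are normalized by the dtype maximum so that downstream filter
parameters defined on an 8-bit grey scale can be applied to a re-quantized
view.

Convention: the two channels (nuclear counterstain and foci stain) are two
single-channel files, or one two-page TIFF read page by page. RGB input is
rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile
from skimage.transform import resize

__all__ = [
    "ImageMeta",
    "ChannelImage",
    "LabelMask",
    "ChannelRole",
    "DimensionError",
    "FormatError",
    "read_image",
    "read_image_pair",
    "rescale_to_pixel_size",
    "write_report",
    "write_label_mask",
    "read_label_mask",
    "write_centers",
    "read_centers",
]


class DimensionError(ValueError):
    """Raised when image/mask dimensions are inconsistent."""


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as single-channel grayscale."""


class ChannelRole(str, Enum):
    NUCLEAR = "nuclear"
    FOCI = "foci"


@dataclass(frozen=True)
class ImageMeta:
    """Geometry of one image: size in pixels and physical pixel pitch (μm)."""

    width_px: int
    height_px: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def field_of_view_um(self) -> tuple[float, float]:
        """(width_um, height_um) covered by the image."""
        return (self.width_px * self.pixel_size_um, self.height_px * self.pixel_size_um)


@dataclass
class ChannelImage:
    """One grayscale channel with intensities in [0, 1] and its metadata."""

    pixels: np.ndarray
    meta: ImageMeta
    channel_role: ChannelRole = ChannelRole.FOCI

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DimensionError("ChannelImage expects a 2-D grid")
        h, w = self.pixels.shape
        if (h, w) != (self.meta.height_px, self.meta.width_px):
            raise DimensionError(
                f"pixel grid {h}x{w} does not match meta "
                f"{self.meta.height_px}x{self.meta.width_px}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Boolean foci mask or integer object-label grid, same frame as an image."""

    pixels: np.ndarray
    meta: ImageMeta

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError("LabelMask expects a 2-D grid")
        h, w = self.pixels.shape
        if (h, w) != (self.meta.height_px, self.meta.width_px):
            raise DimensionError("mask dimensions do not match meta")
        if self.pixels.dtype != bool:
            if not np.issubdtype(self.pixels.dtype, np.integer):
                raise FormatError("mask must be boolean or integer-labeled")
            if self.pixels.size and self.pixels.min() < 0:
                raise ValueError("object labels must be non-negative")

    @property
    def binary(self) -> np.ndarray:
        return self.pixels.astype(bool) if self.pixels.dtype != bool else self.pixels


def _load_gray(path: str | Path) -> np.ndarray:
    """Read one single-channel 2-D image; normalize integer data to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by backend
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path} is not single-channel 2-D grayscale (shape {arr.shape}); "
            "split RGB/multi-page data into one file per channel"
        )
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(np.float64) / float(info.max)
    else:
        arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path} contains non-finite values")
    return np.clip(arr, 0.0, None)


def read_image(
    path: str | Path,
    pixel_size_um: float,
    channel_role: ChannelRole = ChannelRole.FOCI,
) -> ChannelImage:
    """Read one grayscale channel from ``path``."""
    arr = _load_gray(path)
    meta = ImageMeta(width_px=arr.shape[1], height_px=arr.shape[0], pixel_size_um=pixel_size_um)
    return ChannelImage(pixels=arr, meta=meta, channel_role=channel_role)


def read_image_pair(
    nuclear_path: str | Path,
    foci_path: str | Path,
    pixel_size_um: float,
) -> tuple[ChannelImage, ChannelImage]:
    """Read matched nuclear and foci channels sharing one :class:`ImageMeta`.

    Both files must decode to 2-D single-channel grayscale of equal size.
    Integer data are scaled by the dtype maximum so an 8-bit full-range image
    maps exactly onto [0, 1].
    """
    nuc = _load_gray(nuclear_path)
    foc = _load_gray(foci_path)
    if nuc.shape != foc.shape:
        raise DimensionError(
            f"channel dimensions differ: nuclear {nuc.shape} vs foci {foc.shape}"
        )
    meta = ImageMeta(width_px=nuc.shape[1], height_px=nuc.shape[0], pixel_size_um=pixel_size_um)
    return (
        ChannelImage(pixels=nuc, meta=meta, channel_role=ChannelRole.NUCLEAR),
        ChannelImage(pixels=foc, meta=meta, channel_role=ChannelRole.FOCI),
    )


def rescale_to_pixel_size(img: ChannelImage, target_pixel_size_um: float) -> ChannelImage:
    """Resample ``img`` so that one pixel covers ``target_pixel_size_um`` μm.

    Output dimensions are ``round(dim * pixel_size / target)``; interpolation
    is bilinear with anti-aliasing applied when downscaling. An identical
    target pixel size is a no-op.
    """
    if not (target_pixel_size_um > 0):
        raise ValueError("target pixel size must be positive")
    src = img.meta.pixel_size_um
    if np.isclose(src, target_pixel_size_um, rtol=1e-12, atol=0.0):
        return img
    factor = src / target_pixel_size_um
    new_h = max(1, int(round(img.meta.height_px * factor)))
    new_w = max(1, int(round(img.meta.width_px * factor)))
    out = resize(
        img.pixels,
        (new_h, new_w),
        order=1,
        mode="reflect",
        anti_aliasing=factor < 1.0,
        preserve_range=True,
    )
    meta = ImageMeta(width_px=new_w, height_px=new_h, pixel_size_um=target_pixel_size_um)
    return ChannelImage(
        pixels=np.clip(out, 0.0, None), meta=meta, channel_role=img.channel_role
    )


def write_report(rows: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write a metric table to CSV; full float precision, round-trip safe."""
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if rows.empty:
        raise ValueError("report table is empty")
    rows.to_csv(path, index=False)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Persist a mask as 8-bit (boolean) or 16-bit (labels) TIFF/PNG."""
    px = mask.pixels
    if px.dtype == bool:
        out = (px.astype(np.uint8)) * 255
    else:
        if px.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("too many labels for 16-bit storage")
        out = px.astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_label_mask(path: str | Path, pixel_size_um: float, as_binary: bool = False) -> LabelMask:
    path = Path(path)
    arr = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be 2-D")
    pixels = arr > 0 if as_binary else arr.astype(np.int32)
    meta = ImageMeta(width_px=arr.shape[1], height_px=arr.shape[0], pixel_size_um=pixel_size_um)
    return LabelMask(pixels=pixels, meta=meta)


def write_centers(centers: Sequence[tuple[float, float]], path: str | Path) -> None:
    """Write center coordinates as JSON ``[{"x": col, "y": row}, ...]`` (0-based)."""
    payload = [{"x": float(c), "y": float(r)} for r, c in centers]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_centers(path: str | Path) -> list[tuple[float, float]]:
    """Read a JSON center list back into (row, col) tuples."""
    payload = json.loads(Path(path).read_text())
    return [(float(item["y"]), float(item["x"])) for item in payload]
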