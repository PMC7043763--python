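"""Turn binary foci masks into countable objects.

Connected components smaller than a minimum area (default 16 px, strict
inequality) are removed, then each remaining component is scanned with a
circular Hough transform over a small radius range to locate focus centers,
which splits merged (overlapping) foci. Components yielding no accumulator
peak contribute their centroid as a single center. Splitting is centers-only:
the label grid is left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops
from skimage.transform import hough_circle

from .image_io import ChannelImage, LabelMask

__all__ = ["PostprocessConfig", "FociSet", "size_filter", "detect_centers"]


@dataclass(frozen=True)
class PostprocessConfig:
    min_object_area_px: int = 16
    match_radius_px: float = 5.0
    hough_radii_px: tuple[int, ...] = (3, 4, 5, 6)
    hough_peak_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_object_area_px < 0:
            raise ValueError("min_object_area_px must be >= 0")
        if not self.hough_radii_px:
            raise ValueError("hough_radii_px must be non-empty")
        if list(self.hough_radii_px) != sorted(set(self.hough_radii_px)):
            raise ValueError("hough_radii_px must be increasing")
        if any(r < 1 for r in self.hough_radii_px):
            raise ValueError("hough radii must be positive")
        if not (0 < self.hough_peak_threshold < 1):
            raise ValueError("hough_peak_threshold must be in (0, 1)")
        if not (self.match_radius_px > 0):
            raise ValueError("match_radius_px must be positive")


@dataclass
class FociSet:
    """Labeled foci plus split centers for one image or nucleus."""

    labels: np.ndarray
    centers: list[tuple[float, float]]  # (row, col)
    areas_px: list[int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n_objects = int(self.labels.max(initial=0))
        if len(self.centers) < n_objects:
            raise ValueError("splitting can only add centers, never remove objects")
        for r, c in self.centers:
            rr, cc = int(round(r)), int(round(c))
            if not (0 <= rr < self.labels.shape[0] and 0 <= cc < self.labels.shape[1]):
                raise ValueError("center outside the image frame")

    @property
    def count(self) -> int:
        return len(self.centers)


def size_filter(mask: LabelMask, min_area_px: int = 16) -> LabelMask:
    """Remove connected components strictly smaller than ``min_area_px``.

    A component of exactly ``min_area_px`` pixels is kept. Idempotent.
    """
    binary = mask.binary
    labels, n = ndi.label(binary)
    if n == 0:
        return LabelMask(pixels=binary.copy(), meta=mask.meta)
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    out = keep[labels]
    return LabelMask(pixels=out, meta=mask.meta)


def _component_centers(
    comp: np.ndarray, cfg: PostprocessConfig
) -> list[tuple[float, float]]:
    """Hough-based centers of one cropped component mask; [] if no peak."""
    edges = comp & ~ndi.binary_erosion(comp, border_value=0)
    if not edges.any():
        return []
    radii = np.asarray(cfg.hough_radii_px)
    acc = hough_circle(edges, radii)  # (n_radii, H, W)
    acc2d = acc.max(axis=0)
    peak = float(acc2d.max())
    if peak <= 0:
        return []
    coords = peak_local_max(
        acc2d,
        min_distance=int(radii[0]),
        threshold_abs=cfg.hough_peak_threshold * peak,
        exclude_border=False,
    )
    return [(float(r), float(c)) for r, c in coords if comp[r, c]]


def detect_centers(
    mask: LabelMask,
    foci_img: ChannelImage | None = None,
    cfg: PostprocessConfig | None = None,
) -> FociSet:
    """Locate focus centers in a (size-filtered) binary mask.

    Each connected component is processed on its padded bounding-box crop:
    circular Hough accumulation over ``cfg.hough_radii_px`` on the component
    edge map, peaks above ``hough_peak_threshold`` of the maximum kept after
    non-maximum suppression at the smallest radius. A component with no
    accepted peak contributes its centroid.
    """
    cfg = cfg or PostprocessConfig()
    binary = mask.binary
    labels = cc_label(binary)
    centers: list[tuple[float, float]] = []
    areas: list[int] = []
    for prop in regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        comp = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        comp[prop.image] = True
        found = _component_centers(comp, cfg)
        if not found:
            cr, cc = prop.centroid - np.array([r0, c0])
            if not comp[int(round(cr)), int(round(cc))]:
                # centroid of a non-convex component may fall off the object;
                # snap to the nearest component pixel
                rows, cols = np.nonzero(comp)
                j = int(np.argmin((rows - cr) ** 2 + (cols - cc) ** 2))
                cr, cc = float(rows[j]), float(cols[j])
            found = [(cr, cc)]
        for r, c in found:
            centers.append((r + r0, c + c0))
        areas.append(int(prop.area))
    return FociSet(labels=labels, centers=centers, areas_px=areas)
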