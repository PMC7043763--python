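"""Nucleus detection in the nuclear (counterstain) channel.

Pipeline: median filter -> CLAHE -> Otsu binarization -> hole filling ->
distance-transform-seeded watershed to split touching nuclei -> labeled
regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label, regionprops

from .image_io import ChannelImage, ImageMeta, LabelMask

__all__ = [
    "NucleusROI",
    "SegmentationConfig",
    "DegenerateImageError",
    "otsu_threshold",
    "segment_nuclei",
    "rois_to_label_mask",
]


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity variation to threshold."""


@dataclass(frozen=True)
class SegmentationConfig:
    median_radius_px: int = 3
    clahe_clip: float = 0.01
    clahe_tile_px: int = 128
    min_nucleus_area_px: int = 500
    watershed_min_peak_distance_px: int = 20
    keep_border_objects: bool = True

    def __post_init__(self) -> None:
        if self.median_radius_px < 1:
            raise ValueError("median_radius_px must be >= 1")
        if not (0 < self.clahe_clip <= 1):
            raise ValueError("clahe_clip must be in (0, 1]")
        if self.clahe_tile_px < 1:
            raise ValueError("clahe_tile_px must be positive")
        if self.min_nucleus_area_px < 0:
            raise ValueError("min_nucleus_area_px must be >= 0")


@dataclass
class NucleusROI:
    """One segmented nucleus in the full-image frame."""

    label_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    area_px: int

    def __post_init__(self) -> None:
        if self.label_id < 1:
            raise ValueError("label_id must be positive")
        self.mask = np.asarray(self.mask, dtype=bool)
        area = int(self.mask.sum())
        if area == 0:
            raise ValueError("ROI mask must contain at least one pixel")
        if area != self.area_px:
            raise ValueError("area_px does not match mask")
        rows, cols = np.nonzero(self.mask)
        tight = (rows.min(), cols.min(), rows.max() + 1, cols.max() + 1)
        if tuple(self.bbox) != tuple(int(v) for v in tight):
            raise ValueError("bbox does not tightly bound the mask")


def otsu_threshold(img: ChannelImage) -> float:
    """Between-class-variance-maximizing threshold of the intensity histogram.

    The image must contain at least two distinct intensity values; the
    returned threshold lies strictly between the minimum and maximum.
    """
    px = img.pixels
    if px.size == 0 or px.min() == px.max():
        raise DegenerateImageError("cannot threshold a constant image")
    return float(filters.threshold_otsu(px, nbins=256))


def _preprocess(nuclear: ChannelImage, cfg: SegmentationConfig) -> np.ndarray:
    px = np.clip(nuclear.pixels, 0.0, 1.0)
    footprint = morphology.disk(cfg.median_radius_px)
    img8 = np.rint(px * 255.0).astype(np.uint8)
    med = filters.median(img8, footprint=footprint).astype(np.float64) / 255.0
    tile = min(cfg.clahe_tile_px, med.shape[0], med.shape[1])
    return exposure.equalize_adapthist(med, kernel_size=tile, clip_limit=cfg.clahe_clip)


def segment_nuclei(
    nuclear: ChannelImage, cfg: SegmentationConfig | None = None
) -> list[NucleusROI]:
    """Detect and separate individual nuclei; returns pairwise-disjoint ROIs.

    A blank (constant) image yields an empty list rather than an error.
    """
    cfg = cfg or SegmentationConfig()
    if nuclear.pixels.min() == nuclear.pixels.max():
        return []
    enhanced = _preprocess(nuclear, cfg)
    try:
        thr = filters.threshold_otsu(enhanced, nbins=256)
    except ValueError:
        return []
    binary = enhanced > thr
    binary = ndi.binary_fill_holes(binary)
    if cfg.min_nucleus_area_px > 1:
        # max_size removes objects of area <= value, so strict-minority cut is area-1
        binary = morphology.remove_small_objects(binary, max_size=cfg.min_nucleus_area_px - 1)
    if not binary.any():
        return []

    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=cfg.watershed_min_peak_distance_px,
        labels=binary,
        exclude_border=False,
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(binary)
    else:
        labels = segmentation.watershed(-distance, markers, mask=binary)
        # watershed can orphan mask pixels unreachable from any marker
        orphan = binary & (labels == 0)
        if orphan.any():
            extra = cc_label(orphan)
            extra[extra > 0] += labels.max()
            labels = labels + extra

    rois: list[NucleusROI] = []
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < cfg.min_nucleus_area_px:
            continue
        if not cfg.keep_border_objects:
            r0, c0, r1, c1 = prop.bbox
            if r0 == 0 or c0 == 0 or r1 == labels.shape[0] or c1 == labels.shape[1]:
                continue
        mask = np.zeros(labels.shape, dtype=bool)
        mask[labels == prop.label] = True
        rois.append(
            NucleusROI(
                label_id=next_id,
                mask=mask,
                bbox=tuple(int(v) for v in prop.bbox),
                area_px=int(prop.area),
            )
        )
        next_id += 1
    return rois


def rois_to_label_mask(rois: list[NucleusROI], meta: ImageMeta) -> LabelMask:
    """Combine disjoint ROIs into one integer label grid (0 = background)."""
    out = np.zeros((meta.height_px, meta.width_px), dtype=np.int32)
    for roi in rois:
        out[roi.mask] = roi.label_id
    return LabelMask(pixels=out, meta=meta)
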