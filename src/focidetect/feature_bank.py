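"""Multi-scale per-pixel feature space for the foci channel.

The full bank applies 15 sized filters at 11 sizes (165 channels) plus a
Scharr edge channel, one multi-scale vesselness (Frangi) channel, 5 Gabor
magnitude channels and the raw image: 173 channels in total. The reduced
bank keeps 10 sized filters at 3 sizes plus Scharr, Frangi, 3 Gabor
frequencies and the raw image: 36 channels.

"Filter size" means the radius in pixels of a disk footprint for the rank
filters and the half-width of the averaging window for the structure-tensor
anisotropy filter. Rank, percentile, bilateral and entropy filters operate
on a re-quantized 8-bit view of the normalized image (so e.g. the bilateral
window of +/-15 grey levels is meaningful); all other filters operate on the
real-valued image. Every channel is returned on a bounded scale: rank
outputs are divided by 255, entropy by 8 bits, anisotropy is in [0, 1] by
construction, and the differential filters keep their native (finite) range.
Per-channel z-scoring for classification happens downstream with statistics
pooled over the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology
from skimage.filters import rank

from .image_io import ChannelImage, ImageMeta

__all__ = [
    "SIZED_FILTERS_FULL",
    "SIZED_FILTERS_REDUCED",
    "FilterBankConfig",
    "FeatureStack",
    "full_bank_config",
    "reduced_bank_config",
    "apply_bank",
    "anisotropy_filter",
]

SIZED_FILTERS_FULL: tuple[str, ...] = (
    "auto_level",
    "auto_level_percentile",
    "local_hist_eq",
    "gradient",
    "gradient_percentile",
    "maximum",
    "minimum",
    "mean",
    "mean_percentile",
    "bilateral_mean",
    "median",
    "modal",
    "entropy",
    "tophat",
    "anisotropy",
)

# Percentile-pair / bilateral filters dropped from the reduced configuration.
_REMOVED_IN_REDUCED: frozenset[str] = frozenset(
    {"auto_level_percentile", "gradient_percentile", "mean_percentile", "bilateral_mean", "median"}
)

SIZED_FILTERS_REDUCED: tuple[str, ...] = tuple(
    f for f in SIZED_FILTERS_FULL if f not in _REMOVED_IN_REDUCED
)

FULL_SIZES_PX: tuple[int, ...] = (2, 3, 4, 5, 8, 10, 15, 20, 25, 30, 35)
FULL_GABOR_FREQUENCIES: tuple[float, ...] = (0.08, 0.10, 0.13, 0.16, 0.2)
REDUCED_SIZES_PX: tuple[int, ...] = (2, 10, 30)
REDUCED_GABOR_FREQUENCIES: tuple[float, ...] = (0.08, 0.16, 0.2)


@dataclass(frozen=True)
class FilterBankConfig:
    sized_filters: tuple[str, ...] = SIZED_FILTERS_FULL
    sizes_px: tuple[int, ...] = FULL_SIZES_PX
    gabor_frequencies: tuple[float, ...] = FULL_GABOR_FREQUENCIES
    frangi_scale_start: float = 0.0
    frangi_scale_end: float = 5.0
    frangi_scale_step: float = 0.3
    include_scharr: bool = True
    include_raw: bool = True
    footprint: str = "disk"  # or "square"
    gabor_orientation_pooling: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.sized_filters) - set(SIZED_FILTERS_FULL)
        if unknown:
            raise ValueError(f"unknown sized filters: {sorted(unknown)}")
        if any(s < 1 for s in self.sizes_px):
            raise ValueError("filter sizes must be positive")
        if list(self.sizes_px) != sorted(set(self.sizes_px)):
            raise ValueError("sizes_px must be strictly increasing")
        if list(self.gabor_frequencies) != sorted(set(self.gabor_frequencies)):
            raise ValueError("gabor_frequencies must be strictly increasing")
        if any(not (0 < f < 0.5) for f in self.gabor_frequencies):
            raise ValueError("gabor frequencies must lie in (0, 0.5)")
        if not (self.frangi_scale_end > self.frangi_scale_start >= 0):
            raise ValueError("frangi scale range invalid")
        if self.frangi_scale_step <= 0:
            raise ValueError("frangi_scale_step must be positive")
        if self.footprint not in ("disk", "square"):
            raise ValueError("footprint must be 'disk' or 'square'")

    @property
    def n_channels(self) -> int:
        """Closed-form channel count for this configuration."""
        return (
            len(self.sized_filters) * len(self.sizes_px)
            + len(self.gabor_frequencies)
            + int(self.include_scharr)
            + 1  # frangi (single multi-scale channel)
            + int(self.include_raw)
        )

    @property
    def frangi_sigmas(self) -> np.ndarray:
        """Positive scales from start to end at the configured step.

        A zero start is replaced by one step (a zero-scale Hessian is
        undefined).
        """
        start = self.frangi_scale_start if self.frangi_scale_start > 0 else self.frangi_scale_step
        n = int(np.floor((self.frangi_scale_end - start) / self.frangi_scale_step + 1e-9)) + 1
        return start + self.frangi_scale_step * np.arange(n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sized_filters"] = list(self.sized_filters)
        d["sizes_px"] = list(self.sizes_px)
        d["gabor_frequencies"] = list(self.gabor_frequencies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBankConfig":
        d = dict(d)
        for key in ("sized_filters", "sizes_px", "gabor_frequencies"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class FeatureStack:
    """height x width x n_channels grid of finite per-pixel features."""

    values: np.ndarray
    channel_names: list[str]
    meta: ImageMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("FeatureStack expects a 3-D array")
        if self.values.shape[2] != len(self.channel_names):
            raise ValueError("channel_names length must equal n_channels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def as_matrix(self) -> np.ndarray:
        """Flatten to (n_pixels, n_channels), row-major pixel order."""
        h, w, c = self.values.shape
        return self.values.reshape(h * w, c)


def full_bank_config() -> FilterBankConfig:
    """All 15 sized filters at 11 sizes + Scharr + Frangi + 5 Gabor + raw = 173."""
    return FilterBankConfig()


def reduced_bank_config() -> FilterBankConfig:
    """10 sized filters at sizes [2, 10, 30] + Scharr + Frangi + 3 Gabor + raw = 36."""
    return FilterBankConfig(
        sized_filters=SIZED_FILTERS_REDUCED,
        sizes_px=REDUCED_SIZES_PX,
        gabor_frequencies=REDUCED_GABOR_FREQUENCIES,
    )


def _footprint(size: int, shape: str) -> np.ndarray:
    if shape == "disk":
        return morphology.disk(size)
    return np.ones((2 * size + 1, 2 * size + 1), dtype=np.uint8)


def anisotropy_filter(foci: ChannelImage | np.ndarray, size_px: int) -> np.ndarray:
    """Local structure-tensor anisotropy, per pixel, in [0, 1].

    The image gradient (Sobel) outer products are averaged over a
    (2*size+1)^2 window; with eigenvalues lam1 >= lam2 >= 0 of the averaged
    tensor, the score is 1 - lam2/lam1 (0 where lam1 vanishes). Isotropic
    blobs score near 0, line-like structures near 1.
    """
    if size_px < 2:
        raise ValueError("anisotropy filter size must be >= 2")
    img = foci.pixels if isinstance(foci, ChannelImage) else np.asarray(foci, dtype=np.float64)
    gr = ndi.sobel(img, axis=0, mode="reflect")
    gc = ndi.sobel(img, axis=1, mode="reflect")
    win = 2 * size_px + 1
    jrr = ndi.uniform_filter(gr * gr, size=win, mode="reflect")
    jcc = ndi.uniform_filter(gc * gc, size=win, mode="reflect")
    jrc = ndi.uniform_filter(gr * gc, size=win, mode="reflect")
    trace = jrr + jcc
    disc = np.sqrt(np.maximum((jrr - jcc) ** 2 + 4.0 * jrc**2, 0.0))
    lam1 = 0.5 * (trace + disc)
    lam2 = 0.5 * (trace - disc)
    out = np.zeros_like(img, dtype=np.float64)
    nz = lam1 > 1e-12 * max(1.0, float(trace.max(initial=0.0)))
    out[nz] = 1.0 - np.clip(lam2[nz] / lam1[nz], 0.0, 1.0)
    return out


def _sized_channel(name: str, img: np.ndarray, img8: np.ndarray, fp: np.ndarray, size: int) -> np.ndarray:
    if name == "auto_level":
        return rank.autolevel(img8, footprint=fp) / 255.0
    if name == "auto_level_percentile":
        return rank.autolevel_percentile(img8, footprint=fp, p0=0.2, p1=0.9) / 255.0
    if name == "local_hist_eq":
        return rank.equalize(img8, footprint=fp) / 255.0
    if name == "gradient":
        return rank.gradient(img8, footprint=fp) / 255.0
    if name == "gradient_percentile":
        return rank.gradient_percentile(img8, footprint=fp, p0=0.1, p1=0.9) / 255.0
    if name == "maximum":
        return rank.maximum(img8, footprint=fp) / 255.0
    if name == "minimum":
        return rank.minimum(img8, footprint=fp) / 255.0
    if name == "mean":
        return rank.mean(img8, footprint=fp) / 255.0
    if name == "mean_percentile":
        return rank.mean_percentile(img8, footprint=fp, p0=0.2, p1=0.8) / 255.0
    if name == "bilateral_mean":
        return rank.mean_bilateral(img8, footprint=fp, s0=15, s1=15) / 255.0
    if name == "median":
        return rank.median(img8, footprint=fp) / 255.0
    if name == "modal":
        return rank.modal(img8, footprint=fp) / 255.0
    if name == "entropy":
        return rank.entropy(img8, footprint=fp) / 8.0
    if name == "tophat":
        return morphology.white_tophat(img, footprint=fp)
    if name == "anisotropy":
        return anisotropy_filter(img, size)
    raise ValueError(f"unknown sized filter {name!r}")


def _gabor_channel(img: np.ndarray, frequency: float, pool_orientations: bool) -> np.ndarray:
    thetas = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4) if pool_orientations else (0.0,)
    best = None
    for theta in thetas:
        real, imag = filters.gabor(img, frequency=frequency, theta=theta)
        mag = np.hypot(real, imag)
        best = mag if best is None else np.maximum(best, mag)
    return best


def apply_bank(foci: ChannelImage, cfg: FilterBankConfig | None = None) -> FeatureStack:
    """Compute the per-pixel feature stack of the foci channel.

    Channel order: sized filters (filter-major, size-minor), then Scharr,
    Frangi, Gabor frequencies, and the raw image last. Deterministic and
    bit-reproducible for a given input.
    """
    cfg = cfg or full_bank_config()
    img = np.clip(foci.pixels, 0.0, 1.0)
    h, w = img.shape
    max_size = max(cfg.sizes_px) if cfg.sizes_px else 1
    if min(h, w) < 2 * max_size + 1:
        raise ValueError(
            f"image {h}x{w} smaller than the largest filter window ({2 * max_size + 1} px)"
        )
    img8 = np.rint(img * 255.0).astype(np.uint8)

    channels: list[np.ndarray] = []
    names: list[str] = []
    for name in cfg.sized_filters:
        for size in cfg.sizes_px:
            fp = _footprint(size, cfg.footprint)
            channels.append(_sized_channel(name, img, img8, fp, size))
            names.append(f"{name}_s{size}")
    if cfg.include_scharr:
        channels.append(filters.scharr(img))
        names.append("scharr")
    channels.append(
        filters.frangi(img, sigmas=cfg.frangi_sigmas, black_ridges=False)
    )
    names.append("frangi")
    for freq in cfg.gabor_frequencies:
        channels.append(_gabor_channel(img, freq, cfg.gabor_orientation_pooling))
        names.append(f"gabor_f{freq:g}")
    if cfg.include_raw:
        channels.append(img)
        names.append("raw")

    stack = np.stack(channels, axis=-1).astype(np.float64)
    stack[~np.isfinite(stack)] = 0.0  # frangi can emit NaN on flat regions
    return FeatureStack(values=stack, channel_names=names, meta=foci.meta)
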