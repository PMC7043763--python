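"""Detection scoring: pixel-wise and object-wise confusion tallies, derived
metrics (sensitivity, PPV, FNR, F1, MCC), bootstrap confidence intervals over
per-nucleus tallies and CI-overlap significance calls.

Object-wise evaluation matches automatic and manual focus centers one-to-one
within a fixed radius (default 5 px): candidate pairs are matched greedily by
ascending Euclidean distance, ties broken by lexicographic (row, col) order.
Matched pairs are true positives, unmatched automatic centers false
positives, unmatched manual centers false negatives; there are no true
negatives on the object level, so MCC is pixel-wise only.

Metrics with a zero denominator are reported as NaN (flagged), never as a
silent zero. Display rounding is 3 decimals, round-half-even; internal
values keep full precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .image_io import LabelMask
from .nucleus_segmentation import NucleusROI

__all__ = [
    "DetectionTally",
    "MetricReport",
    "BootstrapConfig",
    "pixel_tally",
    "match_centers",
    "compute_metrics",
    "bootstrap_ci",
    "ci_significance",
    "pool_tallies",
    "METRIC_NAMES",
]

METRIC_NAMES = ("sensitivity", "ppv", "fnr", "f1", "mcc")


@dataclass(frozen=True)
class DetectionTally:
    tp: int
    fp: int
    fn: int
    tn: int | None = None  # absent for object-wise tallies

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative")

    def __add__(self, other: "DetectionTally") -> "DetectionTally":
        if (self.tn is None) != (other.tn is None):
            raise ValueError("cannot pool pixel-wise and object-wise tallies")
        tn = None if self.tn is None else self.tn + other.tn
        return DetectionTally(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, tn)


@dataclass
class MetricReport:
    sensitivity: float
    ppv: float
    fnr: float
    f1: float
    mcc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def rounded(self, decimals: int = 3) -> dict[str, float]:
        """Display values: round-half-even at ``decimals`` places."""
        out = {}
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            q = 10**decimals
            out[name] = round(v * q) / q  # Python round is banker's rounding
        return out


@dataclass(frozen=True)
class BootstrapConfig:
    n_reps: int = 1000
    ci_level: float = 0.95
    method: str = "percentile"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.method not in ("percentile", "basic"):
            raise ValueError("method must be 'percentile' or 'basic'")


def pool_tallies(tallies: Iterable[DetectionTally]) -> DetectionTally:
    tallies = list(tallies)
    if not tallies:
        raise ValueError("no tallies to pool")
    pooled = tallies[0]
    for t in tallies[1:]:
        pooled = pooled + t
    return pooled


def pixel_tally(
    pred: LabelMask, truth: LabelMask, roi: NucleusROI | None = None
) -> DetectionTally:
    """Per-pixel confusion counts, optionally restricted to one nucleus ROI."""
    p = pred.binary
    t = truth.binary
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    if roi is not None:
        if roi.mask.shape != p.shape:
            raise ValueError("ROI mask shape differs from prediction")
        sel = roi.mask
        p, t = p[sel], t[sel]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return DetectionTally(tp=tp, fp=fp, fn=fn, tn=tn)


def match_centers(
    auto: Sequence[tuple[float, float]],
    manual: Sequence[tuple[float, float]],
    radius_px: float = 5.0,
) -> DetectionTally:
    """One-to-one center matching within ``radius_px`` (inclusive).

    Greedy nearest-first: all candidate pairs at distance <= radius are
    sorted by (distance, auto index, manual index) and matched in order,
    skipping already-matched points. No true negatives on the object level.
    """
    if not (radius_px > 0):
        raise ValueError("radius must be positive")
    auto = [(float(r), float(c)) for r, c in auto]
    manual = [(float(r), float(c)) for r, c in manual]
    if any(not (math.isfinite(r) and math.isfinite(c)) for r, c in auto + manual):
        raise ValueError("center coordinates must be finite")

    # deterministic processing order: lexicographic (row, col)
    a_order = sorted(range(len(auto)), key=lambda i: auto[i])
    m_order = sorted(range(len(manual)), key=lambda j: manual[j])
    pairs = []
    for ai, i in enumerate(a_order):
        for mj, j in enumerate(m_order):
            d = math.dist(auto[i], manual[j])
            if d <= radius_px:
                pairs.append((d, ai, mj))
    pairs.sort()
    a_used = [False] * len(auto)
    m_used = [False] * len(manual)
    tp = 0
    for _, ai, mj in pairs:
        i, j = a_order[ai], m_order[mj]
        if a_used[i] or m_used[j]:
            continue
        a_used[i] = m_used[j] = True
        tp += 1
    return DetectionTally(tp=tp, fp=len(auto) - tp, fn=len(manual) - tp, tn=None)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def compute_metrics(tally: DetectionTally) -> MetricReport:
    """Sensitivity, PPV, FNR, F1 and (when TN is present) MCC from a tally."""
    tp, fp, fn = tally.tp, tally.fp, tally.fn
    sens = _safe_div(tp, tp + fn)
    ppv = _safe_div(tp, tp + fp)
    fnr = _safe_div(fn, tp + fn)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    mcc = None
    if tally.tn is not None:
        tn = tally.tn
        den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if den2 == 0:
            mcc = float("nan")
        else:
            # exact integer arithmetic in the numerator avoids overflow/rounding
            mcc = float(tp * tn - fp * fn) / math.sqrt(float(den2))
    if all(math.isnan(v) for v in (sens, ppv, fnr, f1)):
        warnings.warn("all-zero tally: every metric is undefined", stacklevel=2)
    return MetricReport(sensitivity=sens, ppv=ppv, fnr=fnr, f1=f1, mcc=mcc)


def _metric_value(tally: DetectionTally, metric: str) -> float:
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    value = getattr(compute_metrics(tally), metric)
    if value is None:
        raise ValueError(f"metric {metric!r} undefined for this tally (no TN counts)")
    return value


def bootstrap_ci(
    per_nucleus_tallies: Sequence[DetectionTally],
    metric: str,
    cfg: BootstrapConfig | None = None,
) -> tuple[float, float, float]:
    """(point, ci_low, ci_high): metric on the pooled tally plus a bootstrap CI.

    Nuclei are resampled with replacement ``cfg.n_reps`` times; the metric is
    recomputed on each resample's pooled tally. ``percentile`` uses the
    empirical quantiles of the resample distribution; ``basic`` reflects them
    around the point estimate. Resamples where the metric is undefined are
    dropped (with a warning if they exceed 20%).
    """
    cfg = cfg or BootstrapConfig()
    tallies = list(per_nucleus_tallies)
    if not tallies:
        raise ValueError("need at least one nucleus tally")
    point = _metric_value(pool_tallies(tallies), metric)

    rng = np.random.default_rng(cfg.seed)
    n = len(tallies)
    values = np.empty(cfg.n_reps, dtype=np.float64)
    for rep in range(cfg.n_reps):
        idx = rng.integers(0, n, size=n)
        values[rep] = _metric_value(pool_tallies(tallies[i] for i in idx), metric)
    defined = values[np.isfinite(values)]
    if defined.size == 0:
        raise ValueError("metric undefined on every bootstrap resample")
    if defined.size < 0.8 * cfg.n_reps:
        warnings.warn(
            f"metric undefined on {cfg.n_reps - defined.size}/{cfg.n_reps} resamples",
            stacklevel=2,
        )
    alpha = 1.0 - cfg.ci_level
    lo_q, hi_q = np.quantile(defined, [alpha / 2, 1 - alpha / 2])
    if cfg.method == "percentile":
        return point, float(lo_q), float(hi_q)
    return point, 2 * point - float(hi_q), 2 * point - float(lo_q)


def ci_significance(a: MetricReport, b: MetricReport, metric: str) -> bool:
    """True iff the two confidence intervals for ``metric`` are disjoint."""
    if metric not in a.ci or metric not in b.ci:
        raise ValueError(f"both reports need a CI for {metric!r}")
    a_lo, a_hi = a.ci[metric]
    b_lo, b_hi = b.ci[metric]
    return a_hi < b_lo or b_hi < a_lo
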