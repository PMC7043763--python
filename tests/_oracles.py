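"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive loops, closed forms) and
shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def otsu_bruteforce(values: np.ndarray, nbins: int = 256):
    """Exhaustive between-class-variance maximization over histogram bins.

    Returns (threshold, left_mask) where left_mask marks values <= threshold.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, nbins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_thr = -1.0, centers[0]
    total = counts.sum()
    for t in range(1, nbins):
        w0 = counts[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:t] * centers[:t]).sum() / w0
        mu1 = (counts[t:] * centers[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[t - 1]
    return best_thr, values <= best_thr


def quantize_to_bins(values: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Replace each value by its histogram bin center (Otsu's working grid)."""
    values = np.asarray(values, dtype=np.float64)
    edges = np.linspace(values.min(), values.max(), nbins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    idx = np.clip(np.digitize(values, edges[1:-1]), 0, nbins - 1)
    return centers[idx]


def between_class_variance(values: np.ndarray, left: np.ndarray) -> float:
    """w0*w1*(mu0-mu1)^2 of a binary split of the raw values."""
    values = np.asarray(values, dtype=np.float64).ravel()
    left = np.asarray(left, dtype=bool).ravel()
    w0, w1 = left.sum(), (~left).sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    return float(w0 * w1 * (values[left].mean() - values[~left].mean()) ** 2)


def sliding_window_max(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Per-pixel max over a centered footprint, explicit loops, reflect-free
    (out-of-bounds neighbours ignored)."""
    h, w = img.shape
    fh, fw = footprint.shape
    cr, cc = fh // 2, fw // 2
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            best = -np.inf
            for dr in range(fh):
                for dc in range(fw):
                    if not footprint[dr, dc]:
                        continue
                    rr, cc2 = r + dr - cr, c + dc - cc
                    if 0 <= rr < h and 0 <= cc2 < w:
                        best = max(best, img[rr, cc2])
            out[r, c] = best
    return out


def window_anisotropy(gr: np.ndarray, gc: np.ndarray, size: int) -> np.ndarray:
    """1 - lam2/lam1 of the windowed structure tensor, explicit per-pixel loop.

    Consumes precomputed gradient fields so it checks only the windowing and
    eigenvalue algebra. Window is the (2*size+1)^2 square clipped at borders,
    mean-normalized like a uniform filter with reflect padding would be only
    in the interior -- callers should compare interior pixels.
    """
    h, w = gr.shape
    out = np.zeros((h, w))
    for r in range(size, h - size):
        for c in range(size, w - size):
            a = gr[r - size : r + size + 1, c - size : c + size + 1]
            b = gc[r - size : r + size + 1, c - size : c + size + 1]
            jrr = np.mean(a * a)
            jcc = np.mean(b * b)
            jrc = np.mean(a * b)
            tr = jrr + jcc
            disc = math.sqrt(max((jrr - jcc) ** 2 + 4 * jrc**2, 0.0))
            lam1 = (tr + disc) / 2
            lam2 = (tr - disc) / 2
            if lam1 > 1e-12:
                out[r, c] = 1.0 - lam2 / lam1
    return out


def pca_eigh(X: np.ndarray):
    """Covariance eigendecomposition oracle: (ratios_desc, components_desc)."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    return vals / vals.sum(), vecs.T


def max_matching_count(auto, manual, radius: float) -> int:
    """Optimal one-to-one match count within radius, exhaustive enumeration."""
    na, nm = len(auto), len(manual)
    feasible = [
        [math.dist(a, m) <= radius for m in manual] for a in auto
    ]
    best = 0
    small, large, swap = (range(na), range(nm), False) if na <= nm else (range(nm), range(na), True)
    k = len(list(small))
    for perm in itertools.permutations(large, k):
        count = 0
        for i, j in zip(small, perm):
            ok = feasible[j][i] if swap else feasible[i][j]
            if ok:
                count += 1
        best = max(best, count)
    return best


def pixel_confusion_loop(pred: np.ndarray, truth: np.ndarray):
    """(tp, fp, fn, tn) by an explicit per-pixel loop."""
    tp = fp = fn = tn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            p, t = bool(pred[r, c]), bool(truth[r, c])
            if p and t:
                tp += 1
            elif p:
                fp += 1
            elif t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def enumerate_bootstrap_metrics(tallies, metric_fn):
    """Pooled metric of every ordered resample of n tallies (n^n outcomes)."""
    n = len(tallies)
    out = []
    for idx in itertools.product(range(n), repeat=n):
        tp = sum(tallies[i][0] for i in idx)
        fp = sum(tallies[i][1] for i in idx)
        fn = sum(tallies[i][2] for i in idx)
        out.append(metric_fn(tp, fp, fn))
    return out
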