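"""PCA projection keeping components up to a cumulative-variance threshold."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .feature_bank import FeatureStack

__all__ = ["PCAProjection", "fit_pca", "project"]


@dataclass
class PCAProjection:
    """Affine projection x -> (x - mean) @ components.T.

    ``components`` rows are orthonormal principal axes over the input
    channels; columns corresponding to channels dropped as constant during
    fitting are identically zero. ``explained_variance_ratio`` is descending
    and its cumulative sum first reaches ``variance_threshold`` at the last
    kept component.
    """

    mean_vector: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    variance_threshold: float = 0.95
    dropped_channels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=np.float64)
        self.components = np.asarray(self.components, dtype=np.float64)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=np.float64
        )
        if self.components.ndim != 2:
            raise ValueError("components must be 2-D (n_kept x n_channels)")
        if self.components.shape[1] != self.mean_vector.shape[0]:
            raise ValueError("components width must match mean_vector length")
        if self.components.shape[0] != self.explained_variance_ratio.shape[0]:
            raise ValueError("one variance ratio per kept component required")

    @property
    def n_channels(self) -> int:
        return self.mean_vector.shape[0]

    @property
    def n_kept(self) -> int:
        return self.components.shape[0]

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.shape[-1] != self.n_channels:
            raise ValueError(
                f"feature width {features.shape[-1]} != projection input {self.n_channels}"
            )
        return (features - self.mean_vector) @ self.components.T


def fit_pca(training_features: np.ndarray, variance_threshold: float = 0.95) -> PCAProjection:
    """Fit the smallest PCA reaching ``variance_threshold`` cumulative EVR.

    Constant (zero-variance) channels are dropped with a warning before the
    eigendecomposition; their coefficients are zero in the returned
    components so the projection still accepts full-width feature vectors.
    Component signs are fixed so each row's largest-magnitude coefficient is
    positive.
    """
    X = np.asarray(training_features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("training features must be a 2-D matrix")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more pixels ({n}) than channels ({p}) to fit PCA")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")
    if not (0 < variance_threshold <= 1):
        raise ValueError("variance_threshold must be in (0, 1]")

    mean = X.mean(axis=0)
    var = X.var(axis=0)
    keep = var > 1e-12
    dropped = tuple(int(i) for i in np.nonzero(~keep)[0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant feature channel(s) before PCA: {dropped}",
            stacklevel=2,
        )
    Xk = X[:, keep] - mean[keep]
    cov = (Xk.T @ Xk) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    total = eigval.sum()
    if total <= 0:
        raise ValueError("training features have zero total variance")
    ratios = eigval / total
    cum = np.cumsum(ratios)
    n_kept = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_kept = min(n_kept, len(ratios))

    comps = np.zeros((n_kept, p), dtype=np.float64)
    comps[:, keep] = eigvec[:, :n_kept].T
    # sign convention: largest-|coefficient| entry positive per component
    for row in comps:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return PCAProjection(
        mean_vector=mean,
        components=comps,
        explained_variance_ratio=ratios[:n_kept],
        variance_threshold=variance_threshold,
        dropped_channels=dropped,
    )


def project(stack: FeatureStack, pca: PCAProjection) -> FeatureStack:
    """Project a feature stack onto the kept principal components."""
    if stack.n_channels != pca.n_channels:
        raise ValueError(
            f"stack has {stack.n_channels} channels, projection expects {pca.n_channels}"
        )
    h, w, _ = stack.values.shape
    out = pca.transform(stack.as_matrix()).reshape(h, w, pca.n_kept)
    names = [f"pc{i + 1}" for i in range(pca.n_kept)]
    return FeatureStack(values=out, channel_names=names, meta=stack.meta)
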