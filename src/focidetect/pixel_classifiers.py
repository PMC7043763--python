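"""Pixel classifiers (MLP, linear SVM, complement naive Bayes, random forest),
their boosted/bagged wrappers and voting ensembles.

The SVM is a bagging ensemble (10 estimators) of AdaBoost-ed (15 estimators)
linear SVMs; RF and cNB are AdaBoost-ed; the MLP is used plain. Any
non-empty subset of the fitted base models can be combined by soft
(mean-probability) or hard (strict-majority, ties negative) voting without
retraining.

A trained model bundles everything needed to go from a raw foci channel to a
binary mask: the filter-bank configuration, pooled z-score statistics, the
PCA projection and the fitted estimators. Complement naive Bayes requires
non-negative count-like inputs, so it consumes a min-max rescaled copy of
the projected features with each column's complement (1 - x) appended:
without the dual columns the classifier sees only feature proportions and is
blind to overall magnitude. The scaler is stored with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.naive_bayes import ComplementNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import LinearSVC

from .dimensionality import PCAProjection, fit_pca, project
from .feature_bank import FeatureStack, FilterBankConfig, apply_bank
from .image_io import ChannelImage, LabelMask
from .nucleus_segmentation import NucleusROI

__all__ = [
    "BASE_MODEL_NAMES",
    "ClassifierSpec",
    "LabeledPixelSet",
    "TrainedPixelModel",
    "TrainingError",
    "train",
    "vote",
    "predict_mask",
    "fit_pixel_pipeline",
    "all_vote_combinations",
    "save_model",
    "load_model",
]

BASE_MODEL_NAMES: tuple[str, ...] = ("MLP", "SVM", "cNB", "RF")


class TrainingError(ValueError):
    """Raised when the training data cannot support fitting."""


@dataclass(frozen=True)
class ClassifierSpec:
    base_models: tuple[str, ...] = BASE_MODEL_NAMES
    adaboost_estimators: int = 15
    bagging_estimators: int = 10
    voting_rule: str = "soft"
    seed: int = 0
    # architecture/size knobs (library defaults unless stated otherwise)
    mlp_hidden_units: int = 100
    mlp_max_iter: int = 200
    rf_trees: int = 100

    def __post_init__(self) -> None:
        if not self.base_models:
            raise ValueError("base_models must be non-empty")
        unknown = set(self.base_models) - set(BASE_MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown base models: {sorted(unknown)}")
        if self.voting_rule not in ("soft", "hard"):
            raise ValueError("voting_rule must be 'soft' or 'hard'")
        if self.adaboost_estimators < 1 or self.bagging_estimators < 1:
            raise ValueError("ensemble sizes must be positive")


@dataclass
class LabeledPixelSet:
    """Per-pixel feature matrix plus boolean labels (True = focus pixel)."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (n_pixels x n_features)")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels length must match feature rows")


@dataclass
class ZScoreStats:
    mean: np.ndarray
    std: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


@dataclass
class TrainedPixelModel:
    spec: ClassifierSpec
    fitted_components: dict
    training_pixel_count: int
    pca: PCAProjection | None = None
    bank_config: FilterBankConfig | None = None
    zscore: ZScoreStats | None = None
    cnb_scaler: MinMaxScaler | None = None

    def __post_init__(self) -> None:
        if self.bank_config is not None and self.pca is not None:
            if self.bank_config.n_channels != self.pca.n_channels:
                raise ValueError("bank channel count does not match PCA input width")


def _mlp(spec: ClassifierSpec) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(spec.mlp_hidden_units,),
        activation="relu",
        solver="adam",
        max_iter=spec.mlp_max_iter,
        random_state=spec.seed,
    )


def _svm(spec: ClassifierSpec) -> BaggingClassifier:
    boosted = AdaBoostClassifier(
        estimator=LinearSVC(),
        n_estimators=spec.adaboost_estimators,
        random_state=spec.seed,
    )
    return BaggingClassifier(
        estimator=boosted,
        n_estimators=spec.bagging_estimators,
        random_state=spec.seed,
        n_jobs=1,
    )


def _cnb(spec: ClassifierSpec) -> AdaBoostClassifier:
    return AdaBoostClassifier(
        estimator=ComplementNB(),
        n_estimators=spec.adaboost_estimators,
        random_state=spec.seed,
    )


def _rf(spec: ClassifierSpec) -> AdaBoostClassifier:
    forest = RandomForestClassifier(
        n_estimators=spec.rf_trees, random_state=spec.seed, n_jobs=1
    )
    return AdaBoostClassifier(
        estimator=forest,
        n_estimators=spec.adaboost_estimators,
        random_state=spec.seed,
    )


_BUILDERS = {"MLP": _mlp, "SVM": _svm, "cNB": _cnb, "RF": _rf}


def _cnb_encode(scaler: MinMaxScaler, X: np.ndarray) -> np.ndarray:
    """Non-negative dual encoding for complement naive Bayes: [x, 1 - x]."""
    Xs = np.clip(scaler.transform(X), 0.0, 1.0)
    return np.hstack([Xs, 1.0 - Xs])


def train(
    spec: ClassifierSpec,
    data: LabeledPixelSet,
    *,
    pca: PCAProjection | None = None,
    bank_config: FilterBankConfig | None = None,
    zscore: ZScoreStats | None = None,
) -> TrainedPixelModel:
    """Fit every base model requested by ``spec`` on the labeled pixel set.

    Deterministic for a fixed seed. ``pca``/``bank_config``/``zscore`` attach
    the preprocessing used to produce ``data.features`` so the model can be
    applied to raw images later.
    """
    if not np.all(np.isfinite(data.features)):
        raise ValueError("features must be finite")
    n_pos = int(data.labels.sum())
    if n_pos == 0 or n_pos == data.labels.size:
        raise TrainingError("training data must contain both classes")

    y = data.labels.astype(np.int64)
    fitted: dict = {}
    cnb_scaler: MinMaxScaler | None = None
    for name in spec.base_models:
        est = _BUILDERS[name](spec)
        if name == "cNB":
            cnb_scaler = MinMaxScaler(feature_range=(0.0, 1.0)).fit(data.features)
            est.fit(_cnb_encode(cnb_scaler, data.features), y)
        else:
            est.fit(data.features, y)
        fitted[name] = est
    return TrainedPixelModel(
        spec=spec,
        fitted_components=fitted,
        training_pixel_count=int(data.labels.size),
        pca=pca,
        bank_config=bank_config,
        zscore=zscore,
        cnb_scaler=cnb_scaler,
    )


def predict_proba_per_model(
    model: TrainedPixelModel,
    features: np.ndarray,
    base_models: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Positive-class probability of each fitted base model on projected features."""
    names = tuple(base_models) if base_models is not None else model.spec.base_models
    out: dict[str, np.ndarray] = {}
    for name in names:
        if name not in model.fitted_components:
            raise KeyError(f"model {name!r} was not trained")
        est = model.fitted_components[name]
        X = features
        if name == "cNB":
            X = _cnb_encode(model.cnb_scaler, features)
        out[name] = est.predict_proba(X)[:, 1]
    return out


def vote(predictions: Sequence[np.ndarray], rule: str = "soft") -> np.ndarray:
    """Combine per-model probability (or label) vectors into one boolean vector.

    soft: mean probability strictly greater than 0.5.
    hard: strict majority of positive labels; ties are negative.
    """
    if len(predictions) == 0:
        raise ValueError("at least one prediction vector is required")
    arrs = [np.asarray(p, dtype=np.float64) for p in predictions]
    length = arrs[0].shape[0]
    if any(a.shape != (length,) for a in arrs):
        raise ValueError("prediction vectors must share one length")
    if rule == "soft":
        return np.mean(arrs, axis=0) > 0.5
    if rule == "hard":
        votes = np.sum([a > 0.5 for a in arrs], axis=0)
        return votes * 2 > len(arrs)
    raise ValueError("rule must be 'soft' or 'hard'")


def _project_image(model: TrainedPixelModel, foci: ChannelImage) -> np.ndarray:
    if model.bank_config is None or model.pca is None or model.zscore is None:
        raise ValueError("model lacks bank/z-score/PCA state; train via fit_pixel_pipeline")
    stack = apply_bank(foci, model.bank_config)
    X = model.zscore.apply(stack.as_matrix())
    return model.pca.transform(X)


def predict_mask(
    model: TrainedPixelModel,
    foci: ChannelImage,
    roi: NucleusROI | None = None,
    base_models: Sequence[str] | None = None,
) -> LabelMask:
    """Apply the full pipeline (bank -> z-score -> PCA -> vote) to one image.

    When ``roi`` is given the returned boolean mask is restricted to it.
    ``base_models`` selects a voting subset of the trained components.
    """
    X = _project_image(model, foci)
    probas = predict_proba_per_model(model, X, base_models)
    flat = vote(list(probas.values()), model.spec.voting_rule)
    mask = flat.reshape(foci.shape)
    if roi is not None:
        mask = mask & roi.mask
    return LabelMask(pixels=mask, meta=foci.meta)


def all_vote_combinations(
    model: TrainedPixelModel, features: np.ndarray
) -> dict[tuple[str, ...], np.ndarray]:
    """Predictions of every non-empty base-model subset from one training pass."""
    from itertools import combinations

    probas = predict_proba_per_model(model, features)
    names = model.spec.base_models
    out: dict[tuple[str, ...], np.ndarray] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            out[combo] = vote([probas[n] for n in combo], model.spec.voting_rule)
    return out


def fit_pixel_pipeline(
    spec: ClassifierSpec,
    foci_images: Sequence[ChannelImage],
    truth_masks: Sequence[LabelMask],
    bank_config: FilterBankConfig,
    *,
    variance_threshold: float = 0.95,
    max_pca_pixels: int = 200_000,
    max_training_pixels: int | None = None,
) -> TrainedPixelModel:
    """Train on whole images: filter bank, pooled z-scoring, PCA, classifiers.

    Pixels of all images are pooled. PCA is fitted on a seeded uniform
    subsample of at most ``max_pca_pixels`` rows; classifier training
    optionally subsamples to ``max_training_pixels`` rows (uniform, so the
    class imbalance of the source images is preserved).
    """
    if len(foci_images) != len(truth_masks) or not foci_images:
        raise ValueError("need matching, non-empty image and mask lists")
    rng = np.random.default_rng(spec.seed)

    mats, labs = [], []
    for img, mask in zip(foci_images, truth_masks):
        if mask.pixels.shape != img.shape:
            raise ValueError("mask/image shape mismatch")
        stack = apply_bank(img, bank_config)
        mats.append(stack.as_matrix())
        labs.append(mask.binary.ravel())
    X = np.vstack(mats)
    y = np.concatenate(labs)
    del mats

    std = X.std(axis=0)
    std[std < 1e-12] = 1.0
    zs = ZScoreStats(mean=X.mean(axis=0), std=std)
    Xz = zs.apply(X)
    del X

    if Xz.shape[0] > max_pca_pixels:
        idx = rng.choice(Xz.shape[0], size=max_pca_pixels, replace=False)
        pca = fit_pca(Xz[idx], variance_threshold)
    else:
        pca = fit_pca(Xz, variance_threshold)
    Xp = pca.transform(Xz)
    del Xz

    if max_training_pixels is not None and Xp.shape[0] > max_training_pixels:
        idx = rng.choice(Xp.shape[0], size=max_training_pixels, replace=False)
        Xp, y = Xp[idx], y[idx]

    return train(
        spec,
        LabeledPixelSet(features=Xp, labels=y),
        pca=pca,
        bank_config=bank_config,
        zscore=zs,
    )


def save_model(model: TrainedPixelModel, path: str | Path) -> None:
    """Persist a trained model bundle (spec, bank config, z-score, PCA, fits)."""
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path: str | Path) -> TrainedPixelModel:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unsupported model bundle version")
    return payload["model"]
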