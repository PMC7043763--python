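from __future__ import annotations

import numpy as np
import pytest

from focidetect.evaluation import compute_metrics, match_centers, pixel_tally
from focidetect.feature_bank import reduced_bank_config
from focidetect.foci_objects import detect_centers, size_filter
from focidetect.image_io import ChannelImage, ImageMeta, LabelMask
from focidetect.pixel_classifiers import ClassifierSpec, fit_pixel_pipeline, predict_mask
from focidetect.synthetic_data import SceneConfig, generate_scene, generate_training_set


def make_image(pixels: np.ndarray, pixel_size_um: float = 0.1172, **kwargs) -> ChannelImage:
    pixels = np.asarray(pixels, dtype=np.float64)
    meta = ImageMeta(width_px=pixels.shape[1], height_px=pixels.shape[0],
                     pixel_size_um=pixel_size_um)
    return ChannelImage(pixels=pixels, meta=meta, **kwargs)


def make_mask(pixels: np.ndarray, pixel_size_um: float = 0.1172) -> LabelMask:
    pixels = np.asarray(pixels)
    meta = ImageMeta(width_px=pixels.shape[1], height_px=pixels.shape[0],
                     pixel_size_um=pixel_size_um)
    return LabelMask(pixels=pixels, meta=meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


class EndToEndRun:
    """One shared training pass: MLP on 8 synthetic scenes, held-out 9th."""

    def __init__(self) -> None:
        scenes = generate_training_set(9, cfg_base=SceneConfig(seed=42))
        self.held_nuclear, self.held_foci, self.held_truth = scenes[0]
        train_scenes = scenes[1:]
        self.spec = ClassifierSpec(
            base_models=("MLP",), seed=0, mlp_hidden_units=50, mlp_max_iter=60
        )
        self.model = fit_pixel_pipeline(
            self.spec,
            [s[1] for s in train_scenes],
            [LabelMask(pixels=s[2].foci_mask, meta=s[1].meta) for s in train_scenes],
            reduced_bank_config(),
            max_training_pixels=150_000,
        )
        self.pred_mask = predict_mask(self.model, self.held_foci)

    def pixel_metrics(self):
        truth = LabelMask(pixels=self.held_truth.foci_mask, meta=self.held_foci.meta)
        return compute_metrics(pixel_tally(self.pred_mask, truth))

    def object_tally(self, min_area: int = 16, radius: float = 5.0):
        filtered = size_filter(self.pred_mask, min_area)
        found = detect_centers(filtered)
        return match_centers(found.centers, self.held_truth.all_centers, radius)


@pytest.fixture(scope="session")
def e2e() -> EndToEndRun:
    """Session-wide end-to-end pipeline run (trains once, ~40 s)."""
    return EndToEndRun()
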