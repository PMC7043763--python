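from __future__ import annotations

import numpy as np
import pytest

from focidetect.evaluation import compute_metrics, pixel_tally
from focidetect.foci_objects import detect_centers
from focidetect.image_io import LabelMask
from focidetect.pixel_classifiers import predict_mask
from focidetect.synthetic_data import (
    PAPER_REGIME_MIX,
    REGIMES,
    PlacementError,
    SceneConfig,
    allocate_regimes,
    generate_scene,
    generate_training_set,
)


class TestGenerateScene:
    def test_zero_mean_means_no_foci(self):
        _, _, truth = generate_scene(SceneConfig(foci_per_nucleus_mean=0.0, seed=3))
        assert not truth.foci_mask.any()
        assert all(v == 0 for v in truth.foci_count.values())

    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(seed=17, regime="noisy")
        a = generate_scene(cfg)
        b = generate_scene(cfg)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)
        assert np.array_equal(a[2].foci_mask, b[2].foci_mask)
        assert a[2].foci_centers == b[2].foci_centers

    def test_different_seeds_differ(self):
        a = generate_scene(SceneConfig(seed=1))
        b = generate_scene(SceneConfig(seed=2))
        assert not np.array_equal(a[1].pixels, b[1].pixels)

    def test_poisson_focus_counts(self):
        # ~320 nuclei: empirical mean within 3 standard errors of the Poisson mean
        mean = 5.0
        counts = []
        for seed in range(110):
            cfg = SceneConfig(
                image_size_px=(128, 128), n_nuclei=3, nucleus_radius_px=16.0,
                foci_per_nucleus_mean=mean, seed=1000 + seed,
            )
            _, _, truth = generate_scene(cfg)
            counts.extend(truth.foci_count.values())
        counts = np.asarray(counts)
        se = np.sqrt(mean / counts.size)
        assert abs(counts.mean() - mean) <= 3 * se

    def test_foci_inside_nuclei(self):
        for seed in (0, 5, 9):
            _, _, truth = generate_scene(SceneConfig(seed=seed))
            outside = truth.foci_mask & (truth.nucleus_label_mask == 0)
            assert not outside.any()

    def test_centers_consistent_with_counts(self):
        _, _, truth = generate_scene(SceneConfig(seed=4))
        for lab, centers in truth.foci_centers.items():
            assert truth.foci_count[lab] == len(centers)

    @pytest.mark.parametrize("regime", REGIMES)
    def test_all_regimes_render(self, regime):
        nuclear, foci, truth = generate_scene(SceneConfig(regime=regime, seed=8))
        assert foci.pixels.min() >= 0.0 and foci.pixels.max() <= 1.0
        assert nuclear.pixels.max() <= 1.0

    def test_noisy_regime_raises_background(self):
        good = generate_scene(SceneConfig(seed=21, regime="good"))[1]
        noisy = generate_scene(SceneConfig(seed=21, regime="noisy"))[1]
        bg_good = np.median(good.pixels)
        bg_noisy = np.median(noisy.pixels)
        assert bg_noisy > bg_good

    def test_artefact_structures_not_in_truth(self):
        good = generate_scene(SceneConfig(seed=33, regime="good"))
        art = generate_scene(SceneConfig(seed=33, regime="artefacts"))
        # same seed: same nuclei and foci truth, extra bright structures only
        assert np.array_equal(good[2].foci_mask, art[2].foci_mask)
        assert art[1].pixels.sum() > good[1].pixels.sum()

    def test_placement_error_when_too_crowded(self):
        with pytest.raises(PlacementError):
            generate_scene(SceneConfig(image_size_px=(64, 64), n_nuclei=20,
                                       nucleus_radius_px=20.0))

    def test_ground_truth_fidelity_separated_scene(self):
        # every planted center recovered from the noiseless truth mask within
        # 1.5 px on a scene without heavy focus overlap
        _, foci, truth = generate_scene(SceneConfig(seed=4, foci_per_nucleus_mean=4.0))
        mask = LabelMask(pixels=truth.foci_mask, meta=foci.meta)
        found = detect_centers(mask)
        planted = truth.all_centers
        assert planted
        for pr, pc in planted:
            d = min(np.hypot(r - pr, c - pc) for r, c in found.centers)
            assert d <= 1.5

    def test_ground_truth_fidelity_aggregate(self):
        # across several scenes (overlapping foci allowed): isolated planted
        # centers are always recovered tightly; overall recovery stays high
        recovered = total = 0
        for seed in range(6):
            _, foci, truth = generate_scene(
                SceneConfig(seed=seed, foci_per_nucleus_mean=4.0)
            )
            found = detect_centers(LabelMask(pixels=truth.foci_mask, meta=foci.meta))
            planted = truth.all_centers
            for i, (pr, pc) in enumerate(planted):
                nn = min(
                    (np.hypot(pr - qr, pc - qc)
                     for j, (qr, qc) in enumerate(planted) if j != i),
                    default=np.inf,
                )
                d = min(np.hypot(r - pr, c - pc) for r, c in found.centers)
                if nn >= 8.0:  # isolated focus: strict recovery
                    assert d <= 1.5
                total += 1
                recovered += d <= 2.5
        assert recovered / total >= 0.85


class TestAllocateRegimes:
    def test_nine_images_reference_mix(self):
        assert allocate_regimes(9, PAPER_REGIME_MIX) == {"good": 6, "noisy": 2, "halos": 1}

    def test_single_good_image(self):
        assert allocate_regimes(1, {"good": 1.0}) == {"good": 1}

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError):
            allocate_regimes(5, {"good": 0.5, "noisy": 0.3})

    def test_counts_sum_to_n(self):
        for n in (1, 4, 9, 25):
            assert sum(allocate_regimes(n, PAPER_REGIME_MIX).values()) == n

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            allocate_regimes(3, {"blurry": 1.0})


class TestGenerateTrainingSet:
    def test_deterministic_and_sized(self):
        a = generate_training_set(3, {"good": 0.67, "noisy": 0.33},
                                  SceneConfig(seed=5, image_size_px=(96, 96),
                                              n_nuclei=2, nucleus_radius_px=18.0))
        b = generate_training_set(3, {"good": 0.67, "noisy": 0.33},
                                  SceneConfig(seed=5, image_size_px=(96, 96),
                                              n_nuclei=2, nucleus_radius_px=18.0))
        assert len(a) == 3
        for (s1, s2) in zip(a, b):
            assert np.array_equal(s1[1].pixels, s2[1].pixels)

    def test_images_within_set_differ(self):
        scenes = generate_training_set(2, {"good": 1.0},
                                       SceneConfig(seed=1, image_size_px=(96, 96),
                                                   n_nuclei=2, nucleus_radius_px=18.0))
        assert not np.array_equal(scenes[0][1].pixels, scenes[1][1].pixels)


class TestSNROrdering:
    def test_good_f1_at_least_noisy_f1(self, e2e):
        good = generate_scene(SceneConfig(seed=77, regime="good"))
        noisy = generate_scene(SceneConfig(seed=77, regime="noisy"))
        scores = {}
        for name, (nuc, foci, truth) in (("good", good), ("noisy", noisy)):
            pred = predict_mask(e2e.model, foci)
            tally = pixel_tally(pred, LabelMask(pixels=truth.foci_mask, meta=foci.meta))
            scores[name] = compute_metrics(tally).f1
        assert scores["good"] >= scores["noisy"]
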