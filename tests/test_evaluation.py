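from __future__ import annotations

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focidetect.evaluation import (
    BootstrapConfig,
    DetectionTally,
    MetricReport,
    bootstrap_ci,
    ci_significance,
    compute_metrics,
    match_centers,
    pixel_tally,
    pool_tallies,
)
from _oracles import enumerate_bootstrap_metrics, max_matching_count, pixel_confusion_loop
from _reference import OBJECT_COUNTS, OBJECT_METRICS, PIXEL_COUNTS
from conftest import make_mask


class TestPixelTally:
    def test_identical_masks(self, rng):
        m = rng.random((20, 20)) > 0.7
        k = int(m.sum())
        t = pixel_tally(make_mask(m), make_mask(m.copy()))
        assert (t.tp, t.fp, t.fn, t.tn) == (k, 0, 0, 400 - k)

    def test_all_negative_prediction(self, rng):
        truth = rng.random((20, 20)) > 0.7
        t = pixel_tally(make_mask(np.zeros((20, 20), bool)), make_mask(truth))
        assert t.tp == 0 and t.fn == int(truth.sum())

    def test_matches_loop_oracle(self, rng):
        pred = rng.random((20, 20)) > 0.5
        truth = rng.random((20, 20)) > 0.5
        t = pixel_tally(make_mask(pred), make_mask(truth))
        assert (t.tp, t.fp, t.fn, t.tn) == pixel_confusion_loop(pred, truth)

    def test_conservation(self, rng):
        pred = rng.random((15, 17)) > 0.4
        truth = rng.random((15, 17)) > 0.6
        t = pixel_tally(make_mask(pred), make_mask(truth))
        assert t.tp + t.fp + t.fn + t.tn == 15 * 17

    def test_roi_restriction(self, rng):
        from focidetect.nucleus_segmentation import NucleusROI

        pred = rng.random((30, 30)) > 0.5
        truth = rng.random((30, 30)) > 0.5
        sel = np.zeros((30, 30), bool)
        sel[5:15, 5:20] = True
        roi = NucleusROI(label_id=1, mask=sel, bbox=(5, 5, 15, 20), area_px=150)
        t = pixel_tally(make_mask(pred), make_mask(truth), roi)
        assert t.tp + t.fp + t.fn + t.tn == 150
        assert (t.tp, t.fp, t.fn, t.tn) == pixel_confusion_loop(
            pred[5:15, 5:20], truth[5:15, 5:20]
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_tally(make_mask(np.zeros((5, 5), bool)), make_mask(np.zeros((6, 6), bool)))


class TestMatchCenters:
    def test_within_radius_matches(self):
        t = match_centers([(10, 10)], [(10, 14)], 5.0)
        assert (t.tp, t.fp, t.fn) == (1, 0, 0)
        assert t.tn is None

    def test_exactly_at_radius_matches(self):
        t = match_centers([(10, 10)], [(10, 15)], 5.0)
        assert t.tp == 1  # "within ... or less": inclusive

    def test_beyond_radius(self):
        t = match_centers([(10, 10)], [(10, 16)], 5.0)
        assert (t.tp, t.fp, t.fn) == (0, 1, 1)

    def test_empty_lists(self):
        t = match_centers([], [], 5.0)
        assert (t.tp, t.fp, t.fn) == (0, 0, 0)

    def test_one_to_one_no_double_matching(self):
        # two auto near one manual: only one can match
        t = match_centers([(10, 10), (10, 11)], [(10, 12)], 5.0)
        assert (t.tp, t.fp, t.fn) == (1, 1, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        auto = [tuple(p) for p in rng.uniform(0, 30, size=(6, 2))]
        manual = [tuple(p) for p in rng.uniform(0, 30, size=(5, 2))]
        t = match_centers(auto, manual, 5.0)
        assert t.tp == max_matching_count(auto, manual, 5.0)

    @settings(max_examples=40, deadline=None)
    @given(
        na=st.integers(0, 6),
        nm=st.integers(0, 6),
        seed=st.integers(0, 10_000),
    )
    def test_count_invariants(self, na, nm, seed):
        rng = np.random.default_rng(seed)
        auto = [tuple(p) for p in rng.uniform(0, 20, size=(na, 2))]
        manual = [tuple(p) for p in rng.uniform(0, 20, size=(nm, 2))]
        t = match_centers(auto, manual, 5.0)
        assert t.tp <= min(na, nm)
        assert t.tp + t.fp == na
        assert t.tp + t.fn == nm


class TestComputeMetrics:
    @pytest.mark.parametrize("model", sorted(OBJECT_COUNTS))
    def test_reference_object_rows(self, model):
        tp, fp, fn = OBJECT_COUNTS[model]
        report = compute_metrics(DetectionTally(tp=tp, fp=fp, fn=fn))
        rounded = report.rounded(3)
        sens, ppv, fnr, f1 = OBJECT_METRICS[model]
        assert rounded["sensitivity"] == sens
        assert rounded["ppv"] == ppv
        assert rounded["fnr"] == fnr
        assert rounded["f1"] == f1
        assert report.mcc is None  # no TN on the object level

    def test_perfect_detection(self):
        r = compute_metrics(DetectionTally(tp=7, fp=0, fn=0))
        assert r.sensitivity == r.ppv == r.f1 == 1.0 and r.fnr == 0.0

    def test_pixelwise_mlp_row_mcc(self):
        tn, fn, tp, fp = PIXEL_COUNTS["MLP"]
        r = compute_metrics(DetectionTally(tp=tp, fp=fp, fn=fn, tn=tn))
        assert r.mcc == pytest.approx(0.787, abs=5e-4)

    def test_all_pixelwise_rows_mcc_above_0p4(self):
        for tn, fn, tp, fp in PIXEL_COUNTS.values():
            r = compute_metrics(DetectionTally(tp=tp, fp=fp, fn=fn, tn=tn))
            assert r.mcc >= 0.4

    def test_zero_denominators_are_nan(self):
        with pytest.warns(UserWarning):
            r = compute_metrics(DetectionTally(tp=0, fp=0, fn=0, tn=10))
        assert math.isnan(r.sensitivity) and math.isnan(r.ppv) and math.isnan(r.f1)

    def test_all_zero_tally_warns(self):
        with pytest.warns(UserWarning):
            compute_metrics(DetectionTally(tp=0, fp=0, fn=0))

    @settings(max_examples=60, deadline=None)
    @given(
        tp=st.integers(0, 1000), fp=st.integers(0, 1000),
        fn=st.integers(0, 1000), tn=st.integers(0, 10_000),
    )
    def test_invariants(self, tp, fp, fn, tn):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = compute_metrics(DetectionTally(tp=tp, fp=fp, fn=fn, tn=tn))
        if tp + fn > 0:
            assert r.sensitivity + r.fnr == pytest.approx(1.0)
        for v in (r.sensitivity, r.ppv, r.fnr, r.f1):
            if not math.isnan(v):
                assert 0.0 <= v <= 1.0
        if r.mcc is not None and not math.isnan(r.mcc):
            assert -1.0 <= r.mcc <= 1.0 + 1e-12
            if fp == 0 and fn == 0 and tp > 0 and tn > 0:
                assert r.mcc == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DetectionTally(tp=-1, fp=0, fn=0)


class TestBootstrap:
    def test_identical_tallies_zero_width_ci(self):
        tallies = [DetectionTally(tp=10, fp=2, fn=1)] * 5
        point, lo, hi = bootstrap_ci(tallies, "f1", BootstrapConfig(n_reps=200, seed=0))
        assert lo == hi == point

    def test_three_nuclei_enumeration_oracle(self):
        tallies = [
            DetectionTally(tp=10, fp=0, fn=5),
            DetectionTally(tp=8, fp=4, fn=0),
            DetectionTally(tp=2, fp=1, fn=6),
        ]
        cfg = BootstrapConfig(n_reps=20_000, ci_level=0.95, seed=7)
        point, lo, hi = bootstrap_ci(tallies, "f1", cfg)

        def f1(tp, fp, fn):
            return 2 * tp / (2 * tp + fp + fn)

        values = enumerate_bootstrap_metrics(
            [(t.tp, t.fp, t.fn) for t in tallies], f1
        )
        # each of the 27 equally likely outcomes has probability 1/27 > 2.5%,
        # so the exact 95% percentile CI endpoints are the extreme outcomes
        assert lo == pytest.approx(min(values), abs=1e-12)
        assert hi == pytest.approx(max(values), abs=1e-12)
        assert point == pytest.approx(f1(20, 5, 11), abs=1e-12)

    def test_seeded_determinism(self):
        tallies = [DetectionTally(tp=k, fp=1, fn=2) for k in (5, 9, 13)]
        cfg = BootstrapConfig(n_reps=500, seed=11)
        assert bootstrap_ci(tallies, "ppv", cfg) == bootstrap_ci(tallies, "ppv", cfg)

    def test_basic_method_reflects(self):
        tallies = [DetectionTally(tp=k, fp=3, fn=2) for k in (5, 9, 13)]
        p, lo_p, hi_p = bootstrap_ci(tallies, "f1", BootstrapConfig(seed=1))
        p2, lo_b, hi_b = bootstrap_ci(
            tallies, "f1", BootstrapConfig(seed=1, method="basic")
        )
        assert p == p2
        assert lo_b == pytest.approx(2 * p - hi_p)
        assert hi_b == pytest.approx(2 * p - lo_p)

    def test_mcc_requires_tn(self):
        with pytest.raises(ValueError):
            bootstrap_ci([DetectionTally(tp=1, fp=1, fn=1)], "mcc")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bootstrap_ci([], "f1")


class TestCiSignificance:
    def _report(self, lo, hi):
        r = MetricReport(sensitivity=0.5, ppv=0.5, fnr=0.5, f1=0.5)
        r.ci["f1"] = (lo, hi)
        return r

    def test_disjoint_is_significant(self):
        assert ci_significance(self._report(0.80, 0.85), self._report(0.87, 0.91), "f1")

    def test_overlap_not_significant(self):
        assert not ci_significance(self._report(0.80, 0.88), self._report(0.87, 0.91), "f1")

    def test_identical_not_significant(self):
        r = self._report(0.8, 0.9)
        assert not ci_significance(r, self._report(0.8, 0.9), "f1")

    def test_missing_ci_raises(self):
        with pytest.raises(ValueError):
            ci_significance(
                MetricReport(0.5, 0.5, 0.5, 0.5), self._report(0.1, 0.2), "f1"
            )


def test_pool_tallies_sums_counts():
    pooled = pool_tallies(
        [DetectionTally(tp=1, fp=2, fn=3, tn=4), DetectionTally(tp=10, fp=20, fn=30, tn=40)]
    )
    assert (pooled.tp, pooled.fp, pooled.fn, pooled.tn) == (11, 22, 33, 44)


def test_pool_mixed_kinds_rejected():
    with pytest.raises(ValueError):
        pool_tallies([DetectionTally(1, 1, 1, 1), DetectionTally(1, 1, 1)])
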