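"""Jaccard, precision/recall/F arithmetic, track matching and contrast metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nepcount import (
    ConfigError,
    EvalCounts,
    GroundTruth,
    KalmanState,
    Track,
    count_eval,
    crop_centered,
    fg_bg_separability,
    gray_histogram,
    hist_distance,
    jaccard,
    mean_fscore,
    prf,
)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for y, x in coords:
        m[y, x] = True
    return m


class TestJaccard:
    def test_identical_masks_score_one(self, rng):
        m = rng.random((16, 16)) < 0.4
        m[0, 0] = True
        assert jaccard(m, m).value == 1.0

    def test_disjoint_masks_score_zero(self):
        a = _mask((4, 4), [(0, 0), (0, 1)])
        b = _mask((4, 4), [(3, 3)])
        assert jaccard(a, b).value == 0.0

    def test_partial_overlap_one_third(self):
        a = _mask((4, 4), [(0, 0), (1, 1)])
        b = _mask((4, 4), [(1, 1), (2, 2)])
        assert jaccard(a, b).value == pytest.approx(1 / 3)

    def test_symmetric_and_translation_invariant(self, rng):
        a = rng.random((20, 20)) < 0.3
        b = rng.random((20, 20)) < 0.3
        a[0, 0] = True
        assert jaccard(a, b).value == jaccard(b, a).value
        assert jaccard(np.roll(a, 3, 1), np.roll(b, 3, 1)).value == pytest.approx(
            jaccard(a, b).value
        )

    def test_both_empty_rejected(self):
        e = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ConfigError):
            jaccard(e, e)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=arrays(bool, (8, 8), elements=st.booleans()),
        b=arrays(bool, (8, 8), elements=st.booleans()),
    )
    def test_bounds_and_symmetry_hold_for_all_mask_pairs(self, a, b):
        if not (a.any() or b.any()):
            return
        j = jaccard(a, b).value
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a).value
        assert (j == 1.0) == bool(np.array_equal(a, b))
        assert (j == 0.0) == bool(not (a & b).any())


class TestPrf:
    # printed per-video rows: (TP, FP, FN) -> P, R, F at 2 decimals
    @pytest.mark.parametrize(
        "tp,fp,fn,p2,r2,f2",
        [
            (37, 3, 3, 0.93, 0.93, 0.93),
            (16, 1, 3, 0.94, 0.84, 0.89),
            (64, 1, 10, 0.98, 0.86, 0.92),
            (6, 8, 5, 0.43, 0.55, 0.48),
            (6, 7, 1, 0.46, 0.86, 0.60),
        ],
    )
    def test_reproduces_published_video_rows(self, tp, fp, fn, p2, r2, f2):
        r = prf(EvalCounts(tp, fp, fn))
        assert round(r.precision, 2) == p2
        assert round(r.recall, 2) == r2
        assert round(r.fscore, 2) == f2

    def test_exact_values_first_row(self):
        r = prf(EvalCounts(37, 3, 3))
        assert r.precision == pytest.approx(0.925)
        assert r.recall == pytest.approx(0.925)
        assert r.fscore == pytest.approx(0.925)

    def test_degenerate_zero_counts(self):
        r = prf(EvalCounts(0, 0, 5))
        assert (r.precision, r.recall, r.fscore) == (0.0, 0.0, 0.0)
        assert r.degenerate_precision and not r.degenerate_recall

    def test_f_between_min_and_max_of_p_and_r(self, rng):
        for _ in range(20):
            tp, fp, fn = rng.integers(1, 50, 3)
            r = prf(EvalCounts(int(tp), int(fp), int(fn)))
            assert min(r.precision, r.recall) - 1e-12 <= r.fscore <= max(r.precision, r.recall) + 1e-12


class TestMeanFscore:
    def test_headline_aggregation(self):
        assert mean_fscore([0.93, 0.89, 0.92, 0.48, 0.60], rounding=2) == pytest.approx(0.764)

    def test_single_report_identity(self):
        assert mean_fscore([0.77], rounding=None) == pytest.approx(0.77)

    def test_equal_values_fixed_point(self):
        assert mean_fscore([0.5, 0.5, 0.5], rounding=2) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            mean_fscore([])


def _track(tid, points):
    t = Track(id=tid, kalman=KalmanState.init(points[0][1:]), first_frame=points[0][0])
    t.history = [(f, x, y) for f, x, y in points]
    return t


def _gt_from(trajs):
    return GroundTruth(
        instances=[], trajectories=trajs, total_count=len(trajs)
    )


class TestCountEval:
    shape = (480, 640)

    def test_perfect_one_to_one_matching(self):
        trajs = {
            i: [(f, 50.0 * i, 10.0 + f) for f in range(20)] for i in (1, 2, 3)
        }
        tracks = [_track(i, trajs[i]) for i in (1, 2, 3)]
        c = count_eval(_gt_from(trajs), tracks, self.shape).counts
        assert (c.true_positive, c.false_positive, c.false_negative) == (3, 0, 0)

    def test_split_track_counts_extra_as_false_positive(self):
        traj = {1: [(f, 100.0 + 3 * f, 50.0) for f in range(40)]}
        first = _track(1, traj[1][:20])
        second = _track(2, traj[1][20:])
        c = count_eval(_gt_from(traj), [first, second], self.shape).counts
        assert (c.true_positive, c.false_positive, c.false_negative) == (1, 1, 0)

    def test_missed_target_is_false_negative(self):
        traj = {1: [(f, 10.0, 10.0) for f in range(10)]}
        c = count_eval(_gt_from(traj), [], self.shape).counts
        assert (c.true_positive, c.false_positive, c.false_negative) == (0, 0, 1)

    def test_spurious_track_is_false_positive(self):
        traj = {1: [(f, 10.0, 10.0) for f in range(10)]}
        ghost = _track(7, [(f, 400.0, 400.0) for f in range(10)])
        c = count_eval(_gt_from(traj), [ghost], self.shape).counts
        assert (c.true_positive, c.false_positive, c.false_negative) == (0, 1, 1)


class TestHistDistance:
    def test_identical_histograms_zero(self, rng):
        h = rng.random(256)
        h /= h.sum()
        assert hist_distance(h, h, "chi_squared") == 0.0
        assert hist_distance(h, h, "euclidean") == 0.0

    def test_disjoint_deltas_euclidean(self):
        h1 = np.zeros(256); h1[0] = 1.0
        h2 = np.zeros(256); h2[1] = 1.0
        assert hist_distance(h1, h2, "euclidean") == pytest.approx(np.sqrt(2))

    def test_chi_squared_hand_example(self):
        assert hist_distance(
            np.array([0.5, 0.5]), np.array([1.0, 0.0]), "chi_squared"
        ) == pytest.approx(1 / 3)

    def test_bin_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            hist_distance(np.ones(4) / 4, np.ones(5) / 5)

    @pytest.mark.parametrize("metric", ["chi_squared", "euclidean"])
    def test_metric_axioms_on_random_simplex_triples(self, rng, metric):
        for _ in range(30):
            h = rng.random((3, 16))
            h /= h.sum(axis=1, keepdims=True)
            a, b, c = h
            assert hist_distance(a, b, metric) == pytest.approx(hist_distance(b, a, metric))
            assert hist_distance(a, a, metric) == 0.0
            dab, dbc, dac = (
                hist_distance(a, b, metric),
                hist_distance(b, c, metric),
                hist_distance(a, c, metric),
            )
            assert dac <= dab + dbc + 1e-12

    def test_gray_histogram_normalized(self, rng):
        h = gray_histogram(rng.random((32, 32)))
        assert h.sum() == pytest.approx(1.0)
        assert len(h) == 256


class TestSeparability:
    def test_identical_distributions_near_zero(self, rng):
        frame = rng.normal(0.5, 0.05, (40, 40, 3)).clip(0, 1)
        mask = np.zeros((40, 40), dtype=bool)
        mask[:20] = True
        assert fg_bg_separability(frame, mask, "euclidean") < 0.02
        assert fg_bg_separability(frame, mask, "mahalanobis") < 1.0

    def test_identity_covariance_reduces_mahalanobis_to_euclidean(self, rng):
        # classes with isotropic unit-variance scatter (approximately)
        frame = rng.normal(0.0, 1.0, (60, 60, 3))
        mask = np.zeros((60, 60), dtype=bool)
        mask[:30] = True
        frame[mask] += 3.0
        eu = fg_bg_separability(frame, mask, "euclidean")
        ma = fg_bg_separability(frame, mask, "mahalanobis")
        assert ma == pytest.approx(eu, rel=0.1)

    def test_closed_form_two_class_example(self):
        # 3 FG and 3 BG pixels with hand-computed pooled covariance
        frame = np.zeros((2, 3, 3))
        fg = np.array([[0.8, 0.2, 0.1], [0.7, 0.3, 0.2], [0.9, 0.1, 0.3]])
        bg = np.array([[0.1, 0.8, 0.2], [0.2, 0.7, 0.1], [0.3, 0.9, 0.3]])
        frame[0] = fg
        frame[1] = bg
        mask = np.zeros((2, 3), dtype=bool)
        mask[0] = True
        delta = fg.mean(0) - bg.mean(0)
        pooled = (np.cov(fg, rowvar=False) * 2 + np.cov(bg, rowvar=False) * 2) / 4
        want_eu = np.linalg.norm(delta)
        want_ma = np.sqrt(delta @ np.linalg.inv(pooled) @ delta)
        assert fg_bg_separability(frame, mask, "euclidean") == pytest.approx(want_eu)
        assert fg_bg_separability(frame, mask, "mahalanobis") == pytest.approx(want_ma)

    def test_single_class_mask_rejected(self, rng):
        with pytest.raises(ConfigError):
            fg_bg_separability(rng.random((4, 4, 3)), np.ones((4, 4), bool))


class TestCropCentered:
    def test_full_size_crop_is_identity(self, rng):
        img = rng.random((20, 30, 3))
        out, clamped = crop_centered(img, width=30, height=20)
        np.testing.assert_array_equal(out, img)
        assert not clamped

    def test_central_quarter(self, rng):
        img = rng.random((20, 20))
        out, clamped = crop_centered(img, width=10, height=10, center=(10, 10))
        np.testing.assert_array_equal(out, img[5:15, 5:15])
        assert not clamped

    def test_window_clamped_at_border(self, rng):
        img = rng.random((20, 20))
        out, clamped = crop_centered(img, width=10, height=10, center=(2, 2))
        np.testing.assert_array_equal(out, img[0:10, 0:10])
        assert clamped
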