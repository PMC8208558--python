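"""Kalman filtering, Hungarian assignment and track lifecycle / counting."""

import itertools

import numpy as np
import pytest

from nepcount import (
    ConfigError,
    Detection,
    KalmanState,
    TrackerConfig,
    TrackerState,
    assign,
    finalize_count,
    kalman_predict,
    kalman_update,
    step,
)


def _det(x, y, frame=0, area=9000):
    return Detection(bbox=(int(x) - 50, int(y) - 50, 100, 100), centroid=(x, y), area=area, frame_index=frame)


class TestKalman:
    def test_predict_extrapolates_position(self):
        k = KalmanState.init((0.0, 0.0))
        k.x[2:] = (2.0, 1.0)
        p = kalman_predict(k)
        assert p.position == pytest.approx((2.0, 1.0))
        assert p.x[2:] == pytest.approx([2.0, 1.0])

    def test_zero_velocity_stationary(self):
        k = KalmanState.init((5.0, 7.0))
        assert kalman_predict(k).position == pytest.approx((5.0, 7.0))

    def test_covariance_trace_grows_under_predict(self):
        k = KalmanState.init((0.0, 0.0))
        assert np.trace(kalman_predict(k).P) > np.trace(k.P)

    def test_update_pulls_to_measurement_as_noise_vanishes(self):
        k = KalmanState.init((0.0, 0.0), measurement_var=1e-12)
        u = kalman_update(kalman_predict(k), (10.0, -3.0))
        assert u.position == pytest.approx((10.0, -3.0), abs=1e-6)

    def test_converges_on_noiseless_linear_trajectory(self):
        k = KalmanState.init((0.0, 0.0))
        err = None
        for t in range(1, 51):
            k = kalman_predict(k)
            truth = (3.0 * t, 1.5 * t)
            err = np.hypot(k.x[0] - truth[0], k.x[1] - truth[1])
            k = kalman_update(k, truth)
        assert err < 0.5

    def test_matches_closed_form_recursion(self):
        """One predict+update step against an independently scripted
        matrix-arithmetic recursion."""
        F = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]], float)
        H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float)
        x0 = np.array([1.0, 2.0, 0.5, -0.5])
        P0 = np.diag([4.0, 4.0, 1.0, 1.0])
        Q = np.diag([0.3, 0.3, 0.1, 0.1])
        R = np.eye(2) * 2.0
        z = np.array([2.2, 1.4])
        # oracle
        xp = F @ x0
        Pp = F @ P0 @ F.T + Q
        S = H @ Pp @ H.T + R
        K = Pp @ H.T @ np.linalg.inv(S)
        x_want = xp + K @ (z - H @ xp)
        P_want = (np.eye(4) - K @ H) @ Pp

        k = KalmanState(x=x0.copy(), P=P0.copy(), Q=Q, R=R)
        out = kalman_update(kalman_predict(k), tuple(z))
        np.testing.assert_allclose(out.x, x_want, atol=1e-10)
        np.testing.assert_allclose(out.P, P_want, atol=1e-10)


class TestAssign:
    def test_single_close_pair_matched(self):
        cfg = TrackerConfig()
        state = TrackerState()
        state = step(state, [_det(0.0, 0.0)], 0, cfg)
        pairs, ut, ud = assign(state.tracks, [_det(3.0, 4.0, 1)], cfg)
        assert pairs == [(0, 0)] and ut == [] and ud == []

    def test_distant_detection_unmatched(self):
        cfg = TrackerConfig()
        state = TrackerState()
        state = step(state, [_det(0.0, 0.0)], 0, cfg)
        pairs, ut, ud = assign(state.tracks, [_det(500.0, 0.0, 1)], cfg)
        assert pairs == [] and ut == [0] and ud == [0]

    def test_matches_brute_force_permutation_minimum(self, rng):
        cfg = TrackerConfig(non_assignment_cost=1e6)  # no gating
        for _ in range(10):
            tracks_xy = rng.uniform(0, 200, (4, 2))
            dets_xy = rng.uniform(0, 200, (4, 2))
            state = TrackerState()
            state = step(state, [_det(x, y) for x, y in tracks_xy], 0, cfg)
            # zero velocity: predicted positions equal (approximately) updated ones
            dets = [_det(x, y, 1) for x, y in dets_xy]
            pairs, _, _ = assign(state.tracks, dets, cfg)
            pred = np.array([t.kalman.position for t in state.tracks])
            cost = np.linalg.norm(pred[:, None] - dets_xy[None], axis=2)
            got = sum(cost[r, c] for r, c in pairs)
            want = min(
                sum(cost[i, p[i]] for i in range(4))
                for p in itertools.permutations(range(4))
            )
            assert got == pytest.approx(want)

    def test_permutation_invariance_of_total_cost(self, rng):
        cfg = TrackerConfig(non_assignment_cost=1e6)
        state = TrackerState()
        xy = rng.uniform(0, 100, (3, 2))
        state = step(state, [_det(x, y) for x, y in xy], 0, cfg)
        dets = [_det(x, y, 1) for x, y in rng.uniform(0, 100, (3, 2))]
        pred = np.array([t.kalman.position for t in state.tracks])

        def total(det_order):
            ds = [dets[i] for i in det_order]
            pairs, _, _ = assign(state.tracks, ds, cfg)
            return sum(
                np.hypot(*(np.array(pred[r]) - np.array(ds[c].centroid)))
                for r, c in pairs
            )

        costs = {round(total(p), 9) for p in itertools.permutations(range(3))}
        assert len(costs) == 1

    def test_empty_inputs(self):
        cfg = TrackerConfig()
        assert assign([], [], cfg) == ([], [], [])


class TestStepAndCount:
    def test_single_stream_single_track(self):
        cfg = TrackerConfig()
        state = TrackerState()
        for t in range(30):
            state = step(state, [_det(10.0 + 3 * t, 50.0, t)], t, cfg)
        assert len(state.tracks) == 1 and not state.lost
        assert finalize_count(state, cfg).total_count == 1

    def test_track_lost_after_miss_streak(self):
        cfg = TrackerConfig(max_invisible=10)
        state = TrackerState()
        for t in range(15):
            state = step(state, [_det(10.0 + 3 * t, 50.0, t)], t, cfg)
        for t in range(15, 15 + 12):
            state = step(state, [], t, cfg)
        assert state.tracks == []
        assert len(state.lost) == 1
        assert finalize_count(state, cfg).total_count == 1

    def test_parallel_streams_keep_identities(self):
        cfg = TrackerConfig()
        state = TrackerState()
        for t in range(40):
            dets = [_det(5.0 + 3 * t, 100.0, t), _det(5.0 + 3 * t, 200.0, t)]
            state = step(state, dets, t, cfg)
        assert sorted(t.id for t in state.tracks) == [1, 2]
        ys = {t.id: t.kalman.position[1] for t in state.tracks}
        assert ys[1] == pytest.approx(100.0, abs=2.0)
        assert ys[2] == pytest.approx(200.0, abs=2.0)

    def test_noise_track_below_gate_not_counted(self):
        cfg = TrackerConfig()
        state = TrackerState()
        for t in range(20):
            dets = [_det(10.0 + 3 * t, 50.0, t)]
            if t in (5, 6):  # two-frame flicker elsewhere
                dets.append(_det(400.0, 400.0, t))
            state = step(state, dets, t, cfg)
        assert finalize_count(state, cfg).total_count == 1

    def test_empty_run_counts_zero(self):
        assert finalize_count(TrackerState(), TrackerConfig()).total_count == 0

    def test_decreasing_frame_index_rejected(self):
        cfg = TrackerConfig()
        state = TrackerState()
        state = step(state, [], 5, cfg)
        with pytest.raises(ConfigError):
            step(state, [], 5, cfg)

    def test_track_ids_strictly_increasing_never_reused(self):
        cfg = TrackerConfig(max_invisible=2)
        state = TrackerState()
        frame = 0
        seen_ids = []
        for burst in range(3):
            for t in range(12):
                state = step(state, [_det(10.0 + 3 * t, 50.0, frame)], frame, cfg)
                frame += 1
            for _ in range(5):
                state = step(state, [], frame, cfg)
                frame += 1
            seen_ids = [t.id for t in state.lost]
        assert seen_ids == sorted(seen_ids)
        assert len(set(seen_ids)) == len(seen_ids) == 3

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_count_recovery_for_k_separated_targets(self, k):
        """Noiseless detections of K well-separated constant-velocity targets
        yield exactly K counted tracks."""
        cfg = TrackerConfig()
        state = TrackerState()
        for t in range(50):
            dets = [
                _det(10.0 + 2.5 * t + 7 * i, 80.0 * (i + 1), t) for i in range(k)
            ]
            state = step(state, dets, t, cfg)
        assert finalize_count(state, cfg).total_count == k
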