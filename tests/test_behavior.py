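"""Speed, state segmentation, and windowed motor metrics."""

import numpy as np
import pytest

from nemoresponse.behavior import (
    BehaviorConfig,
    SegmentationParams,
    StateSegmentation,
    Trajectory,
    behavior_cohort_table,
    instantaneous_speed,
    mean_speed_in_window,
    path_length,
    reverse_distance,
    segment_states,
    state_time_ratios,
    straight_line_distance,
)
from nemoresponse.errors import InvalidArgumentError
from nemoresponse.protocol import make_protocol
from nemoresponse.synthetic import LocomotionParams, simulate_trajectory


def make_traj(protocol, x, y, animal_id="w0", group="g"):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) / protocol.frame_rate
    y = np.broadcast_to(np.asarray(y, dtype=float), x.shape).copy()
    return Trajectory(animal_id, group, t, x, y, protocol)


@pytest.fixture(scope="module")
def short_protocol():
    return make_protocol(5, 10, 5, 1, "CO2")


class TestInstantaneousSpeed:
    def test_three_four_five(self, short_protocol):
        x = np.zeros(21)
        y = np.zeros(21)
        x[1:] = 3.0
        y[1:] = 4.0
        traj = Trajectory("w", "g", np.arange(21.0), x, y, short_protocol)
        st = instantaneous_speed(traj, smooth_s=0)
        assert st.speed_mm_s[0] == pytest.approx(5.0)
        assert st.t_s[0] == 1.0  # later-frame timestamp

    def test_stationary_track(self, short_protocol):
        traj = make_traj(short_protocol, np.zeros(21), 0.0)
        st = instantaneous_speed(traj)
        assert np.all(st.speed_mm_s == 0.0)

    @pytest.mark.parametrize("smooth_s", [0, 1, 3])
    def test_constant_velocity_fixed_point(self, short_protocol, smooth_s):
        traj = make_traj(short_protocol, 0.25 * np.arange(21), 0.0)
        st = instantaneous_speed(traj, smooth_s=smooth_s)
        assert np.allclose(st.speed_mm_s, 0.25)


class TestSegmentStates:
    PARAMS = SegmentationParams(min_bout_s=0.0)

    def test_straight_track_single_forward(self, short_protocol):
        traj = make_traj(short_protocol, 0.1 * np.arange(21), 0.0)
        seg = segment_states(traj, self.PARAMS)
        assert seg.intervals == ((0.0, 20.0, "forward"),)

    def test_out_and_back_forward_then_reverse(self, short_protocol):
        x = np.concatenate([0.1 * np.arange(11), 0.1 * np.arange(9, -1, -1)])
        traj = make_traj(short_protocol, x, 0.0)
        seg = segment_states(traj, self.PARAMS)
        assert [iv[2] for iv in seg.intervals] == ["forward", "reverse"]
        assert seg.intervals[0][1] == 10.0  # split at the turn frame

    def test_pause_detection(self, short_protocol):
        x = np.concatenate([0.1 * np.arange(8), np.full(5, 0.7), 0.7 + 0.1 * np.arange(1, 9)])
        traj = make_traj(short_protocol, x, 0.0)
        seg = segment_states(traj, self.PARAMS)
        assert [iv[2] for iv in seg.intervals] == ["forward", "pause", "forward"]

    def test_short_bout_merged(self, short_protocol):
        # one-frame stop inside an otherwise straight run is absorbed
        x = 0.1 * np.arange(21.0)
        x[10] = x[9]  # single zero-displacement interval
        x[11:] = x[10] + 0.1 * np.arange(1, 11)
        traj = make_traj(short_protocol, x, 0.0)
        seg = segment_states(traj, SegmentationParams(min_bout_s=1.5))
        assert seg.intervals == ((0.0, 20.0, "forward"),)

    def test_matches_simulator_ground_truth_no_jitter(self, behavior_protocol):
        params = LocomotionParams.from_rate_dicts(
            baseline={("forward", "reverse"): 0.05, ("forward", "pause"): 0.05,
                      ("reverse", "forward"): 0.5, ("pause", "forward"): 0.4},
            stimulus={("forward", "pause"): 0.8, ("pause", "forward"): 0.05,
                      ("forward", "reverse"): 0.2, ("reverse", "pause"): 0.5},
            speed_sd=(0.0, 0.0, 0.0), heading_diffusion=0.0, frame_rate=5.0,
        )
        agree = []
        for seed in range(10):
            traj, states = simulate_trajectory(behavior_protocol, params, seed=seed)
            seg = segment_states(traj, self.PARAMS)
            labels = seg.labels_for(traj.t_s[:-1])
            agree.append(np.mean([a == b for a, b in zip(labels, states)]))
        assert np.mean(agree) >= 0.99

    def test_oracle_equivalence_small_tracks(self, rng):
        """Vectorized segmentation equals a literal framewise re-implementation."""
        import math

        proto = make_protocol(10, 20, 10, 1, "CO2")

        def oracle(traj, p):
            xs, ys, dt = traj.x_mm, traj.y_mm, traj.dt_s
            labels = []
            mode, ref = "forward", None
            alpha = min(1.0, dt / p.heading_ref_tau_s)
            thr = math.radians(p.reversal_angle_deg)
            for i in range(len(xs) - 1):
                dx, dy = xs[i + 1] - xs[i], ys[i + 1] - ys[i]
                sp = math.hypot(dx, dy) / dt
                if sp < p.pause_speed_mm_s:
                    labels.append("pause")
                    continue
                h = math.atan2(dy, dx)
                if ref is None:
                    ref = h
                else:
                    d = (h - ref + math.pi) % (2 * math.pi) - math.pi
                    if abs(d) > thr:
                        mode = "reverse" if mode == "forward" else "forward"
                        ref = h
                    else:
                        ref = ref + alpha * d
                labels.append(mode)
            # same merge rule
            from nemoresponse.behavior import _merge_short_bouts

            return _merge_short_bouts(labels, dt, p.min_bout_s)

        p = SegmentationParams(min_bout_s=2.0)
        for _ in range(50):
            n = int(rng.integers(5, 41))
            steps = rng.choice([0.0, 0.05, 0.1, -0.1], size=(n, 2))
            xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            traj = Trajectory("w", "g", np.arange(n + 1.0), xy[:, 0], xy[:, 1],
                              make_protocol(1, max(1, n - 2), 1, 1, "CO2"))
            seg = segment_states(traj, p)
            assert seg.labels_for(traj.t_s[:-1]) == oracle(traj, p)


class TestWindowedMetrics:
    def make_seg(self):
        return StateSegmentation(
            intervals=((0.0, 10.0, "forward"), (10.0, 15.0, "pause"), (15.0, 20.0, "reverse"))
        )

    def test_ratio_partition(self):
        assert state_time_ratios(self.make_seg(), (0.0, 20.0)) == (0.5, 0.25, 0.25)

    def test_window_inside_pause(self):
        assert state_time_ratios(self.make_seg(), (11.0, 14.0)) == (0.0, 0.0, 1.0)

    def test_ratios_sum_exactly_one(self, rng):
        for _ in range(20):
            bounds = np.sort(rng.uniform(0, 100, size=5))
            states = ["forward", "reverse", "pause", "forward"]
            iv = tuple(
                (float(a), float(b), s) for a, b, s in zip(bounds, bounds[1:], states)
                if b > a
            )
            seg = StateSegmentation(intervals=iv)
            w = (float(bounds[0]), float(bounds[-1]))
            f, r, p = state_time_ratios(seg, w)
            assert f + r + p == 1.0

    def test_mean_speed(self, short_protocol):
        traj = make_traj(short_protocol, 0.2 * np.arange(21), 0.0)
        st = instantaneous_speed(traj, smooth_s=0)
        assert mean_speed_in_window(st, (5.0, 15.0)) == pytest.approx(0.2)

    def test_default_windows_anchor_to_onset(self, behavior_protocol):
        from nemoresponse.behavior import BehaviorWindows

        win = BehaviorWindows().absolute(behavior_protocol)
        assert win["early"] == (20.0, 40.0)
        assert win["late"] == (50.0, 70.0)
        assert win["stimulus"] == (20.0, 80.0)

    def test_straight_line_distance(self, short_protocol):
        traj = make_traj(short_protocol, 0.1 * np.arange(21), 0.0)
        assert straight_line_distance(traj, (0.0, 20.5)) == pytest.approx(2.0)

    def test_out_and_back_zero_distance(self, short_protocol):
        x = np.concatenate([0.1 * np.arange(11), 0.1 * np.arange(9, -1, -1)])
        traj = make_traj(short_protocol, x, 0.0)
        assert straight_line_distance(traj, (0.0, 20.5)) == pytest.approx(0.0)

    def test_straight_line_bounded_by_path_length(self, short_protocol, rng):
        for _ in range(20):
            xy = np.cumsum(rng.normal(0, 0.05, size=(21, 2)), axis=0)
            traj = Trajectory("w", "g", np.arange(21.0), xy[:, 0], xy[:, 1], short_protocol)
            w = (0.0, 20.5)
            assert straight_line_distance(traj, w) <= path_length(traj, w) + 1e-12

    def test_reverse_distance(self, short_protocol):
        x = np.concatenate([0.1 * np.arange(11), 0.1 * np.arange(9, -1, -1)])
        traj = make_traj(short_protocol, x, 0.0)
        seg = segment_states(traj, SegmentationParams(min_bout_s=0.0))
        assert reverse_distance(traj, seg, (0.0, 20.0)) == pytest.approx(1.0)
        assert reverse_distance(traj, seg, (0.0, 10.0)) == pytest.approx(0.0)

    def test_rigid_motion_invariance(self, short_protocol, rng):
        xy = np.cumsum(rng.normal(0, 0.08, size=(21, 2)), axis=0)
        traj = Trajectory("w", "g", np.arange(21.0), xy[:, 0], xy[:, 1], short_protocol)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy2 = xy @ rot.T + np.array([3.0, -1.5])
        traj2 = Trajectory("w", "g", np.arange(21.0), xy2[:, 0], xy2[:, 1], short_protocol)
        w = (0.0, 20.0)
        p = SegmentationParams(min_bout_s=0.0)
        seg1, seg2 = segment_states(traj, p), segment_states(traj2, p)
        assert seg1.intervals == seg2.intervals
        assert straight_line_distance(traj, w) == pytest.approx(straight_line_distance(traj2, w))
        assert reverse_distance(traj, seg1, w) == pytest.approx(reverse_distance(traj2, seg2, w))
        st1 = instantaneous_speed(traj)
        st2 = instantaneous_speed(traj2)
        assert np.allclose(st1.speed_mm_s, st2.speed_mm_s)


class TestCohortTable:
    def test_identical_tracks_zero_variance(self, behavior_protocol):
        x = 0.1 * np.arange(behavior_protocol.n_frames + 1) / behavior_protocol.frame_rate
        t = np.arange(behavior_protocol.n_frames + 1) / behavior_protocol.frame_rate
        trajs = [
            Trajectory(f"w{i}", "g", t, x.copy(), np.zeros_like(x), behavior_protocol)
            for i in range(4)
        ]
        metrics, summary = behavior_cohort_table(trajs, BehaviorConfig())
        for col in ("speed_early", "speed_late", "pause_ratio", "straight_line_mm"):
            assert metrics[col].std() == 0.0
        assert np.all(summary["sem_mm_s"] == 0.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidArgumentError):
            behavior_cohort_table([], BehaviorConfig())
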