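"""Centroid-trajectory locomotion analysis.

Derives stimulus-locked motor metrics from (t, x, y) centroid tracks:
instantaneous speed, forward/reverse/pause state segmentation, windowed mean
speeds, state time ratios, straight-line distance, and distance traveled in
reverse.

Conventions
-----------
* The displacement between frames i and i+1 defines a per-interval speed and
  heading; the speed sample is timestamped at the *later* frame.
* Analysis windows are half-open ``[start_s, end_s)``.
* Pauses are frames whose raw speed falls below ``pause_speed_mm_s``.
* Direction from centroid-only data: moving intervals start as forward; when
  the instantaneous heading departs from a smoothed reference heading by more
  than ``reversal_angle_deg``, the direction state toggles forward<->reverse
  and the reference resets.  The reference tracks within-bout heading drift
  with an exponential moving average (time constant ``heading_ref_tau_s``).
* Bouts shorter than ``min_bout_s`` are merged into the longer neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .protocol import StimulusProtocol

__all__ = [
    "Trajectory",
    "SpeedTrace",
    "StateSegmentation",
    "SegmentationParams",
    "BehaviorWindows",
    "instantaneous_speed",
    "segment_states",
    "state_time_ratios",
    "mean_speed_in_window",
    "straight_line_distance",
    "path_length",
    "reverse_distance",
    "behavior_cohort_table",
]

STATES = ("forward", "reverse", "pause")


@dataclass(frozen=True)
class Trajectory:
    """Centroid track of one animal on the assay plate (mm, seconds)."""

    animal_id: str
    group: str
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        x = np.asarray(self.x_mm, dtype=float)
        y = np.asarray(self.y_mm, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 3:
            raise InvalidArgumentError("t_s, x_mm, y_mm must be equal-length 1-D arrays with >= 3 frames")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InvalidArgumentError("t_s must be strictly increasing and uniformly spaced")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise InvalidArgumentError("coordinates must be finite")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "x_mm", x)
        object.__setattr__(self, "y_mm", y)

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])


@dataclass(frozen=True)
class SpeedTrace:
    """Instantaneous speed samples (mm/s), timestamped at the later frame."""

    t_s: np.ndarray
    speed_mm_s: np.ndarray


@dataclass(frozen=True)
class StateSegmentation:
    """Contiguous, non-overlapping forward/reverse/pause intervals.

    ``intervals`` is an ordered list of ``(start_s, end_s, state)`` covering
    the analyzed span; adjacent intervals never share a state.
    """

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        iv = tuple(self.intervals)
        if not iv:
            raise InvalidArgumentError("segmentation must contain at least one interval")
        for (s0, e0, st0), (s1, e1, st1) in zip(iv, iv[1:]):
            if e0 != s1:
                raise InvalidArgumentError("intervals must be contiguous")
            if st0 == st1:
                raise InvalidArgumentError("adjacent intervals must not share a state")
        for s, e, st in iv:
            if not s < e:
                raise InvalidArgumentError("interval must have start < end")
            if st not in STATES:
                raise InvalidArgumentError(f"unknown state {st!r}")
        object.__setattr__(self, "intervals", iv)

    @property
    def span(self) -> tuple[float, float]:
        return (self.intervals[0][0], self.intervals[-1][1])

    def state_at(self, t: float) -> str:
        """State of the interval containing time ``t`` (half-open lookup)."""
        for s, e, st in self.intervals:
            if s <= t < e:
                return st
        raise InvalidArgumentError(f"time {t} outside segmentation span {self.span}")

    def labels_for(self, edges: np.ndarray) -> list[str]:
        """Per-interval labels for displacement intervals starting at ``edges``."""
        return [self.state_at(t) for t in edges]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds for state segmentation (all configurable)."""

    pause_speed_mm_s: float = 0.02
    min_bout_s: float = 0.6
    reversal_angle_deg: float = 120.0
    heading_ref_tau_s: float = 1.0

    def __post_init__(self) -> None:
        if self.pause_speed_mm_s <= 0 or self.reversal_angle_deg <= 0:
            raise InvalidArgumentError("thresholds must be positive")
        if self.min_bout_s < 0 or self.heading_ref_tau_s <= 0:
            raise InvalidArgumentError("min_bout_s must be >= 0 and heading_ref_tau_s > 0")


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------

def instantaneous_speed(traj: Trajectory, smooth_s: float = 1.0) -> SpeedTrace:
    """Framewise centroid speed, optionally smoothed.

    Speed is displacement magnitude over the frame interval; smoothing is a
    centered moving average over ``smooth_s`` seconds with truncated windows
    at the edges.  ``smooth_s=0`` disables smoothing.
    """
    if smooth_s < 0:
        raise InvalidArgumentError("smooth_s must be >= 0")
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    speed = np.hypot(dx, dy) / traj.dt_s
    if smooth_s > 0:
        w = max(1, int(round(smooth_s / traj.dt_s)))
        if w > 1:
            speed = (
                pd.Series(speed).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
            )
    return SpeedTrace(t_s=traj.t_s[1:], speed_mm_s=speed)


def _raw_speed_heading(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    speed = np.hypot(dx, dy) / traj.dt_s
    heading = np.arctan2(dy, dx)
    return speed, heading


def _ang_diff(a: float, b: float) -> float:
    """Absolute angular difference in [0, pi]."""
    d = (a - b + np.pi) % (2 * np.pi) - np.pi
    return abs(d)


def _merge_short_bouts(labels: list[str], dt: float, min_bout_s: float) -> list[str]:
    """Merge bouts shorter than ``min_bout_s`` into the longer neighbor.

    Repeatedly absorbs the shortest sub-threshold bout (earliest on ties)
    until none remain; then adjacent equal-state runs coalesce implicitly.
    """
    labels = list(labels)
    if min_bout_s <= 0 or not labels:
        return labels
    while True:
        # run-length encode
        runs: list[tuple[int, int, str]] = []  # (start, length, state)
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            runs.append((i, j - i, labels[i]))
            i = j
        if len(runs) == 1:
            return labels
        short = [
            (length, idx) for idx, (_, length, _) in enumerate(runs) if length * dt < min_bout_s
        ]
        if not short:
            return labels
        _, ridx = min(short)
        start, length, _ = runs[ridx]
        left_len = runs[ridx - 1][1] if ridx > 0 else -1
        right_len = runs[ridx + 1][1] if ridx < len(runs) - 1 else -1
        absorb = runs[ridx - 1][2] if left_len >= right_len else runs[ridx + 1][2]
        for k in range(start, start + length):
            labels[k] = absorb


def segment_states(traj: Trajectory, params: SegmentationParams | None = None) -> StateSegmentation:
    """Label the track's displacement intervals forward / reverse / pause.

    Frames with raw speed below the pause threshold are pauses.  Moving
    intervals start as forward; a heading departure exceeding the reversal
    angle relative to the smoothed pre-bout reference toggles the direction
    state.  Sub-``min_bout_s`` bouts merge into the longer neighbor.
    """
    if params is None:
        params = SegmentationParams()
    speed, heading = _raw_speed_heading(traj)
    n = speed.size
    dt = traj.dt_s
    thr = np.deg2rad(params.reversal_angle_deg)
    alpha = min(1.0, dt / params.heading_ref_tau_s)

    labels: list[str] = []
    mode = "forward"
    ref: float | None = None
    for i in range(n):
        if speed[i] < params.pause_speed_mm_s:
            labels.append("pause")
            continue
        h = heading[i]
        if ref is None:
            ref = h
        elif _ang_diff(h, ref) > thr:
            mode = "reverse" if mode == "forward" else "forward"
            ref = h
        else:
            # EMA of the reference toward the current heading (circular)
            d = (h - ref + np.pi) % (2 * np.pi) - np.pi
            ref = ref + alpha * d
        labels.append(mode)

    labels = _merge_short_bouts(labels, dt, params.min_bout_s)

    intervals: list[tuple[float, float, str]] = []
    t = traj.t_s
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        intervals.append((float(t[i]), float(t[j]), labels[i]))
        i = j
    return StateSegmentation(intervals=tuple(intervals))


# ---------------------------------------------------------------------------
# windowed metrics
# ---------------------------------------------------------------------------

def state_time_ratios(
    seg: StateSegmentation, window: tuple[float, float]
) -> tuple[float, float, float]:
    """(forward, reverse, pause) time fractions within a window; sums to 1."""
    start, end = window
    if not start < end:
        raise InvalidArgumentError(f"empty window {window}")
    s0, s1 = seg.span
    if start < s0 - 1e-9 or end > s1 + 1e-9:
        raise InvalidArgumentError(f"window {window} outside the analyzed span {seg.span}")
    total = {st: 0.0 for st in STATES}
    for s, e, st in seg.intervals:
        total[st] += max(0.0, min(e, end) - max(s, start))
    w = end - start
    fwd = total["forward"] / w
    rev = total["reverse"] / w
    # pause is the complement of the rounded sum, so fwd + rev + pau evaluated
    # left-to-right is exactly 1.0 in floating point
    pau = 1.0 - (fwd + rev)
    return (fwd, rev, pau)


def mean_speed_in_window(st: SpeedTrace, window: tuple[float, float]) -> float:
    """Arithmetic mean of speed samples with timestamps in the window."""
    start, end = window
    mask = (st.t_s >= start) & (st.t_s < end)
    if not mask.any():
        raise InvalidArgumentError(f"no speed samples in window {window}")
    return float(np.mean(st.speed_mm_s[mask]))


def _frames_in_window(traj: Trajectory, window: tuple[float, float]) -> np.ndarray:
    start, end = window
    return np.flatnonzero((traj.t_s >= start) & (traj.t_s < end))


def straight_line_distance(traj: Trajectory, window: tuple[float, float]) -> float:
    """Euclidean distance between the first and last positions in the window."""
    idx = _frames_in_window(traj, window)
    if idx.size < 2:
        raise InvalidArgumentError(f"fewer than 2 frames in window {window}")
    i, j = idx[0], idx[-1]
    return float(np.hypot(traj.x_mm[j] - traj.x_mm[i], traj.y_mm[j] - traj.y_mm[i]))


def path_length(traj: Trajectory, window: tuple[float, float]) -> float:
    """Summed framewise displacement within the window."""
    idx = _frames_in_window(traj, window)
    if idx.size < 2:
        raise InvalidArgumentError(f"fewer than 2 frames in window {window}")
    x = traj.x_mm[idx[0] : idx[-1] + 1]
    y = traj.y_mm[idx[0] : idx[-1] + 1]
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def reverse_distance(
    traj: Trajectory, seg: StateSegmentation, window: tuple[float, float]
) -> float:
    """Summed displacement over intervals labeled reverse within the window.

    A displacement interval counts when its start frame lies in the window
    and its segmentation label is reverse.
    """
    start, end = window
    total = 0.0
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    disp = np.hypot(dx, dy)
    s0, s1 = seg.span
    for i, t in enumerate(traj.t_s[:-1]):
        if start <= t < end and s0 <= t < s1 and seg.state_at(t) == "reverse":
            total += disp[i]
    return float(total)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorWindows:
    """Stimulus-anchored analysis windows (seconds after pulse onset).

    Defaults: the full pulse ``[onset, onset+60)``, an early window covering
    the first 20 s of the pulse, and a late 20-s window starting 30 s after
    onset.
    """

    stimulus: tuple[float, float] = (0.0, 60.0)
    early: tuple[float, float] = (0.0, 20.0)
    late: tuple[float, float] = (30.0, 50.0)
    baseline: tuple[float, float] = (-20.0, 0.0)

    def absolute(self, protocol: StimulusProtocol) -> dict[str, tuple[float, float]]:
        onset = protocol.pulse_onset_s
        out = {}
        for name in ("stimulus", "early", "late", "baseline"):
            a, b = getattr(self, name)
            out[name] = (onset + a, onset + b)
        return out


@dataclass(frozen=True)
class BehaviorConfig:
    """Bundle of segmentation, smoothing, and window parameters."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    windows: BehaviorWindows = field(default_factory=BehaviorWindows)
    smooth_s: float = 1.0


def behavior_cohort_table(
    trajectories: list[Trajectory],
    config: BehaviorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal motor metrics plus group-mean speed traces.

    Returns ``(metrics, speed_summary)``.  ``metrics`` has one row per animal:
    group, gas label, mean speed in the early and late windows and baseline,
    forward/reverse/pause time ratios over the stimulus-clock window,
    straight-line distance, and distance traveled in reverse.
    ``speed_summary`` has framewise group mean +/- SEM speed.
    """
    if not trajectories:
        raise InvalidArgumentError("empty cohort")
    if config is None:
        config = BehaviorConfig()
    rows = []
    speed_frames = []
    for traj in trajectories:
        win = config.windows.absolute(traj.protocol)
        st = instantaneous_speed(traj, smooth_s=config.smooth_s)
        seg = segment_states(traj, config.segmentation)
        fwd, rev, pau = state_time_ratios(seg, win["stimulus"])
        gas = "air" if traj.protocol.is_air_control else "CO2"
        rows.append(
            {
                "animal_id": traj.animal_id,
                "group": traj.group,
                "gas": gas,
                "speed_baseline": mean_speed_in_window(st, win["baseline"]),
                "speed_early": mean_speed_in_window(st, win["early"]),
                "speed_late": mean_speed_in_window(st, win["late"]),
                "forward_ratio": fwd,
                "reverse_ratio": rev,
                "pause_ratio": pau,
                "straight_line_mm": straight_line_distance(traj, win["stimulus"]),
                "reverse_mm": reverse_distance(traj, seg, win["stimulus"]),
            }
        )
        speed_frames.append(
            pd.DataFrame(
                {
                    "group": traj.group,
                    "gas": gas,
                    "t_s": st.t_s,
                    "speed_mm_s": st.speed_mm_s,
                }
            )
        )
    metrics = pd.DataFrame(rows)
    allspeed = pd.concat(speed_frames, ignore_index=True)
    speed_summary = (
        allspeed.groupby(["group", "gas", "t_s"])["speed_mm_s"]
        .agg(
            mean_mm_s="mean",
            sem_mm_s=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            n="size",
        )
        .reset_index()
    )
    return metrics, speed_summary
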