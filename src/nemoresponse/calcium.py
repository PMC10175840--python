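"""Ratiometric (FRET) calcium-trace analysis.

Recordings made with a two-channel ratiometric indicator (donor CFP, acceptor
YFP; e.g. yellow cameleon YC3.60) are reduced to a percent fractional ratio
change

    %dR/R0(t) = 100 * (R(t) - R0) / R0,      R(t) = acceptor(t) / donor(t)

where ``R0`` is the mean ratio over a pre-stimulus baseline window.  Because
the two channels share the optical path, any common gain or bleaching factor
cancels in the ratio; %dR/R0 is invariant to rescaling both channels by the
same positive constant.

Per-animal responses are summarised by the maximum and minimum of %dR/R0 over
a response window, and classified as excitatory / inhibitory / silent against
an empirical null: the standard deviation of the same statistic measured in
animals that received an air pulse instead of CO2.  A response counts as
non-silent when its absolute value exceeds ``k`` (default 3) times that
air-control SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DataError, DegenerateNullWarning, InvalidArgumentError
from .protocol import StimulusProtocol

__all__ = [
    "CalciumTrace",
    "RatioTrace",
    "NullModel",
    "ResponseCall",
    "default_baseline_window",
    "default_response_window",
    "compute_ratio_trace",
    "peak_amplitudes",
    "extremum_statistic",
    "fit_air_null",
    "categorize_response",
    "classify_cohort",
    "cohort_mean_sem",
    "order_for_heatmap",
]

RESPONSE_CLASSES = ("excitatory", "inhibitory", "silent")


@dataclass(frozen=True)
class CalciumTrace:
    """Two-channel fluorescence time series for one animal.

    ``donor`` and ``acceptor`` are raw intensities (arbitrary units, must be
    strictly positive); ``t_s`` must be uniformly spaced at the protocol's
    frame rate.
    """

    animal_id: str
    neuron: str
    group: str
    t_s: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        d = np.asarray(self.donor, dtype=float)
        a = np.asarray(self.acceptor, dtype=float)
        if not (t.shape == d.shape == a.shape) or t.ndim != 1 or t.size < 2:
            raise InvalidArgumentError("t_s, donor, acceptor must be equal-length 1-D arrays (>=2 frames)")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidArgumentError("t_s must be strictly increasing")
        if not np.allclose(dt, 1.0 / self.protocol.frame_rate, rtol=1e-6, atol=1e-9):
            raise InvalidArgumentError("t_s spacing must match the protocol frame rate")
        if np.any(~np.isfinite(d)) or np.any(~np.isfinite(a)) or np.any(d <= 0) or np.any(a <= 0):
            raise DataError("donor and acceptor must be finite and strictly positive at every frame")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "donor", d)
        object.__setattr__(self, "acceptor", a)


@dataclass(frozen=True)
class RatioTrace:
    """Derived acceptor/donor ratio trace with its baseline and %dR/R0."""

    animal_id: str
    neuron: str
    group: str
    t_s: np.ndarray
    r: np.ndarray
    r0: float
    dr_pct: np.ndarray
    protocol: StimulusProtocol


@dataclass(frozen=True)
class NullModel:
    """Empirical null for response classification, fit on air controls.

    ``sd`` is the sample standard deviation (n-1 denominator) of the chosen
    per-animal statistic (max, min, or signed extremum of %dR/R0) across the
    air-control animals, over ``window``.
    """

    statistic_name: str
    sd: float
    n_controls: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.statistic_name not in ("max", "min", "extremum"):
            raise InvalidArgumentError(f"unknown statistic {self.statistic_name!r}")
        if self.sd < 0:
            raise InvalidArgumentError("sd must be >= 0")
        if self.n_controls < 2:
            raise InvalidArgumentError("n_controls must be >= 2")


@dataclass(frozen=True)
class ResponseCall:
    """Per-animal peak amplitudes and excitatory/inhibitory/silent call."""

    animal_id: str
    group: str
    max_pct: float
    min_pct: float
    response_class: str
    null: NullModel = field(repr=False, compare=False, default=None)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

#: Seconds dropped from the start of the pre-pulse period before the baseline
#: window begins (lets the preparation settle).
BASELINE_SETTLE_S = 2.0
#: Seconds past pulse offset included in the response window, to capture
#: responses that begin only after the pulse ends.
POST_OFFSET_RESPONSE_S = 30.0


def default_baseline_window(protocol: StimulusProtocol) -> tuple[float, float]:
    """Full pre-pulse air period minus the first 2 s."""
    onset = protocol.pulse_onset_s
    start = min(BASELINE_SETTLE_S, onset / 2.0)
    return (start, onset)


def default_response_window(protocol: StimulusProtocol) -> tuple[float, float]:
    """Pulse onset through 30 s past pulse offset (clipped to the recording)."""
    end = min(protocol.pulse_offset_s + POST_OFFSET_RESPONSE_S, protocol.duration_s)
    return (protocol.pulse_onset_s, end)


def _window_mask(t_s: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    start, end = window
    if not (start < end):
        raise InvalidArgumentError(f"window must have start < end, got {window}")
    return (t_s >= start) & (t_s < end)


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def compute_ratio_trace(
    trace: CalciumTrace,
    baseline_window: tuple[float, float] | None = None,
) -> RatioTrace:
    """Convert a two-channel trace to a %dR/R0 ratio trace.

    The baseline window must lie inside the recording, strictly before the
    pulse onset, and contain at least 2 frames.
    """
    if baseline_window is None:
        baseline_window = default_baseline_window(trace.protocol)
    start, end = baseline_window
    if start < trace.t_s[0] - 1e-9 or end > trace.protocol.duration_s + 1e-9:
        raise InvalidArgumentError(f"baseline window {baseline_window} outside the recording")
    if end > trace.protocol.pulse_onset_s + 1e-9:
        raise InvalidArgumentError(
            f"baseline window {baseline_window} overlaps the stimulus pulse "
            f"(onset {trace.protocol.pulse_onset_s} s)"
        )
    mask = _window_mask(trace.t_s, baseline_window)
    if mask.sum() < 2:
        raise InvalidArgumentError("baseline window must contain at least 2 frames")
    r = trace.acceptor / trace.donor
    r0 = float(np.mean(r[mask]))
    dr_pct = 100.0 * (r - r0) / r0
    return RatioTrace(
        animal_id=trace.animal_id,
        neuron=trace.neuron,
        group=trace.group,
        t_s=trace.t_s,
        r=r,
        r0=r0,
        dr_pct=dr_pct,
        protocol=trace.protocol,
    )


def peak_amplitudes(rt: RatioTrace, response_window: tuple[float, float] | None = None) -> tuple[float, float]:
    """Maximum and minimum %dR/R0 over frames in the half-open window."""
    if response_window is None:
        response_window = default_response_window(rt.protocol)
    mask = _window_mask(rt.t_s, response_window)
    if not mask.any():
        raise InvalidArgumentError(f"response window {response_window} contains no frames")
    vals = rt.dr_pct[mask]
    return float(np.max(vals)), float(np.min(vals))


def extremum_statistic(rt: RatioTrace, response_window: tuple[float, float], statistic: str) -> float:
    """Per-animal summary statistic over the response window.

    ``"max"``/``"min"`` are the window extrema of %dR/R0; ``"extremum"`` is
    the signed value of largest magnitude (ties favour the maximum).
    """
    mx, mn = peak_amplitudes(rt, response_window)
    if statistic == "max":
        return mx
    if statistic == "min":
        return mn
    if statistic == "extremum":
        return mx if abs(mx) >= abs(mn) else mn
    raise InvalidArgumentError(f"unknown statistic {statistic!r}")


def fit_air_null(
    air_traces: list[RatioTrace],
    response_window: tuple[float, float] | None = None,
    statistic: str = "extremum",
) -> NullModel:
    """Fit the empirical null SD from air-control ratio traces.

    Computes the chosen per-animal statistic over the response window for each
    air trace and takes the sample SD (n-1).  At least two controls with the
    same protocol timing are required.
    """
    if len(air_traces) < 2:
        raise InvalidArgumentError("need at least 2 air-control traces to fit a null")
    if response_window is None:
        response_window = default_response_window(air_traces[0].protocol)
    for rt in air_traces[1:]:
        if (rt.protocol.pulse_onset_s, rt.protocol.pulse_offset_s) != (
            air_traces[0].protocol.pulse_onset_s,
            air_traces[0].protocol.pulse_offset_s,
        ):
            raise InvalidArgumentError("air-control traces must share the same protocol timing")
    stats = np.array([extremum_statistic(rt, response_window, statistic) for rt in air_traces])
    sd = float(np.std(stats, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "air-control null has zero SD; every nonzero response will classify as non-silent",
            DegenerateNullWarning,
            stacklevel=2,
        )
    return NullModel(statistic_name=statistic, sd=sd, n_controls=len(air_traces), window=tuple(response_window))


def categorize_response(call_in: tuple[float, float], null: NullModel, k: float = 3.0) -> str:
    """Excitatory / inhibitory / silent call from window extrema.

    A response is excitatory if its maximum exceeds ``k * null.sd`` and
    dominates in magnitude; inhibitory if ``|min|`` exceeds the threshold and
    strictly dominates; silent otherwise.  Ties in magnitude (both above
    threshold) classify excitatory.
    """
    if k <= 0:
        raise InvalidArgumentError("k must be positive")
    max_pct, min_pct = call_in
    if max_pct < min_pct:
        raise InvalidArgumentError("max_pct must be >= min_pct")
    thr = k * null.sd
    if max_pct > thr and max_pct >= abs(min_pct):
        return "excitatory"
    if abs(min_pct) > thr and abs(min_pct) > max_pct:
        return "inhibitory"
    return "silent"


def classify_cohort(
    traces: list[CalciumTrace],
    air_traces: list[CalciumTrace],
    baseline_window: tuple[float, float] | None = None,
    response_window: tuple[float, float] | None = None,
    k: float = 3.0,
    statistic: str = "extremum",
) -> tuple[list[ResponseCall], pd.DataFrame]:
    """Classify every animal in a cohort against an air-control null.

    Returns the per-animal calls and a group x class table with ``count`` and
    ``pct`` columns (percentages within group).
    """
    if not traces:
        raise InvalidArgumentError("empty cohort")
    air_rts = [compute_ratio_trace(t, baseline_window) for t in air_traces]
    null = fit_air_null(air_rts, response_window, statistic=statistic)
    calls: list[ResponseCall] = []
    for t in traces:
        rt = compute_ratio_trace(t, baseline_window)
        mx, mn = peak_amplitudes(rt, response_window or default_response_window(rt.protocol))
        cls = categorize_response((mx, mn), null, k=k)
        calls.append(ResponseCall(animal_id=t.animal_id, group=t.group, max_pct=mx, min_pct=mn,
                                  response_class=cls, null=null))
    df = pd.DataFrame(
        [{"animal_id": c.animal_id, "group": c.group, "response_class": c.response_class} for c in calls]
    )
    counts = (
        df.groupby(["group", "response_class"], sort=True).size().rename("count").reset_index()
    )
    # ensure all three classes appear for every group
    full = pd.MultiIndex.from_product(
        [sorted(df["group"].unique()), RESPONSE_CLASSES], names=["group", "response_class"]
    )
    counts = counts.set_index(["group", "response_class"]).reindex(full, fill_value=0).reset_index()
    totals = counts.groupby("group")["count"].transform("sum")
    counts["pct"] = 100.0 * counts["count"] / totals
    return calls, counts


def cohort_mean_sem(traces: list[RatioTrace]) -> pd.DataFrame:
    """Framewise mean and SEM (sample SD / sqrt(n)) of %dR/R0 across animals.

    All traces must share an identical frame grid.  Returns a DataFrame with
    columns ``t_s``, ``mean_pct``, ``sem_pct``.
    """
    if len(traces) < 2:
        raise InvalidArgumentError("need at least 2 traces")
    t0 = traces[0].t_s
    for rt in traces[1:]:
        if rt.t_s.shape != t0.shape or not np.allclose(rt.t_s, t0):
            raise InvalidArgumentError("traces must share an identical frame grid")
    mat = np.vstack([rt.dr_pct for rt in traces])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return pd.DataFrame({"t_s": t0, "mean_pct": mean, "sem_pct": sem})


def order_for_heatmap(
    traces: list[RatioTrace],
    metric: str = "euclidean",
    linkage: str = "average",
) -> np.ndarray:
    """Row order for a per-animal response heatmap.

    Agglomerative clustering over the per-animal %dR/R0 vectors; rows are the
    optimal-leaf-ordered dendrogram leaves.  Deterministic for fixed inputs.
    """
    if len(traces) < 2:
        raise InvalidArgumentError("need at least 2 traces to order")
    t0 = traces[0].t_s
    for rt in traces[1:]:
        if rt.t_s.shape != t0.shape or not np.allclose(rt.t_s, t0):
            raise InvalidArgumentError("traces must share an identical frame grid")
    mat = np.vstack([rt.dr_pct for rt in traces])
    if np.any(~np.isfinite(mat)):
        raise DataError("NaN or infinite values in traces")
    if len(traces) == 2:
        return np.array([0, 1])
    d = pdist(mat, metric=metric)
    z = hierarchy.linkage(d, method=linkage)
    z = hierarchy.optimal_leaf_ordering(z, d)
    return np.asarray(hierarchy.leaves_list(z))
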