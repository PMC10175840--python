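"""Synthetic recordings with known ground truth.

Emulates the three data streams the analysis consumes:

* two-channel ratiometric calcium recordings with stimulus-locked excitatory,
  inhibitory, or silent responses (including responses that begin only after
  pulse offset, as seen for post-pulse inhibition);
* centroid locomotion trajectories generated by a three-state
  (forward/reverse/pause) Markov jump process whose transition rates switch
  when the stimulus turns on;
* binomial chemotaxis-plate counts.

Every simulator is deterministic under a seed; cohort simulators give each
animal an independent child stream spawned from ``(root seed, animal index)``
via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import STATES, Trajectory
from .calcium import CalciumTrace
from .errors import InvalidArgumentError
from .protocol import StimulusProtocol, make_protocol  # noqa: F401  (re-export)
from .stats import ChemotaxisCounts

__all__ = [
    "CalciumGroundTruth",
    "LocomotionParams",
    "make_protocol",
    "response_kernel",
    "simulate_calcium_trace",
    "simulate_calcium_cohort",
    "simulate_trajectory",
    "simulate_chemotaxis_assay",
    "adult_like_params",
    "dauer_like_params",
]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in seq.spawn(n)]


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalciumGroundTruth:
    """True response parameters behind one simulated animal.

    ``amplitude_pct`` is the kernel peak in % ratio change (>= 0; 0 for
    silent).  ``post_offset`` starts the response at pulse offset + latency
    instead of onset + latency.
    """

    response_class: str
    amplitude_pct: float
    onset_latency_s: float = 1.0
    rise_s: float = 3.0
    decay_tau_s: float = 10.0
    post_offset: bool = False

    def __post_init__(self) -> None:
        if self.response_class not in ("excitatory", "inhibitory", "silent"):
            raise InvalidArgumentError(f"unknown response class {self.response_class!r}")
        if self.amplitude_pct < 0:
            raise InvalidArgumentError("amplitude_pct must be >= 0")
        if self.response_class == "silent" and self.amplitude_pct != 0:
            raise InvalidArgumentError("silent responses must have amplitude 0")
        if self.rise_s <= 0 or self.decay_tau_s <= 0:
            raise InvalidArgumentError("rise_s and decay_tau_s must be positive")


def response_kernel(t_s: np.ndarray, truth: CalciumGroundTruth, protocol: StimulusProtocol) -> np.ndarray:
    """Signed fractional response kernel evaluated at the frame times.

    A linear rise over ``rise_s`` to the peak followed by exponential decay
    with time constant ``decay_tau_s``; zero before the response start.  The
    peak equals ``amplitude_pct / 100`` with sign +1 (excitatory) or -1
    (inhibitory).
    """
    if truth.response_class == "silent" or truth.amplitude_pct == 0:
        return np.zeros_like(np.asarray(t_s, dtype=float))
    anchor = protocol.pulse_offset_s if truth.post_offset else protocol.pulse_onset_s
    start = anchor + truth.onset_latency_s
    rel = np.asarray(t_s, dtype=float) - start
    amp = truth.amplitude_pct / 100.0
    k = np.where(
        rel < 0,
        0.0,
        np.where(rel < truth.rise_s, rel / truth.rise_s, np.exp(-(rel - truth.rise_s) / truth.decay_tau_s)),
    )
    sign = -1.0 if truth.response_class == "inhibitory" else 1.0
    return sign * amp * k


def simulate_calcium_trace(
    protocol: StimulusProtocol,
    truth: CalciumGroundTruth,
    noise_sd: float = 0.01,
    bleach_rate: float = 0.0,
    seed: int = 0,
    animal_id: str = "a0",
    neuron: str = "sim",
    group: str = "sim",
    baseline_ratio: float = 2.0,
    donor_level: float = 100.0,
) -> CalciumTrace:
    """Simulate one two-channel recording.

    The noise-free acceptor/donor ratio is ``baseline_ratio * (1 + kernel)``;
    both channels carry independent multiplicative Gaussian noise of relative
    SD ``noise_sd`` and a shared exponential bleach ``exp(-bleach_rate t)``
    (which cancels in the ratio).
    """
    if noise_sd < 0 or bleach_rate < 0:
        raise InvalidArgumentError("noise_sd and bleach_rate must be >= 0")
    if truth.response_class == "inhibitory" and truth.amplitude_pct >= 100:
        raise InvalidArgumentError("inhibitory amplitude >= 100% would drive the ratio non-positive")
    rng = np.random.default_rng(seed)
    t = protocol.times()
    ratio = baseline_ratio * (1.0 + response_kernel(t, truth, protocol))
    bleach = np.exp(-bleach_rate * t)
    donor = donor_level * bleach * (1.0 + noise_sd * rng.standard_normal(t.size))
    acceptor = donor_level * ratio * bleach * (1.0 + noise_sd * rng.standard_normal(t.size))
    if np.any(donor <= 0) or np.any(acceptor <= 0):
        raise InvalidArgumentError(
            "simulated channel intensities went non-positive; reduce noise_sd or bleach_rate"
        )
    return CalciumTrace(
        animal_id=animal_id, neuron=neuron, group=group,
        t_s=t, donor=donor, acceptor=acceptor, protocol=protocol,
    )


#: Default amplitude distribution for cohort simulation (% units).
DEFAULT_AMPLITUDE_DIST = {"kind": "uniform", "low": 10.0, "high": 30.0}


def _draw_amplitude(dist: dict, rng: np.random.Generator) -> float:
    kind = dist.get("kind", "uniform")
    if kind == "uniform":
        return float(rng.uniform(dist["low"], dist["high"]))
    if kind == "fixed":
        return float(dist["value"])
    if kind == "lognormal":
        return float(rng.lognormal(dist["mean_log"], dist["sd_log"]))
    raise InvalidArgumentError(f"unknown amplitude distribution kind {kind!r}")


def simulate_calcium_cohort(
    protocol: StimulusProtocol,
    class_mix: tuple[float, float, float] | dict[str, float],
    amplitude_dist: dict | None = None,
    n: int = 16,
    seed: int = 0,
    noise_sd: float = 0.01,
    bleach_rate: float = 0.0,
    group: str = "sim",
    neuron: str = "sim",
    latency_s: float = 1.0,
    post_offset_class: str | None = None,
) -> tuple[list[CalciumTrace], list[CalciumGroundTruth]]:
    """Simulate ``n`` animals with classes drawn i.i.d. from ``class_mix``.

    ``class_mix`` orders (excitatory, inhibitory, silent) when given as a
    tuple.  ``post_offset_class`` optionally makes one class respond after
    pulse offset (e.g. ``"inhibitory"`` for post-pulse inhibition).
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if isinstance(class_mix, dict):
        mix = [class_mix.get("excitatory", 0.0), class_mix.get("inhibitory", 0.0), class_mix.get("silent", 0.0)]
    else:
        mix = list(class_mix)
    if len(mix) != 3 or any(p < 0 for p in mix) or not np.isclose(sum(mix), 1.0, atol=1e-9):
        raise InvalidArgumentError("class_mix must be 3 non-negative probabilities summing to 1")
    if amplitude_dist is None:
        amplitude_dist = DEFAULT_AMPLITUDE_DIST
    classes = ("excitatory", "inhibitory", "silent")
    rngs = _child_rngs(seed, n + 1)
    draw_rng = rngs[0]
    picks = draw_rng.choice(3, size=n, p=np.array(mix) / sum(mix))
    traces, truths = [], []
    for i in range(n):
        rng = rngs[i + 1]
        cls = classes[picks[i]]
        amp = 0.0 if cls == "silent" else _draw_amplitude(amplitude_dist, rng)
        truth = CalciumGroundTruth(
            response_class=cls,
            amplitude_pct=amp,
            onset_latency_s=latency_s,
            post_offset=(cls == post_offset_class),
        )
        trace = simulate_calcium_trace(
            protocol, truth, noise_sd=noise_sd, bleach_rate=bleach_rate,
            seed=rng.integers(0, 2**31 - 1),
            animal_id=f"{group}-{i:03d}", neuron=neuron, group=group,
        )
        traces.append(trace)
        truths.append(truth)
    return traces, truths


# ---------------------------------------------------------------------------
# locomotion
# ---------------------------------------------------------------------------

def _rates(d: dict[tuple[str, str], float]) -> np.ndarray:
    m = np.zeros((3, 3))
    idx = {s: i for i, s in enumerate(STATES)}
    for (a, b), r in d.items():
        if r < 0:
            raise InvalidArgumentError("transition rates must be >= 0")
        m[idx[a], idx[b]] = r
    np.fill_diagonal(m, 0.0)
    return m


@dataclass(frozen=True)
class LocomotionParams:
    """Three-state locomotion generator parameters.

    ``rates_baseline`` and ``rates_stimulus`` are per-second off-diagonal
    transition-rate matrices over (forward, reverse, pause); the stimulus
    matrix applies while the pulse is on (optionally truncated after
    ``stimulus_adaptation_s`` and extended ``carry_over_s`` past offset).
    Speeds are per-state means/SDs in mm/s (pause mean 0 means true stops;
    a small pause SD emulates centroid jitter).
    """

    rates_baseline: np.ndarray
    rates_stimulus: np.ndarray
    speed_mean: tuple[float, float, float] = (0.15, 0.12, 0.0)
    speed_sd: tuple[float, float, float] = (0.02, 0.02, 0.0)
    heading_diffusion: float = 0.3  # rad^2 / s
    frame_rate: float = 5.0
    carry_over_s: float = 0.0
    stimulus_adaptation_s: float | None = None
    initial_state: str = "forward"

    def __post_init__(self) -> None:
        rb = np.array(self.rates_baseline, dtype=float)
        rs = np.array(self.rates_stimulus, dtype=float)
        for m in (rb, rs):
            if m.shape != (3, 3) or np.any(m < 0):
                raise InvalidArgumentError("rate matrices must be 3x3 with non-negative entries")
        np.fill_diagonal(rb, 0.0)
        np.fill_diagonal(rs, 0.0)
        object.__setattr__(self, "rates_baseline", rb)
        object.__setattr__(self, "rates_stimulus", rs)
        if any(s < 0 for s in self.speed_mean) or any(s < 0 for s in self.speed_sd):
            raise InvalidArgumentError("speeds must be >= 0")
        if min(self.speed_mean[0], self.speed_mean[1]) <= self.speed_mean[2]:
            raise InvalidArgumentError("forward/reverse speeds must exceed pause speed")
        if self.heading_diffusion < 0 or self.frame_rate <= 0 or self.carry_over_s < 0:
            raise InvalidArgumentError("invalid heading_diffusion, frame_rate, or carry_over_s")
        if self.initial_state not in STATES:
            raise InvalidArgumentError(f"unknown initial state {self.initial_state!r}")

    @classmethod
    def from_rate_dicts(cls, baseline: dict, stimulus: dict, **kw) -> "LocomotionParams":
        return cls(rates_baseline=_rates(baseline), rates_stimulus=_rates(stimulus), **kw)


def adult_like_params(frame_rate: float = 5.0) -> LocomotionParams:
    """Starved-adult-like parameters: transient slowing and reversals.

    Stimulus rates apply only during the first 20 s of the pulse
    (``stimulus_adaptation_s``), emulating the rapid adaptation in which
    adults resume pre-stimulus speed midway through the pulse.
    """
    return LocomotionParams.from_rate_dicts(
        baseline={
            ("forward", "reverse"): 0.05, ("forward", "pause"): 0.03,
            ("reverse", "forward"): 0.50, ("reverse", "pause"): 0.05,
            ("pause", "forward"): 0.50, ("pause", "reverse"): 0.05,
        },
        stimulus={
            ("forward", "reverse"): 0.60, ("forward", "pause"): 0.40,
            ("reverse", "forward"): 0.25, ("reverse", "pause"): 0.15,
            ("pause", "forward"): 0.10, ("pause", "reverse"): 0.15,
        },
        speed_mean=(0.15, 0.12, 0.0),
        frame_rate=frame_rate,
        stimulus_adaptation_s=20.0,
    )


def dauer_like_params(frame_rate: float = 5.0) -> LocomotionParams:
    """Dauer-like parameters: profound pausing for the whole pulse."""
    return LocomotionParams.from_rate_dicts(
        baseline={
            ("forward", "reverse"): 0.05, ("forward", "pause"): 0.05,
            ("reverse", "forward"): 0.50, ("reverse", "pause"): 0.05,
            ("pause", "forward"): 0.40, ("pause", "reverse"): 0.05,
        },
        stimulus={
            ("forward", "reverse"): 0.20, ("forward", "pause"): 1.50,
            ("reverse", "forward"): 0.10, ("reverse", "pause"): 1.00,
            ("pause", "forward"): 0.02, ("pause", "reverse"): 0.02,
        },
        speed_mean=(0.10, 0.08, 0.0),
        frame_rate=frame_rate,
        stimulus_adaptation_s=None,
    )


def simulate_trajectory(
    protocol: StimulusProtocol,
    params: LocomotionParams,
    seed: int = 0,
    animal_id: str = "w0",
    group: str = "sim",
    start_xy: tuple[float, float] = (0.0, 0.0),
    initial_heading: float | None = None,
) -> tuple[Trajectory, list[str]]:
    """Simulate one centroid track and its per-interval true states.

    States follow a Markov jump process realized at frame boundaries: in each
    frame the exit probability is ``min(1, total_rate * dt)`` with the
    destination drawn proportionally to the individual rates.  This Euler
    discretization keeps the mean state dwell time exactly ``1/exit_rate``
    and the stationary occupancy equal to that of the continuous-time rate
    matrix (rates faster than the frame rate saturate at one jump per
    frame).  Position integrates heading x per-state speed; reversal frames
    move along ``heading + pi``; heading diffuses as a Wiener process on
    moving frames.

    Positions span the full protocol duration (``n_frames + 1`` samples);
    ``states[i]`` is the state during ``[t_i, t_{i+1})``, so
    ``len(states) == n_frames``.
    """
    if not np.isclose(params.frame_rate, protocol.frame_rate):
        raise InvalidArgumentError("params.frame_rate must match the protocol frame rate")
    rng = np.random.default_rng(seed)
    dt = 1.0 / protocol.frame_rate
    n = protocol.n_frames + 1
    t = np.arange(n) * dt

    try:
        onset, offset = protocol.pulse_onset_s, protocol.pulse_offset_s
        has_pulse = protocol.pulse is not None
    except Exception:
        has_pulse = False
    if has_pulse:
        stim_end = offset if params.stimulus_adaptation_s is None else min(
            offset, onset + params.stimulus_adaptation_s
        )
        stim_end += params.carry_over_s
    idx = {s: i for i, s in enumerate(STATES)}
    state = idx[params.initial_state]
    heading = float(rng.uniform(-np.pi, np.pi)) if initial_heading is None else float(initial_heading)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = start_xy
    states: list[str] = []
    sig_h = np.sqrt(params.heading_diffusion * dt)
    # pre-drawn randomness (one value per frame and purpose) keeps the python
    # loop cheap and the draw order — hence the output — deterministic
    speed_noise = rng.standard_normal(n - 1)
    heading_noise = rng.standard_normal(n - 1)
    u_jump = rng.random(n - 1)
    u_dest = rng.random(n - 1)
    stay_prob = {
        id(m): 1.0 - np.minimum(1.0, m.sum(axis=1) * dt)
        for m in (params.rates_baseline, params.rates_stimulus)
    }
    cum_dest = {
        id(m): np.cumsum(
            np.divide(m, m.sum(axis=1, keepdims=True), out=np.zeros_like(m), where=m.sum(axis=1, keepdims=True) > 0),
            axis=1,
        )
        for m in (params.rates_baseline, params.rates_stimulus)
    }
    for i in range(n - 1):
        stimulus_on = has_pulse and (onset <= t[i] < stim_end)
        rates = params.rates_stimulus if stimulus_on else params.rates_baseline
        states.append(STATES[state])
        mu = params.speed_mean[state]
        sd = params.speed_sd[state]
        speed = mu if sd == 0 else max(0.0, mu + sd * speed_noise[i])
        moving = STATES[state] != "pause"
        if moving and sig_h > 0:
            heading += sig_h * heading_noise[i]
        phi = heading + (np.pi if STATES[state] == "reverse" else 0.0)
        x[i + 1] = x[i] + speed * dt * np.cos(phi)
        y[i + 1] = y[i] + speed * dt * np.sin(phi)
        # state update at the frame boundary
        if u_jump[i] >= stay_prob[id(rates)][state]:
            cum = cum_dest[id(rates)][state]
            state = int(np.searchsorted(cum, u_dest[i], side="right"))
    traj = Trajectory(animal_id=animal_id, group=group, t_s=t, x_mm=x, y_mm=y, protocol=protocol)
    return traj, states


def simulate_behavior_cohort(
    protocol: StimulusProtocol,
    params: LocomotionParams,
    n: int,
    seed: int,
    group: str = "sim",
) -> tuple[list[Trajectory], list[list[str]]]:
    """Simulate ``n`` animals with independent child streams."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rngs = _child_rngs(seed, n)
    trajs, all_states = [], []
    for i, rng in enumerate(rngs):
        traj, st = simulate_trajectory(
            protocol, params, seed=int(rng.integers(0, 2**31 - 1)),
            animal_id=f"{group}-{i:03d}", group=group,
        )
        trajs.append(traj)
        all_states.append(st)
    return trajs, all_states


# ---------------------------------------------------------------------------
# chemotaxis
# ---------------------------------------------------------------------------

def simulate_chemotaxis_assay(
    p_test: float, n_worms: int, seed: int = 0, plate_id: str = ""
) -> ChemotaxisCounts:
    """Binomial plate assay: each worm ends on the test side w.p. ``p_test``."""
    if not (0.0 <= p_test <= 1.0):
        raise InvalidArgumentError("p_test must lie in [0, 1]")
    if n_worms < 1:
        raise InvalidArgumentError("n_worms must be >= 1")
    rng = np.random.default_rng(seed)
    n_test = int(rng.binomial(n_worms, p_test))
    return ChemotaxisCounts(n_test=n_test, n_control=n_worms - n_test, plate_id=plate_id)
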