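"""Gas-delivery stimulus protocols.

A recording (imaging or behavior) is structured as an ordered sequence of gas
segments: an air pre-pulse, a stimulus pulse (CO2, or air for the matched
control), and a post-stimulus air period.  All downstream analysis windows
(baseline, response, early/late speed windows) are anchored to the pulse onset
and offset defined here.  Windows throughout the package are half-open
``[start_s, end_s)`` against frame timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["GasSegment", "StimulusProtocol", "make_protocol"]

#: Gas mixture used for the behavioral CO2 pulse.
BEHAVIOR_CO2 = "2.5% CO2, 21% O2, balance N2"
#: Gas mixture used for the imaging CO2 pulse.
IMAGING_CO2 = "15% CO2"
#: Control gas.
AIR = "21% O2, balance N2"


@dataclass(frozen=True)
class GasSegment:
    """One contiguous gas-delivery segment.

    Parameters
    ----------
    label
        ``"air"`` or ``"CO2"``.
    composition
        Free-text gas mixture tag (e.g. ``"2.5% CO2, 21% O2, balance N2"``).
    start_s, end_s
        Segment boundaries in seconds from recording start; half-open
        ``[start_s, end_s)``.
    """

    label: str
    composition: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in ("air", "CO2"):
            raise InvalidArgumentError(f"segment label must be 'air' or 'CO2', got {self.label!r}")
        if not (self.start_s < self.end_s):
            raise InvalidArgumentError(
                f"segment must have start_s < end_s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class StimulusProtocol:
    """A full gas-delivery protocol sampled at a fixed frame rate.

    Invariants: segments are contiguous and non-overlapping, the first starts
    at 0, and a standard pulse protocol has exactly one CO2 segment (an
    air-control protocol has none).
    """

    frame_rate: float
    segments: tuple[GasSegment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isfinite(self.frame_rate) or self.frame_rate <= 0:
            raise InvalidArgumentError(f"frame_rate must be positive, got {self.frame_rate}")
        if not self.segments:
            raise InvalidArgumentError("protocol needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.segments[0].start_s != 0:
            raise InvalidArgumentError("first segment must start at 0 s")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start_s != prev.end_s:
                raise InvalidArgumentError(
                    f"segments must be contiguous: {prev.end_s} != {cur.start_s}"
                )
        if sum(s.label == "CO2" for s in self.segments) > 1:
            raise InvalidArgumentError("at most one CO2 segment per protocol")

    # -- geometry ---------------------------------------------------------

    @property
    def duration_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame i at ``i / frame_rate``)."""
        return np.arange(self.n_frames) / self.frame_rate

    # -- pulse anchors ----------------------------------------------------

    @property
    def pulse(self) -> GasSegment | None:
        """The CO2 segment, or ``None`` for an air-control protocol."""
        for s in self.segments:
            if s.label == "CO2":
                return s
        return None

    @property
    def is_air_control(self) -> bool:
        return self.pulse is None

    @property
    def pulse_onset_s(self) -> float:
        """Onset of the stimulus pulse (middle segment for air controls).

        Air-control protocols built by :func:`make_protocol` keep the same
        three-segment geometry, so the matched clock windows of the control
        condition are anchored to the middle segment.
        """
        if self.pulse is not None:
            return self.pulse.start_s
        if len(self.segments) == 3:
            return self.segments[1].start_s
        raise InvalidArgumentError("protocol has no pulse segment to anchor windows to")

    @property
    def pulse_offset_s(self) -> float:
        if self.pulse is not None:
            return self.pulse.end_s
        if len(self.segments) == 3:
            return self.segments[1].end_s
        raise InvalidArgumentError("protocol has no pulse segment to anchor windows to")

    def frame_in_pulse(self) -> np.ndarray:
        """Boolean mask of frames inside the half-open pulse window."""
        t = self.times()
        return (t >= self.pulse_onset_s) & (t < self.pulse_offset_s)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "frame_rate": self.frame_rate,
            "segments": [
                {"label": s.label, "composition": s.composition, "start_s": s.start_s, "end_s": s.end_s}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            frame_rate=float(d["frame_rate"]),
            segments=tuple(
                GasSegment(s["label"], s.get("composition", ""), float(s["start_s"]), float(s["end_s"]))
                for s in d["segments"]
            ),
        )


def make_protocol(
    pre_s: float,
    pulse_s: float,
    post_s: float,
    frame_rate: float = 5.0,
    pulse_label: str = "CO2",
    pulse_composition: str | None = None,
) -> StimulusProtocol:
    """Build the standard three-segment protocol: air, pulse, air.

    ``pulse_label="air"`` produces the matched air-control protocol with
    identical segment boundaries.

    Parameters
    ----------
    pre_s, pulse_s, post_s
        Durations (seconds) of the air pre-pulse, the stimulus pulse, and the
        post-stimulus air period.  All must be positive.
    frame_rate
        Acquisition rate in frames/s.
    pulse_label
        ``"CO2"`` for a stimulus protocol, ``"air"`` for the control.
    pulse_composition
        Gas mixture tag for the pulse; defaults to the behavioral CO2 mix for
        a CO2 pulse and plain air otherwise.
    """
    for name, v in (("pre_s", pre_s), ("pulse_s", pulse_s), ("post_s", post_s), ("frame_rate", frame_rate)):
        if not np.isfinite(v) or v <= 0:
            raise InvalidArgumentError(f"{name} must be positive, got {v}")
    if pulse_composition is None:
        pulse_composition = BEHAVIOR_CO2 if pulse_label == "CO2" else AIR
    segments = (
        GasSegment("air", AIR, 0.0, pre_s),
        GasSegment(pulse_label, pulse_composition, pre_s, pre_s + pulse_s),
        GasSegment("air", AIR, pre_s + pulse_s, pre_s + pulse_s + post_s),
    )
    return StimulusProtocol(frame_rate=frame_rate, segments=segments)
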