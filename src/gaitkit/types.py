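"""Shared domain types: recordings, gait events, parameter containers."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Canonical smartphone channel order: triaxial acceleration, triaxial
#: angular velocity, rotation angles around the Z/X/Y axes.
CHANNEL_NAMES = ("Ax", "Ay", "Az", "Gx", "Gy", "Gz", "Yaw", "Pitch", "Roll")

#: Channels whose variation during walking is small relative to the rest and
#: that are dropped before model training (vertical-ish acceleration,
#: medio-lateral angular velocity, pitch angle for a thigh-mounted phone).
DEFAULT_EXCLUDED_CHANNELS = frozenset({"Az", "Gx", "Pitch"})


class EventKind(str, enum.Enum):
    HEEL_STRIKE = "HS"
    TOE_OFF = "TO"


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A typed gait instant: heel strike or toe off, in seconds."""

    time_s: float
    kind: EventKind

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"event time must be >= 0, got {self.time_s}")


@dataclass
class SignalRecording:
    """One walking trial: 50 Hz multichannel sensor series plus ground truth.

    Parameters
    ----------
    fs_hz
        Sampling rate in Hz.
    channels
        Mapping channel name -> 1-D float array; all series share one length.
    stance_ref
        Optional binary reference (1 = stance, 0 = swing), e.g. from an
        insole pressure sensor or the simulator's ground truth.
    true_events
        Optional exact event times (real-valued, sub-sample) when known.
    meta
        Free-form trial metadata (subject id, age group, speed condition,
        task STW/VFT/PTW, ...).
    """

    fs_hz: float
    channels: dict[str, np.ndarray]
    stance_ref: np.ndarray | None = None
    true_events: list[GaitEvent] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channel series have unequal lengths: {lengths}")
        if self.stance_ref is not None:
            self.stance_ref = np.asarray(self.stance_ref)
            if len(self.stance_ref) != self.n_samples:
                raise ValueError("stance_ref length differs from channels")
            bad = set(np.unique(self.stance_ref)) - {0, 1}
            if bad:
                raise ValueError(f"stance_ref values outside {{0,1}}: {bad}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def t(self) -> np.ndarray:
        """Time vector in seconds (uniform grid, t[0] = 0)."""
        return np.arange(self.n_samples) / self.fs_hz

    def channel_matrix(self) -> np.ndarray:
        """Stack channels into an (n_samples, n_channels) matrix."""
        return np.column_stack([self.channels[c] for c in self.channels])


@dataclass
class GaitParameters:
    """Per-trial means of the eight spatiotemporal gait parameters."""

    cadence_spm: float
    stride_time_s: float
    stance_phase_pct: float
    swing_phase_pct: float
    stance_time_s: float
    swing_time_s: float
    stride_length_m: float
    walking_speed_mps: float
    n_cycles: int = 0
    n_skipped: int = 0

    FIELDS = (
        "cadence_spm",
        "stride_time_s",
        "stance_phase_pct",
        "swing_phase_pct",
        "stance_time_s",
        "swing_time_s",
        "stride_length_m",
        "walking_speed_mps",
    )

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}
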