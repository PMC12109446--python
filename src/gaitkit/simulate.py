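"""Synthetic thigh-IMU gait recordings with exact ground-truth events.

The generator emulates the statistical structure of 50 Hz smartphone
recordings from a thigh-mounted phone during straight-line walking: six of
the nine channels carry gait-locked periodic components (harmonics of the
stride frequency, phase-locked to heel strike) plus impact/swing-initiation
transients, sensor noise and slow drift, while Az, Gx and Pitch show only
small-amplitude variation.  A binary stance/swing trace (the stand-in for an
insole pressure reference) and the exact real-valued event times are carried
alongside the signals, so event-timing error can be measured to sub-sample
precision downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil

import numpy as np

from .types import CHANNEL_NAMES, EventKind, GaitEvent, SignalRecording

#: Cadence / stride-length multipliers per self-selected speed condition,
#: plus a noise multiplier: slow and fast walking are noisier for built-in
#: phone sensors, which makes those conditions measurably harder.
SPEED_CONDITIONS = {
    "low": {"tempo": 0.8, "noise": 1.5},
    "normal": {"tempo": 1.0, "noise": 1.0},
    "high": {"tempo": 1.25, "noise": 1.5},
}

#: Dual-task adjustments: cognitive load (VFT, verbal fluency while walking)
#: slows cadence, lengthens the stance phase and raises cycle-to-cycle
#: jitter; the physical dual task (PTW, carrying a tray) does the same more
#: mildly.  Magnitudes follow published single- vs dual-task contrasts in
#: elderly walkers.
TASK_ADJUSTMENTS = {
    "STW": {"tempo": 1.0, "stance_shift": 0.0, "jitter": 0.0},
    "VFT": {"tempo": 0.842, "stance_shift": 0.042, "jitter": 0.02},
    "PTW": {"tempo": 0.914, "stance_shift": 0.027, "jitter": 0.012},
}

AGE_GROUPS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")

# Per-channel harmonic amplitude and phase tables for the six informative
# channels (3 harmonics of the stride frequency each).  Values are fixed
# design constants in sensor units; subject-to-subject variability rescales
# them mildly.  Ay additionally carries a heel-strike impact bump, Gz (and
# more weakly Gy) a swing-initiation bump at toe off.
_HARMONICS = {
    "Ax": ((0.8, 0.4, 0.15), (0.0, 1.1, 2.3)),
    "Ay": ((1.5, 0.7, 0.30), (1.7, 0.4, 2.9)),
    "Gy": ((1.8, 0.5, 0.20), (0.9, 2.2, 0.5)),
    "Gz": ((1.2, 0.6, 0.25), (2.5, 1.3, 0.7)),
    "Yaw": ((1.0, 0.3, 0.10), (0.3, 1.9, 1.2)),
    "Roll": ((1.4, 0.5, 0.20), (2.0, 0.8, 2.6)),
}
_QUIET_CHANNELS = ("Az", "Gx", "Pitch")
_QUIET_SD = 0.10  # keeps var(quiet) well under 10% of the informative minimum

_HS_BUMP = {"Ay": (2.5, 0.040), "Ax": (0.8, 0.040)}  # amplitude, width (s)
_TO_BUMP = {"Gz": (2.0, 0.050), "Gy": (0.8, 0.050)}


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of one simulated walking trial.

    cadence_spm is in steps/minute; with two steps per stride the implied
    stride time is 120 / cadence_spm seconds.  ``asymmetry`` scales
    cycle-to-cycle stride-time jitter (SD as a fraction of the stride time).
    ``lead_in_s`` is the stretch of swing recorded before the first heel
    strike, as when recording starts before walking does.
    """

    cadence_spm: float = 100.0
    stance_fraction: float = 0.60
    speed_condition: str = "normal"
    task: str = "STW"
    stride_length_m: float = 1.2
    n_cycles: int = 6
    asymmetry: float = 0.0
    noise_sd: float = 0.05
    drift_sd: float = 0.002
    lead_in_s: float = 0.0
    fs_hz: float = 50.0
    seed: int = 0
    subject_id: str = "S000"
    age_group: str = "20-29"

    def __post_init__(self) -> None:
        if self.cadence_spm <= 0:
            raise ValueError(f"cadence must be positive, got {self.cadence_spm}")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError(
                f"stance_fraction must lie in (0, 1), got {self.stance_fraction}"
            )
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.noise_sd < 0 or self.drift_sd < 0 or self.asymmetry < 0:
            raise ValueError("noise_sd, drift_sd and asymmetry must be >= 0")
        if self.speed_condition not in SPEED_CONDITIONS:
            raise ValueError(f"unknown speed condition {self.speed_condition!r}")
        if self.task not in TASK_ADJUSTMENTS:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def stride_time_s(self) -> float:
        """Nominal stride time after speed and task tempo adjustments."""
        tempo = SPEED_CONDITIONS[self.speed_condition]["tempo"]
        tempo *= TASK_ADJUSTMENTS[self.task]["tempo"]
        return 120.0 / (self.cadence_spm * tempo)

    @property
    def effective_stance_fraction(self) -> float:
        sf = self.stance_fraction + TASK_ADJUSTMENTS[self.task]["stance_shift"]
        return min(sf, 0.95)


def _event_times(profile: GaitProfile, rng: np.random.Generator):
    """Real-valued heel-strike / toe-off times, with optional jitter."""
    stride = profile.stride_time_s
    jitter_sd = profile.asymmetry + TASK_ADJUSTMENTS[profile.task]["jitter"]
    factors = 1.0 + jitter_sd * rng.standard_normal(profile.n_cycles)
    factors = np.clip(factors, 0.5, 1.5)
    strides = stride * factors
    hs = profile.lead_in_s + np.concatenate([[0.0], np.cumsum(strides)])
    to = hs[:-1] + profile.effective_stance_fraction * strides
    return hs, to, strides


def generate_recording(profile: GaitProfile) -> SignalRecording:
    """Simulate one trial from a :class:`GaitProfile`.

    Returns a :class:`SignalRecording` whose ``stance_ref`` is 1 on
    [t_HS(i), t_TO(i)) and 0 elsewhere (sample k covering time k/fs), and
    whose ``true_events`` alternate HEEL_STRIKE / TOE_OFF starting with the
    first heel strike.  Deterministic for a fixed profile (seed included).
    """
    rng = np.random.default_rng(profile.seed)
    hs, to, strides = _event_times(profile, rng)
    duration = hs[-1]  # closing heel strike ends the last cycle
    fs = profile.fs_hz
    n = ceil(duration * fs - 1e-9)  # guard against float round-up at exact grid
    t = np.arange(n) / fs

    # stride phase in [0, 1), phase-locked to the current cycle's heel strike
    cycle_idx = np.clip(np.searchsorted(hs, t, side="right") - 1, 0, len(strides) - 1)
    phase = (t - hs[cycle_idx]) / strides[cycle_idx]
    in_walk = t >= hs[0]

    stance = np.zeros(n, dtype=np.int8)
    for h, o in zip(hs[:-1], to):
        stance[(t >= h) & (t < o)] = 1

    noise_mult = SPEED_CONDITIONS[profile.speed_condition]["noise"]
    channels: dict[str, np.ndarray] = {}
    for name in CHANNEL_NAMES:
        if name in _HARMONICS:
            amps, phases = _HARMONICS[name]
            scale = rng.uniform(0.85, 1.15)  # subject-to-subject variability
            y = np.zeros(n)
            for k, (a, p) in enumerate(zip(amps, phases), start=1):
                y += scale * a * np.cos(2 * np.pi * k * phase + p)
            y *= in_walk
            if name in _HS_BUMP:
                amp, width = _HS_BUMP[name]
                for h in hs[:-1]:
                    y += amp * np.exp(-0.5 * ((t - h) / width) ** 2)
            if name in _TO_BUMP:
                amp, width = _TO_BUMP[name]
                for o in to:
                    y += amp * np.exp(-0.5 * ((t - o) / width) ** 2)
            y += noise_mult * profile.noise_sd * rng.standard_normal(n)
        else:
            y = _QUIET_SD * rng.standard_normal(n)
        y += np.cumsum(profile.drift_sd * rng.standard_normal(n))
        channels[name] = y

    events = []
    for h, o in zip(hs[:-1], to):
        events.append(GaitEvent(h, EventKind.HEEL_STRIKE))
        events.append(GaitEvent(o, EventKind.TOE_OFF))

    meta = {
        "subject_id": profile.subject_id,
        "age_group": profile.age_group,
        "speed_condition": profile.speed_condition,
        "task": profile.task,
        "stride_length_m": profile.stride_length_m,
        "cadence_spm": 120.0 / np.mean(strides),
    }
    return SignalRecording(
        fs_hz=fs, channels=channels, stance_ref=stance, true_events=events, meta=meta
    )


#: Default per-subject parameter ranges for cohort generation (uniform draws).
DEFAULT_PROFILE_RANGES = {
    "cadence_spm": (95.0, 115.0),
    "stance_fraction": (0.58, 0.62),
    "n_cycles": 6,
    "noise_sd": 0.05,
    "drift_sd": 0.002,
    "asymmetry": 0.01,
    "lead_in_s": 0.3,
}

#: Stride length grows linearly with stride frequency (faster cadence, longer
#: steps); these coefficients place typical elderly walkers near 1.2 m at a
#: 1.18 s stride.
STRIDE_LENGTH_LAW = {"intercept_m": 0.30, "slope_m_s": 1.05, "noise_sd": 0.03}


def draw_profile(
    rng: np.random.Generator,
    subject_id: str,
    age_group: str,
    ranges: dict | None = None,
    speed_condition: str = "normal",
    task: str = "STW",
) -> GaitProfile:
    """Draw one subject profile from uniform parameter ranges."""
    r = dict(DEFAULT_PROFILE_RANGES)
    if ranges:
        r.update(ranges)
    lo, hi = r["cadence_spm"]
    if lo > hi:
        raise ValueError("empty cadence range")
    cadence = rng.uniform(lo, hi)
    lo, hi = r["stance_fraction"]
    if lo > hi:
        raise ValueError("empty stance_fraction range")
    stance = rng.uniform(lo, hi)
    stride_freq = cadence / 120.0
    stride_length = (
        STRIDE_LENGTH_LAW["intercept_m"]
        + STRIDE_LENGTH_LAW["slope_m_s"] * stride_freq
        + STRIDE_LENGTH_LAW["noise_sd"] * rng.standard_normal()
    )
    return GaitProfile(
        cadence_spm=cadence,
        stance_fraction=stance,
        speed_condition=speed_condition,
        task=task,
        stride_length_m=float(np.clip(stride_length, 0.2, 2.5)),
        n_cycles=int(r["n_cycles"]),
        asymmetry=float(r["asymmetry"]),
        noise_sd=float(r["noise_sd"]),
        drift_sd=float(r["drift_sd"]),
        lead_in_s=float(r["lead_in_s"]),
        seed=int(rng.integers(0, 2**31 - 1)),
        subject_id=subject_id,
        age_group=age_group,
    )


def generate_cohort(
    n_subjects: int,
    profile_ranges: dict | None = None,
    seed: int = 0,
    speed_conditions: tuple[str, ...] = ("normal",),
    task: str = "STW",
) -> list[SignalRecording]:
    """Generate a cohort, one recording per subject and speed condition.

    Subjects cycle through the six decade age bands (20-29 ... 70-79) so a
    cohort of 150 stratifies into 6 groups of 25.  Deterministic under seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    recordings = []
    for i in range(n_subjects):
        age_group = AGE_GROUPS[i % len(AGE_GROUPS)]
        profile = draw_profile(
            rng, subject_id=f"S{i:03d}", age_group=age_group, ranges=profile_ranges
        )
        for cond in speed_conditions:
            rec_profile = replace(profile, speed_condition=cond)
            recordings.append(generate_recording(rec_profile))
    return recordings


def generate_task_pair(
    n_subjects: int,
    tasks: tuple[str, ...] = ("STW", "VFT"),
    profile_ranges: dict | None = None,
    seed: int = 0,
) -> dict[str, list[SignalRecording]]:
    """Paired single-task / dual-task recordings from the same subjects.

    Each subject keeps one base profile; the task adjustment (tempo, stance
    shift, jitter) is the only systematic difference between conditions, so
    downstream paired comparisons measure exactly the dual-task effect.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[SignalRecording]] = {task: [] for task in tasks}
    for i in range(n_subjects):
        age_group = AGE_GROUPS[i % len(AGE_GROUPS)]
        profile = draw_profile(
            rng, subject_id=f"S{i:03d}", age_group=age_group, ranges=profile_ranges
        )
        for task in tasks:
            out[task].append(generate_recording(replace(profile, task=task)))
    return out
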