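"""Spatiotemporal gait parameters from event sequences.

A gait cycle is the heel-strike-to-heel-strike interval of the instrumented
leg; the toe off inside it splits stance from swing.  Per cycle:

    stride_time  = HS_end − HS_start
    stance_time  = TO − HS_start          swing_time = HS_end − TO
    stance phase = 100 · stance_time / stride_time   (swing = 100 − stance)
    cadence      = 120 / stride_time      (two steps per stride)

Stride length is not observable from a thigh sensor alone; it is estimated
by a calibrated linear model on stride frequency (1/stride_time), and
walking speed follows as stride_length / stride_time.  Regressing on
frequency rather than on speed avoids the circularity speed = length/time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .types import EventKind, GaitEvent, GaitParameters

STRIDE_LENGTH_CLIP_M = (0.2, 2.5)


@dataclass(frozen=True)
class GaitCycle:
    hs_start: float
    to: float
    hs_end: float

    def __post_init__(self) -> None:
        if not self.hs_start < self.to < self.hs_end:
            raise ValueError(
                f"cycle must satisfy hs_start < to < hs_end, got "
                f"({self.hs_start}, {self.to}, {self.hs_end})"
            )

    @property
    def stride_time_s(self) -> float:
        return self.hs_end - self.hs_start

    @property
    def stance_time_s(self) -> float:
        return self.to - self.hs_start

    @property
    def swing_time_s(self) -> float:
        return self.hs_end - self.to


@dataclass
class StrideLengthModel:
    """Linear stride-length estimate from stride frequency (Hz).

    predict(f) = intercept_m + slope_m_s · f, clipped to a plausible
    human range.  ``calibration`` stores the fit summary (n, residual SD,
    coefficient standard errors).
    """

    intercept_m: float
    slope_m_s: float
    calibration: dict = field(default_factory=dict)

    def predict(self, stride_frequency_hz: float | np.ndarray) -> np.ndarray:
        pred = self.intercept_m + self.slope_m_s * np.asarray(stride_frequency_hz)
        return np.clip(pred, *STRIDE_LENGTH_CLIP_M)


#: Default coefficients, calibrated on the simulator's generative law
#: (stride_length = 0.30 + 1.05 · f); re-calibratable via
#: :func:`fit_stride_length_model`.
DEFAULT_STRIDE_LENGTH_MODEL = StrideLengthModel(intercept_m=0.30, slope_m_s=1.05)


def segment_cycles(events: list[GaitEvent]) -> tuple[list[GaitCycle], int]:
    """Group sorted events into (HS, TO, HS) cycles.

    Stretches that break the HS→TO→HS pattern (missing toe off, doubled
    heel strike, toe off before the stride closes) are skipped and counted.
    Returns (cycles, n_skipped).
    """
    hs_times = [e.time_s for e in events if e.kind == EventKind.HEEL_STRIKE]
    cycles: list[GaitCycle] = []
    skipped = 0
    for start, end in zip(hs_times[:-1], hs_times[1:]):
        inside = [
            e.time_s
            for e in events
            if e.kind == EventKind.TOE_OFF and start < e.time_s < end
        ]
        if len(inside) == 1:
            cycles.append(GaitCycle(start, inside[0], end))
        else:
            skipped += 1
    return cycles, skipped


def compute_parameters(
    cycles: list[GaitCycle],
    stride_length_model: StrideLengthModel | None = None,
    n_skipped: int = 0,
) -> GaitParameters:
    """Per-trial means of the eight gait parameters over complete cycles."""
    if not cycles:
        raise ValueError("at least one complete gait cycle is required")
    model = stride_length_model or DEFAULT_STRIDE_LENGTH_MODEL
    stride = np.asarray([c.stride_time_s for c in cycles])
    stance = np.asarray([c.stance_time_s for c in cycles])
    swing = np.asarray([c.swing_time_s for c in cycles])
    if np.any(stride <= 0):
        raise ValueError("zero-duration cycle")
    stance_pct = 100.0 * stance / stride
    length = model.predict(1.0 / stride)
    speed = length / stride
    return GaitParameters(
        cadence_spm=float(np.mean(120.0 / stride)),
        stride_time_s=float(np.mean(stride)),
        stance_phase_pct=float(np.mean(stance_pct)),
        swing_phase_pct=float(np.mean(100.0 - stance_pct)),
        stance_time_s=float(np.mean(stance)),
        swing_time_s=float(np.mean(swing)),
        stride_length_m=float(np.mean(length)),
        walking_speed_mps=float(np.mean(speed)),
        n_cycles=len(cycles),
        n_skipped=n_skipped,
    )


def parameters_from_events(
    events: list[GaitEvent],
    stride_length_model: StrideLengthModel | None = None,
) -> GaitParameters:
    cycles, skipped = segment_cycles(events)
    return compute_parameters(cycles, stride_length_model, n_skipped=skipped)


def fit_stride_length_model(
    stride_frequencies_hz: np.ndarray, stride_lengths_m: np.ndarray
) -> StrideLengthModel:
    """Ordinary least squares of stride length on stride frequency."""
    f = np.asarray(stride_frequencies_hz, dtype=float)
    y = np.asarray(stride_lengths_m, dtype=float)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if len(np.unique(f)) < 2:
        raise ValueError("need >= 2 distinct stride frequencies to fit")
    design = sm.add_constant(f)
    fit = sm.OLS(y, design).fit()
    return StrideLengthModel(
        intercept_m=float(fit.params[0]),
        slope_m_s=float(fit.params[1]),
        calibration={
            "n": int(fit.nobs),
            "residual_sd": float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0,
            "intercept_se": float(fit.bse[0]),
            "slope_se": float(fit.bse[1]),
            "r_squared": float(fit.rsquared),
        },
    )
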