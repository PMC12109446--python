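"""From stance-probability traces to discrete gait events and timing error.

A model's output trace in [0, 1] is thresholded at 0.5 and debounced
(phases shorter than a physiologic minimum are merged away); heel strikes
are 0→1 transitions of the binary trace, toe offs are 1→0 transitions,
each timestamped at the first sample of the new phase.  Detected events
are greedily matched to reference events of the same kind and the mean
absolute timing difference is reported in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import EventKind, GaitEvent


def binarize_trace(
    trace: np.ndarray,
    threshold: float = 0.5,
    min_phase_ms: float = 100.0,
    fs_hz: float = 50.0,
) -> np.ndarray:
    """Threshold a probability trace and remove implausibly short phases.

    Debouncing flips any run of constant value shorter than ``min_phase_ms``
    into its neighbours, processing the leftmost offending run first, until
    every remaining run meets the minimum (or a single run is left).
    """
    trace = np.asarray(trace, dtype=float)
    if np.any((trace < 0) | (trace > 1)):
        raise ValueError("trace values must lie in [0, 1]")
    binary = (trace >= threshold).astype(np.int8)
    min_len = int(np.ceil(min_phase_ms * fs_hz / 1000.0))
    if min_len <= 1 or len(binary) == 0:
        return binary
    while True:
        runs = _runs(binary)
        if len(runs) <= 1:
            break
        short = [(s, e) for s, e in runs if e - s < min_len]
        if not short:
            break
        s, e = short[0]
        binary[s:e] ^= 1
    return binary


def _runs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of constant value."""
    if len(binary) == 0:
        return []
    edges = np.flatnonzero(np.diff(binary)) + 1
    bounds = np.concatenate([[0], edges, [len(binary)]])
    return list(zip(bounds[:-1], bounds[1:]))


def extract_events(
    binary: np.ndarray, fs_hz: float = 50.0, t0: float = 0.0
) -> list[GaitEvent]:
    """Emit one event per transition of a binary stance trace.

    A 0→1 transition is a heel strike, 1→0 a toe off; the timestamp is the
    time of the first sample of the new phase (first-contact semantics).
    Constant input yields no events.
    """
    binary = np.asarray(binary)
    bad = set(np.unique(binary)) - {0, 1}
    if bad:
        raise ValueError(f"binary trace contains values outside {{0,1}}: {bad}")
    diffs = np.diff(binary.astype(np.int8))
    events = []
    for i in np.flatnonzero(diffs):
        kind = EventKind.HEEL_STRIKE if diffs[i] > 0 else EventKind.TOE_OFF
        events.append(GaitEvent(t0 + (i + 1) / fs_hz, kind))
    return events


@dataclass
class EventTimingReport:
    """Matched event pairs and per-kind timing MAE in milliseconds."""

    matches: list[tuple[GaitEvent, GaitEvent, float]] = field(default_factory=list)
    unmatched_reference: int = 0
    spurious_predicted: int = 0

    def _abs_ms(self, kind: EventKind) -> np.ndarray:
        return np.asarray([d for r, _, d in self.matches if r.kind == kind])

    def signed_differences_ms(self, kind: EventKind | None = None) -> np.ndarray:
        """Signed (predicted − reference) differences in ms."""
        return np.asarray(
            [
                (p.time_s - r.time_s) * 1000.0
                for r, p, _ in self.matches
                if kind is None or r.kind == kind
            ]
        )

    def mae_ms(self, kind: EventKind) -> float:
        d = self._abs_ms(kind)
        return float(np.mean(d)) if len(d) else float("nan")

    def sd_ms(self, kind: EventKind) -> float:
        d = self._abs_ms(kind)
        return float(np.std(d, ddof=1)) if len(d) > 1 else float("nan")

    def n_matches(self, kind: EventKind | None = None) -> int:
        if kind is None:
            return len(self.matches)
        return sum(1 for r, _, _ in self.matches if r.kind == kind)

    def summary(self) -> dict:
        return {
            "heel_strike": {
                "mae_ms": self.mae_ms(EventKind.HEEL_STRIKE),
                "sd_ms": self.sd_ms(EventKind.HEEL_STRIKE),
                "n": self.n_matches(EventKind.HEEL_STRIKE),
            },
            "toe_off": {
                "mae_ms": self.mae_ms(EventKind.TOE_OFF),
                "sd_ms": self.sd_ms(EventKind.TOE_OFF),
                "n": self.n_matches(EventKind.TOE_OFF),
            },
            "unmatched_reference": self.unmatched_reference,
            "spurious_predicted": self.spurious_predicted,
        }


def match_and_score(
    reference: list[GaitEvent],
    predicted: list[GaitEvent],
    max_gap_ms: float = 250.0,
) -> EventTimingReport:
    """Greedy nearest-neighbour matching of same-kind events.

    Candidate pairs within ``max_gap_ms`` are taken in order of increasing
    |Δt|, each event used at most once; kinds are never cross-matched.
    Unmatched and spurious events are counted but excluded from the MAE.
    """
    report = EventTimingReport()
    matched_ref: set[int] = set()
    matched_pred: set[int] = set()
    candidates = []
    for i, r in enumerate(reference):
        for j, p in enumerate(predicted):
            if r.kind != p.kind:
                continue
            dt_ms = abs(p.time_s - r.time_s) * 1000.0
            if dt_ms <= max_gap_ms:
                candidates.append((dt_ms, i, j))
    for dt_ms, i, j in sorted(candidates):
        if i in matched_ref or j in matched_pred:
            continue
        matched_ref.add(i)
        matched_pred.add(j)
        report.matches.append((reference[i], predicted[j], dt_ms))
    report.matches.sort(key=lambda m: m[0].time_s)
    report.unmatched_reference = len(reference) - len(matched_ref)
    report.spurious_predicted = len(predicted) - len(matched_pred)
    return report


def merge_reports(reports: list[EventTimingReport]) -> EventTimingReport:
    """Pool matches and counts across trials."""
    out = EventTimingReport()
    for r in reports:
        out.matches.extend(r.matches)
        out.unmatched_reference += r.unmatched_reference
        out.spurious_predicted += r.spurious_predicted
    return out
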