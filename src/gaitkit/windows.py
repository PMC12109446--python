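"""Sliding-window dataset construction and train/validation/test splitting.

Each supervised pair is an (ω × C) window of preprocessed sensor samples
predicting the stance/swing label of the sample immediately after the
window: the first pair maps samples 1..ω to label ω+1, the last maps
samples n−ω..n−1 to label n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SignalRecording

DEFAULT_WINDOW = 40


@dataclass
class WindowPair:
    """One example: window X (ω × C) and the next-sample stance label Y."""

    X: np.ndarray
    Y: int
    subject_id: str
    index: int  # 0-based index of the window's first sample in its trial


@dataclass
class DatasetSplit:
    train: list[WindowPair]
    val: list[WindowPair]
    test: list[WindowPair]

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


def make_pairs(rec: SignalRecording, window: int = DEFAULT_WINDOW) -> list[WindowPair]:
    """Build the n − ω sliding-window pairs of one trial."""
    if rec.stance_ref is None:
        raise ValueError("recording has no stance reference labels")
    n = rec.n_samples
    if n <= window:
        raise ValueError(f"recording length {n} must exceed window {window}")
    mat = rec.channel_matrix()
    subject = str(rec.meta.get("subject_id", ""))
    labels = np.asarray(rec.stance_ref)
    return [
        WindowPair(X=mat[t : t + window], Y=int(labels[t + window]),
                   subject_id=subject, index=t)
        for t in range(n - window)
    ]


def _largest_remainder(total: int, fractions: tuple[float, float, float]) -> list[int]:
    exact = [f * total for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = total - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # largest remainder first
    for i in range(short):
        base[order[i]] += 1
    return base


def split_cohort(
    pairs_by_subject: dict[str, list[WindowPair]],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    unit: str = "by_subject",
    seed: int = 0,
    age_group_of: dict[str, str] | None = None,
) -> DatasetSplit:
    """Split pooled pairs 60/20/20, stratified within age group.

    ``by_subject`` (default) assigns whole subjects to one partition so no
    subject leaks across train/validation/test; ``by_pair`` shuffles and
    splits individual pairs.  Largest-remainder allocation, ties broken by
    subject id order; deterministic under seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if unit not in ("by_subject", "by_pair"):
        raise ValueError(f"unknown split unit {unit!r}")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for sid in sorted(pairs_by_subject):
        g = (age_group_of or {}).get(sid, "all")
        groups.setdefault(g, []).append(sid)

    train: list[WindowPair] = []
    val: list[WindowPair] = []
    test: list[WindowPair] = []
    for g in sorted(groups):
        sids = groups[g]
        if unit == "by_subject":
            order = list(rng.permutation(len(sids)))
            shuffled = [sids[i] for i in order]
            n_tr, n_va, n_te = _largest_remainder(len(sids), fractions)
            for part, chunk in zip(
                (train, val, test),
                (shuffled[:n_tr], shuffled[n_tr : n_tr + n_va], shuffled[n_tr + n_va :]),
            ):
                for sid in chunk:
                    part.extend(pairs_by_subject[sid])
        else:
            pooled = [p for sid in sids for p in pairs_by_subject[sid]]
            order = rng.permutation(len(pooled))
            n_tr, n_va, n_te = _largest_remainder(len(pooled), fractions)
            train.extend(pooled[i] for i in order[:n_tr])
            val.extend(pooled[i] for i in order[n_tr : n_tr + n_va])
            test.extend(pooled[i] for i in order[n_tr + n_va :])
    return DatasetSplit(train=train, val=val, test=test)


def stack_pairs(pairs: list[WindowPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into (N, ω, C) inputs and (N,) float labels."""
    X = np.stack([p.X for p in pairs]).astype(np.float64)
    y = np.asarray([p.Y for p in pairs], dtype=np.float64)
    return X, y
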