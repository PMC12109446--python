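"""End-to-end runs on the synthetic benchmark.

Ties the stages together: simulate a cohort, filter and normalize, build
sliding-window pairs, train a model, convert test-set probability traces to
events, and score event timing per speed condition.  Also hosts the
dual-task experiment (gait parameters from events, paired statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import events as ev
from . import params as gp
from . import simulate, stats, windows
from .config import PipelineConfig
from .models import TrainedModel, build_model, predict_trace, train
from .preprocess import Normalizer, preprocess_recording
from .types import EventKind, SignalRecording


def preprocess_cohort(
    recordings: list[SignalRecording], cfg: PipelineConfig
) -> list[SignalRecording]:
    return [preprocess_recording(r, cfg.filters) for r in recordings]


def split_recordings_by_subject(
    recordings: list[SignalRecording],
) -> dict[str, list[SignalRecording]]:
    by_subject: dict[str, list[SignalRecording]] = {}
    for rec in recordings:
        by_subject.setdefault(str(rec.meta.get("subject_id", "")), []).append(rec)
    return by_subject


@dataclass
class BenchmarkResult:
    model: TrainedModel
    split: windows.DatasetSplit
    test_recordings: list[SignalRecording]
    reports_by_speed: dict[str, ev.EventTimingReport] = field(default_factory=dict)

    def pooled_report(self) -> ev.EventTimingReport:
        return ev.merge_reports(list(self.reports_by_speed.values()))


def train_on_cohort(
    recordings: list[SignalRecording], cfg: PipelineConfig
) -> tuple[TrainedModel, windows.DatasetSplit, list[SignalRecording]]:
    """Preprocess, normalize, window, split and train on a cohort.

    Returns the trained model (carrying its normalizer), the window split,
    and the held-out test recordings (preprocessed and normalized).
    """
    processed = preprocess_cohort(recordings, cfg)
    by_subject = split_recordings_by_subject(processed)
    subject_ids = sorted(by_subject)

    # assign whole subjects to partitions before fitting normalization
    rng = np.random.default_rng(cfg.substream("split"))
    age_of = {
        sid: str(by_subject[sid][0].meta.get("age_group", "all"))
        for sid in subject_ids
    }
    groups: dict[str, list[str]] = {}
    for sid in subject_ids:
        groups.setdefault(age_of[sid], []).append(sid)
    train_ids, val_ids, test_ids = [], [], []
    for g in sorted(groups):
        sids = [groups[g][i] for i in rng.permutation(len(groups[g]))]
        n_tr, n_va, _ = windows._largest_remainder(len(sids), cfg.split_fractions)
        train_ids += sids[:n_tr]
        val_ids += sids[n_tr : n_tr + n_va]
        test_ids += sids[n_tr + n_va :]
    if not val_ids or not test_ids:
        # small cohorts: age-stratified allocation can starve a partition;
        # fall back to one global split
        sids = [subject_ids[i] for i in rng.permutation(len(subject_ids))]
        n_tr, n_va, _ = windows._largest_remainder(len(sids), cfg.split_fractions)
        train_ids = sids[:n_tr]
        val_ids = sids[n_tr : n_tr + n_va]
        test_ids = sids[n_tr + n_va :]

    normalizer = Normalizer.fit(
        [r for sid in train_ids for r in by_subject[sid]]
    )
    normalized = {
        sid: [normalizer.transform(r) for r in recs]
        for sid, recs in by_subject.items()
    }

    def pairs_of(sids: list[str]) -> list[windows.WindowPair]:
        return [
            p
            for sid in sids
            for rec in normalized[sid]
            for p in windows.make_pairs(rec, cfg.window)
        ]

    split = windows.DatasetSplit(
        train=pairs_of(train_ids), val=pairs_of(val_ids), test=pairs_of(test_ids)
    )
    model = build_model(
        cfg.model,
        in_channels=len(normalized[subject_ids[0]][0].channel_names),
        channel_names=normalized[subject_ids[0]][0].channel_names,
    )
    model.normalizer = normalizer
    train(model, split, cfg.model)
    test_recs = [r for sid in test_ids for r in normalized[sid]]
    return model, split, test_recs


def detect_events(
    model: TrainedModel, rec: SignalRecording, cfg: PipelineConfig
) -> list[ev.GaitEvent]:
    """Probability trace → binary trace → timestamped events for one trial."""
    trace = predict_trace(model, rec, cfg.window)
    binary = ev.binarize_trace(
        trace, cfg.events.threshold, cfg.events.min_phase_ms, rec.fs_hz
    )
    return ev.extract_events(binary, rec.fs_hz, t0=cfg.window / rec.fs_hz)


def evaluate_model(
    model: TrainedModel,
    test_recordings: list[SignalRecording],
    cfg: PipelineConfig,
) -> dict[str, ev.EventTimingReport]:
    """Per-speed-condition event-timing reports on held-out recordings.

    Reference events inside the first ω samples have no prediction window
    and are excluded from matching.
    """
    reports: dict[str, list[ev.EventTimingReport]] = {}
    horizon = cfg.window / cfg_fs(test_recordings)
    for rec in test_recordings:
        detected = detect_events(model, rec, cfg)
        reference = [e for e in (rec.true_events or []) if e.time_s >= horizon]
        report = ev.match_and_score(reference, detected, cfg.events.max_gap_ms)
        speed = str(rec.meta.get("speed_condition", "normal"))
        reports.setdefault(speed, []).append(report)
    return {speed: ev.merge_reports(rs) for speed, rs in reports.items()}


def cfg_fs(recordings: list[SignalRecording]) -> float:
    return recordings[0].fs_hz if recordings else 50.0


def run_event_benchmark(cfg: PipelineConfig) -> BenchmarkResult:
    """Simulate → preprocess → train → evaluate, all from one config."""
    cohort = simulate.generate_cohort(
        cfg.simulator.n_subjects,
        profile_ranges=cfg.simulator.profile_ranges or None,
        seed=cfg.substream("simulate"),
        speed_conditions=cfg.simulator.speed_conditions,
    )
    model, split, test_recs = train_on_cohort(cohort, cfg)
    result = BenchmarkResult(model=model, split=split, test_recordings=test_recs)
    result.reports_by_speed = evaluate_model(model, test_recs, cfg)
    return result


def benchmark_config(seed: int, n_subjects: int = 20) -> PipelineConfig:
    """The standard scaled-down synthetic benchmark configuration.

    20 subjects walking at all three self-selected speeds, window ω = 40,
    10 training epochs of the cross-attention model at reduced width
    (32 TCN channels / 32 GRU units) — sized so a full simulate→train→
    evaluate pass runs in minutes on one CPU while leaving a wide margin
    to the event-timing bounds it is checked against.
    """
    from .config import SimulatorConfig
    from .models import ModelConfig

    return PipelineConfig(
        seed=seed,
        window=40,
        simulator=SimulatorConfig(
            n_subjects=n_subjects, speed_conditions=("normal", "low", "high")
        ),
        model=ModelConfig(
            architecture="bitcn_bigru_crossattn",
            tcn_channels=32,
            gru_hidden=32,
            epochs=10,
            batch_size=128,
            seed=seed,
        ),
    )


def run_dual_task_experiment(
    n_subjects: int = 25,
    tasks: tuple[str, ...] = ("STW", "VFT"),
    seed: int = 0,
    stride_model: gp.StrideLengthModel | None = None,
) -> dict:
    """Paired single-task vs dual-task gait parameters and t tests.

    Gait parameters are computed per subject from each condition's event
    sequence; the paired comparison then mirrors a within-subject
    single-task vs dual-task design.
    """
    cohort = simulate.generate_task_pair(n_subjects, tasks=tasks, seed=seed)
    per_task_params: dict[str, list[dict]] = {}
    for task, recs in cohort.items():
        per_task_params[task] = [
            gp.parameters_from_events(r.true_events, stride_model).as_dict()
            for r in recs
        ]
    comparisons = {}
    base = tasks[0]
    for other in tasks[1:]:
        comparisons[f"{base}/{other}"] = stats.compare_conditions(
            per_task_params[base], per_task_params[other], base, other
        )
    return {"parameters": per_task_params, "comparisons": comparisons}
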