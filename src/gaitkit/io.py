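"""CSV/JSON readers and writers for recordings, events and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CHANNEL_NAMES, EventKind, GaitEvent, GaitParameters, SignalRecording


def write_recording_csv(rec: SignalRecording, path) -> None:
    """`time,Ax,...,Roll[,stance]` — one row per sample."""
    data = {"time": rec.t}
    for name in rec.channel_names:
        data[name] = rec.channels[name]
    if rec.stance_ref is not None:
        data["stance"] = rec.stance_ref.astype(int)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path, fs_hz: float | None = None,
                       meta: dict | None = None) -> SignalRecording:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    t = df["time"].to_numpy()
    if fs_hz is None:
        steps = np.diff(t)
        if len(steps) == 0 or np.ptp(steps) > 1e-6:
            raise ValueError(f"{path}: cannot infer a uniform sampling rate")
        fs_hz = 1.0 / steps[0]
    channel_cols = [c for c in df.columns if c not in ("time", "stance")]
    unknown = set(channel_cols) - set(CHANNEL_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown channels {sorted(unknown)}")
    channels = {c: df[c].to_numpy(dtype=float) for c in channel_cols}
    stance = df["stance"].to_numpy(dtype=int) if "stance" in df.columns else None
    return SignalRecording(
        fs_hz=fs_hz, channels=channels, stance_ref=stance, meta=dict(meta or {})
    )


def write_events_csv(events: list[GaitEvent], path) -> None:
    """`event_type,time_s` with event_type in {HS, TO}."""
    df = pd.DataFrame(
        {"event_type": [e.kind.value for e in events],
         "time_s": [e.time_s for e in events]}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_events_csv(path) -> list[GaitEvent]:
    df = pd.read_csv(path)
    return [
        GaitEvent(float(row.time_s), EventKind(row.event_type))
        for row in df.itertuples()
    ]


def write_cohort(recordings: list[SignalRecording], out_dir) -> Path:
    """Write per-trial recording + events CSVs and a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, rec in enumerate(recordings):
        sid = rec.meta.get("subject_id", f"S{i:03d}")
        cond = rec.meta.get("speed_condition", "normal")
        task = rec.meta.get("task", "STW")
        stem = f"{sid}_{task}_{cond}"
        rec_path = out_dir / f"{stem}.csv"
        write_recording_csv(rec, rec_path)
        entry = {"recording": rec_path.name, "fs_hz": rec.fs_hz, **rec.meta}
        if rec.true_events is not None:
            ev_path = out_dir / f"{stem}_events.csv"
            write_events_csv(rec.true_events, ev_path)
            entry["events"] = ev_path.name
        manifest.append(entry)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(cohort_dir) -> list[SignalRecording]:
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    recordings = []
    for entry in manifest:
        meta = {
            k: v for k, v in entry.items() if k not in ("recording", "events", "fs_hz")
        }
        rec = read_recording_csv(
            cohort_dir / entry["recording"], fs_hz=entry["fs_hz"], meta=meta
        )
        if "events" in entry:
            rec.true_events = read_events_csv(cohort_dir / entry["events"])
        recordings.append(rec)
    return recordings


def write_params_csv(rows: list[tuple[dict, GaitParameters]], path) -> None:
    """One row per trial: metadata plus the eight gait parameters."""
    records = []
    for meta, params in rows:
        rec = {
            "subject_id": meta.get("subject_id", ""),
            "task": meta.get("task", ""),
            "speed_condition": meta.get("speed_condition", ""),
            **params.as_dict(),
            "n_cycles": params.n_cycles,
            "n_skipped": params.n_skipped,
        }
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.4f")


def read_params_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
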