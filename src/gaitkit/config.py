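"""Pipeline configuration: one YAML/JSON document, one root seed.

All stage randomness flows from ``seed`` through named substreams
(simulate / split / train), so a single config reproduces a full
simulate → preprocess → train → evaluate → params → compare run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .models import ModelConfig
from .preprocess import FilterConfig


@dataclass
class SimulatorConfig:
    n_subjects: int = 150
    speed_conditions: tuple[str, ...] = ("normal", "low", "high")
    tasks: tuple[str, ...] = ("STW",)
    profile_ranges: dict = field(default_factory=dict)


@dataclass
class EventConfig:
    threshold: float = 0.5
    min_phase_ms: float = 100.0
    max_gap_ms: float = 250.0


@dataclass
class PipelineConfig:
    seed: int = 0
    window: int = 40
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_unit: str = "by_subject"
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    events: EventConfig = field(default_factory=EventConfig)
    stride_length: dict = field(
        default_factory=lambda: {"intercept_m": 0.30, "slope_m_s": 1.05}
    )

    def substream(self, name: str) -> int:
        """Derive a named child seed from the root seed (below 2**31)."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filters"]["excluded_channels"] = sorted(
            self.filters.excluded_channels
        )
        d["model"]["tcn_dilations"] = list(self.model.tcn_dilations)
        d["simulator"]["speed_conditions"] = list(self.simulator.speed_conditions)
        d["simulator"]["tasks"] = list(self.simulator.tasks)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulator", {})
        filt = d.pop("filters", {})
        model = d.pop("model", {})
        events = d.pop("events", {})
        if "speed_conditions" in sim:
            sim["speed_conditions"] = tuple(sim["speed_conditions"])
        if "tasks" in sim:
            sim["tasks"] = tuple(sim["tasks"])
        if "excluded_channels" in filt:
            filt["excluded_channels"] = frozenset(filt["excluded_channels"])
        if "tcn_dilations" in model:
            model["tcn_dilations"] = tuple(model["tcn_dilations"])
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(
            simulator=SimulatorConfig(**sim),
            filters=FilterConfig(**filt),
            model=ModelConfig(**model),
            events=EventConfig(**events),
            **d,
        )

    def save(self, path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=2))
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(doc)
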