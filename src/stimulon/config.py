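"""Pipeline configuration: one plain-text (YAML) file drives every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import Thresholds
from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    """Validated configuration for an end-to-end run.

    Either a ``simulate`` block (synthetic inputs) or explicit paths to an
    annotation (GFF3 + FASTA), a counts TSV with its library design, and a
    boxes TSV.  Thresholds default to the standard decision rule:
    |FC| >= 3 with p < 0.05.
    """

    seed: int
    output_dir: str = "stimulon_out"
    simulate: dict | None = None
    gff3: str | None = None
    fasta: str | None = None
    counts: str | None = None
    design: str | None = None
    boxes: str | None = None
    patterns: str | None = None
    qpcr: str | None = None
    thresholds: dict = field(default_factory=dict)
    operon_gap: int = 200
    upstream_window: int = 900
    mismatch_budget: int = 1

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed")
        th = self.make_thresholds()
        th.validate()
        if self.operon_gap < 0 or self.upstream_window < 1:
            raise ValueError("operon_gap must be >= 0, upstream_window >= 1")
        if self.mismatch_budget < 0:
            raise ValueError("mismatch_budget must be >= 0")
        if self.simulate is None:
            needed = ("gff3", "fasta", "counts", "design", "boxes")
            missing = [k for k in needed if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    "config needs either a simulate block or paths for: "
                    + ", ".join(missing))

    def make_thresholds(self) -> Thresholds:
        return Thresholds(**self.thresholds)

    def make_simulation_config(self) -> SimulationConfig:
        block = dict(self.simulate or {})
        block.pop("enabled", None)
        cfg = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in block.items()})
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
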