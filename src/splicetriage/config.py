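"""Pipeline configuration: every grading threshold and scan window in one place.

The defaults encode the published grading rules: a natural-site weakening is
severe when the 0-1 strength score drops by at least ``severe_drop`` (0.4) or
falls from at/above ``severe_floor`` to below it; a cryptic site is severe when
its mutant score exceeds ``cryptic_severe`` (0.4); score differences must
exceed ``reporting_delta`` (0.2) to be reported at all.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    severe_drop: float = 0.4          # rule (i): drop >= this is severe
    severe_floor: float = 0.4         # rule (i): crossing below this is severe
    cryptic_severe: float = 0.4       # rule (ii): mutant score > this is severe
    reporting_delta: float = 0.2      # only |delta| > this is reported
    natural_lost_floor: float = 0.1   # mutant natural-site score below this => "lost"
    creation_floor: float = 0.2       # WT score below this => a gain is "created"


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    splice_window: int = 200          # nt scanned either side of the edit
    sre_window: int = 100
    surrogate_threshold: float = 100.0  # Grantham distance at/above which a missense is severe
    stop_loss_class_row: str = "missense"  # summary row that stop-loss variants are folded into
    motif_table: str | None = None    # path overriding the packaged SRE table
    export_table: str | None = None   # path overriding the packaged export-element table

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
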