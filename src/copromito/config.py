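"""Pipeline configuration: every tunable threshold, stage toggles, seed.

The YAML round trip is strict: unknown keys are an error, so a typo in a
config file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

STAGES = (
    "preprocess",
    "align",
    "assign",
    "coassemble",
    "authenticate",
    "annotate",
    "phylo",
    "popgen",
    "radiocarbon",
)


@dataclass
class PipelineConfig:
    """All pipeline parameters with their documented defaults.

    Alignment: ``err`` (assumed per-base error) and ``miss_thres`` control
    the read-length-dependent edit-distance ceiling; ``max_gap_opens`` caps
    gap openings per alignment.  Consensus: a position is called only from
    ``min_concordant`` agreeing unique sequences; columns where more than
    ``dispute_frac`` of aligned read bases disagree are flagged.  The
    mapping-quality gate is ``mq_min`` (inclusive by default; set
    ``mq_strict`` for a strictly-greater gate).
    """

    seed: int = 0

    # preprocess
    min_read_len: int = 20
    qual_floor: int = 2
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

    # align
    err: float = 0.02
    miss_thres: float = 0.1
    max_gap_opens: int = 1
    seed_len: int = 12

    # coassembly
    mq_min: int = 25
    mq_strict: bool = False
    min_concordant: int = 2
    dispute_frac: float = 0.25
    damage_window: int = 10
    max_iterations: int = 5
    primer_margin: int = 25
    max_amplicon: int = 150

    # damage authentication
    fold_threshold: float = 3.0

    # phylo
    bootstrap_reps: int = 500

    # popgen
    min_depth: int = 2
    min_shared: int = 100

    # stage toggles
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.min_read_len >= 1, "min_read_len must be >= 1"),
            (0 < self.err < 1, "err must be in (0,1)"),
            (0 < self.miss_thres < 1, "miss_thres must be in (0,1)"),
            (self.max_gap_opens in (0, 1, 2), "max_gap_opens must be 0, 1 or 2"),
            (self.seed_len >= 4, "seed_len must be >= 4"),
            (0 <= self.mq_min <= 37, "mq_min must be in [0,37]"),
            (self.min_concordant >= 1, "min_concordant must be >= 1"),
            (0 < self.dispute_frac < 1, "dispute_frac must be in (0,1)"),
            (self.max_iterations >= 1, "max_iterations must be >= 1"),
            (self.bootstrap_reps >= 1, "bootstrap_reps must be >= 1"),
            (self.min_depth >= 1, "min_depth must be >= 1"),
            (self.fold_threshold > 0, "fold_threshold must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage names: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
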