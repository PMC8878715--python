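"""Pipeline configuration: thresholds, loci, scoring, seeds.

A single serializable object holds every tunable the pipeline stages
share; the manifest hash changes iff a semantic field changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .extract import DEFAULT_IG_LOCI, LocusInterval


@dataclass
class PipelineConfig:
    hexamer_trim_len: int = 6
    min_read_cov: int = 40
    min_v_identity: float = 95.0
    min_d_match: int = 8
    min_hit_score: int = 20
    um_threshold: int = 0
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    alpha: float = 0.05
    min_shift: float = 0.01
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    require_d: bool = True
    seed: int = 0
    loci: list[LocusInterval] = field(
        default_factory=lambda: list(DEFAULT_IG_LOCI)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.min_v_identity <= 100:
            raise ValueError("min_v_identity must be in [0, 100]")
        if self.min_read_cov < 1 or self.min_d_match < 1 or self.min_hit_score < 1:
            raise ValueError("coverage thresholds must be positive")
        if self.hexamer_trim_len < 0:
            raise ValueError("hexamer_trim_len must be >= 0")
        if not 0 <= self.fdr_threshold <= 1 or not 0 <= self.alpha <= 1:
            raise ValueError("fdr_threshold and alpha must be in [0, 1]")
        if self.fc_threshold < 0 or self.min_shift < 0:
            raise ValueError("fc_threshold and min_shift must be >= 0")
        if self.um_threshold < 0:
            raise ValueError("um_threshold must be >= 0")
        if self.match <= 0 or min(self.mismatch, self.gap_open,
                                  self.gap_extend) >= 0:
            raise ValueError("invalid alignment scoring")

    def scoring(self):
        from .align import AlignScoring
        return AlignScoring(self.match, self.mismatch,
                            self.gap_open, self.gap_extend)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loci"] = [asdict(l) for l in self.loci]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "loci" in data:
            data["loci"] = [LocusInterval(**l) for l in data["loci"]]
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
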