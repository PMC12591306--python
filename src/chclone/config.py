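"""Pipeline configuration.

Every numeric threshold used by the filtering, classification and
association stages lives here so a run is fully described by one YAML file
plus a seed.  Defaults are the study conditions this pipeline targets: a
0.5% VAF detection floor, germline cutoffs at 1% population AF and 35% VAF
(manual-review band above 20%), confidence cutoffs at >400x depth with >2
(SNV) / >5 (indel) alternate reads, a 10% cross-sample recurrence cap, a
7.4 GBq dose-group cutoff and a 50-year age split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # detection / filtering thresholds (strict inequalities throughout)
    vaf_floor: float = 0.005
    vaf_germline: float = 0.35
    vaf_review: float = 0.20
    popaf_max: float = 0.01
    min_depth_exclusive: int = 400
    min_alt_snv_exclusive: int = 2
    min_alt_indel_exclusive: int = 5
    recurrence_fraction: float = 0.10
    # sequence-bias tests
    alpha_orientation: float = 0.05
    alpha_strand: float = 0.01
    min_bias_imbalance: float = 0.90
    min_bias_count: int = 20
    mask_flank_bp: int = 5
    # cohort stratification
    dose_cutoff_gbq: float = 7.4
    dose_unit_gbq: float = 1.11
    age_split_years: float = 50.0
    # significance
    q_threshold: float = 0.10
    vaf_cutoffs: tuple = (0.005, 0.01, 0.02, 0.05)
    # reproducibility
    seed: int = 0
    # optional file paths (populated for CLI runs)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.vaf_floor < 1, "vaf_floor in (0,1)"),
            (0 < self.vaf_germline <= 1, "vaf_germline in (0,1]"),
            (0 < self.vaf_review <= self.vaf_germline,
             "vaf_review in (0, vaf_germline]"),
            (0 < self.popaf_max < 1, "popaf_max in (0,1)"),
            (self.min_depth_exclusive >= 0, "min_depth_exclusive >= 0"),
            (0 <= self.recurrence_fraction <= 1,
             "recurrence_fraction in [0,1]"),
            (0 < self.alpha_orientation < 1, "alpha_orientation in (0,1)"),
            (0 < self.alpha_strand < 1, "alpha_strand in (0,1)"),
            (0.5 <= self.min_bias_imbalance <= 1,
             "min_bias_imbalance in [0.5,1]"),
            (self.min_bias_count >= 0, "min_bias_count >= 0"),
            (self.mask_flank_bp >= 0, "mask_flank_bp >= 0"),
            (self.dose_cutoff_gbq > 0, "dose_cutoff_gbq > 0"),
            (self.dose_unit_gbq > 0, "dose_unit_gbq > 0"),
            (0 < self.q_threshold < 1, "q_threshold in (0,1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        self.vaf_cutoffs = tuple(float(c) for c in self.vaf_cutoffs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vaf_cutoffs"] = list(self.vaf_cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
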