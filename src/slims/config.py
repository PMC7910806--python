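"""Project configuration: file locations and workflow thresholds.

Defaults encode the workflow's operating points: a targeted locus is
recovered at >= 6x reference coverage and >= 350 bp assembled; a sample
fails sequencing when under 5% of scored loci are recovered; samples
yielding under 10 ng total DNA are excluded from submission; and the
per-genus sequencing goal is half of the accepted species.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class ProjectConfig:
    db_path: str = "project.slims.sqlite"

    # Locus-recovery QC
    coverage_min: float = 6.0
    length_min_bp: int = 350
    failure_fraction: float = 0.05  # strict: failed iff fraction < this

    # Sequencing submission
    yield_min_ng: float = 10.0
    quota_fraction: float = 0.5
    quota_mode: str = "species"  # or "samples"
    missing_yield_policy: str = "fatal"  # or "exclude"

    # ANOVA response: per-sample count of recovered loci, or the fraction
    anova_response: str = "count"  # or "fraction"
    family_table_min_n: int = 50

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProjectConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def __post_init__(self) -> None:
        if self.quota_mode not in ("species", "samples"):
            raise ValueError("quota_mode must be 'species' or 'samples'")
        if self.missing_yield_policy not in ("fatal", "exclude"):
            raise ValueError("missing_yield_policy must be 'fatal' or 'exclude'")
        if self.anova_response not in ("count", "fraction"):
            raise ValueError("anova_response must be 'count' or 'fraction'")
        if not 0 < self.failure_fraction < 1:
            raise ValueError("failure_fraction must lie in (0, 1)")
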