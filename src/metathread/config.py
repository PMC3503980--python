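"""Pipeline configuration: the constants every stage shares, loadable from a
single declarative YAML file and echoed verbatim into run manifests."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable pipeline constants.

    Defaults are the shipped operating points: template relatedness and
    clustering at TM-score 0.4, contact reporting threshold 0.35, trivial
    template exclusion above 40% sequence identity, 2-fold cross-validation
    and targets of 50-600 residues.
    """

    method_roster: list[str] = field(default_factory=list)
    selection_cutoff: float = 0.5
    contact_threshold: float = 0.35
    gap_penalty: float = 0.1
    tm_related_threshold: float = 0.4
    tm_cluster_threshold: float = 0.4
    seqid_exclusion: float = 40.0
    folds: int = 2
    seed: int = 0
    target_length_range: tuple[int, int] = (50, 600)

    def __post_init__(self) -> None:
        for name in ("selection_cutoff", "contact_threshold",
                     "tm_related_threshold", "tm_cluster_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0.0 <= self.seqid_exclusion <= 100.0:
            raise ValueError("seqid_exclusion is a percentage")
        lo, hi = self.target_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid target_length_range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_length_range"] = list(self.target_length_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "target_length_range" in data:
            data["target_length_range"] = tuple(data["target_length_range"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CONFIG = PipelineConfig()
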