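"""Pipeline configuration with the screen's published default thresholds."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds of every screen stage.

    Defaults: log2 fold-change cut 1.0 at adjusted p <= 0.05 for paired DE,
    focal-event segment-mean cuts +/-0.3, recurrence in >= 2 samples,
    >= 2 indicative probes per candidate, and |r| >= 0.7 at adjusted p < 0.05
    for co-expression edges.
    """

    fc_thr: float = 1.0
    alpha: float = 0.05
    amp_thr: float = 0.3
    del_thr: float = -0.3
    min_support: int = 2
    min_probes: int = 2
    r_thr: float = 0.7
    exclude_genes: tuple[str, ...] = ()
    overlap_rule: str = "weighted"

    def __post_init__(self) -> None:
        if not (self.amp_thr > 0 > self.del_thr):
            raise ValueError("amp_thr must be > 0 > del_thr")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.r_thr <= 1:
            raise ValueError("r_thr must be in (0, 1]")
        self.exclude_genes = tuple(self.exclude_genes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_genes"] = list(d["exclude_genes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the resolved configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
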