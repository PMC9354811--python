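"""Pipeline configuration: one validated object, YAML in and out.

The exact configuration used for a run is serialized into every output
directory so results stay reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .qc import QCThresholds
from .signal import FilterSpec


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the processing and statistics stages."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    window_s: float = 0.025  # moving-RMS window
    hop: int = 1  # fully overlapping "mobile" window
    mvic_rule: str = "max_of_attempts"
    mvic_central_s: float = 2.0
    qc: QCThresholds = field(default_factory=QCThresholds)
    alpha: float = 0.05
    family_mode: str = "per-phase"  # Bonferroni family structure
    output_precision: int = 6  # decimals in written signal files

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.window_s <= 0 or self.hop < 1:
            raise ValueError("invalid envelope window/hop")
        if self.mvic_rule not in ("max_of_attempts", "mean_of_attempts"):
            raise ValueError(f"unknown MVIC rule {self.mvic_rule!r}")
        if self.family_mode not in ("per-phase", "global"):
            raise ValueError(f"unknown family mode {self.family_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "filter" in data and isinstance(data["filter"], dict):
            data["filter"] = FilterSpec(**data["filter"])
        if "qc" in data and isinstance(data["qc"], dict):
            qc = dict(data["qc"])
            for key in ("median_band", "expected_band"):
                if key in qc:
                    qc[key] = tuple(qc[key])
            data["qc"] = QCThresholds(**qc)
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
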