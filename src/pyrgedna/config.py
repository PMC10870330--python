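"""Structured pipeline configuration (YAML) with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .curation import CurationConfig
from .reads import QCParams
from .simulate import DEFAULT_FORWARD_PRIMER, DEFAULT_REVERSE_PRIMER, SimConfig

__all__ = ["PrimerConfig", "DetectionConfig", "PipelineConfig"]

#: Illumina tail prefixes carried as inert strings (amplicon-side only;
#: indexing chemistry is out of scope)
DEFAULT_FWD_TAIL = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
DEFAULT_REV_TAIL = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"


@dataclass
class PrimerConfig:
    forward: str = DEFAULT_FORWARD_PRIMER
    reverse: str = DEFAULT_REVERSE_PRIMER
    forward_tail: str = DEFAULT_FWD_TAIL
    reverse_tail: str = DEFAULT_REV_TAIL


@dataclass
class DetectionConfig:
    cluster_threshold: float = 0.01
    window_years: int = 5
    min_reads: int = 1


@dataclass
class PipelineConfig:
    primers: PrimerConfig = field(default_factory=PrimerConfig)
    qc: QCParams = field(default_factory=QCParams)
    curation: CurationConfig = field(default_factory=CurationConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for name, payload in data.items():
            section = getattr(cfg, name)
            valid = {f.name for f in dataclasses.fields(section)}
            bad = set(payload) - valid
            if bad:
                raise ValueError(
                    f"unknown keys in section {name!r}: {sorted(bad)}"
                )
            coerced = dict(payload)
            # YAML lists -> tuples where the dataclass default is a tuple
            for f in dataclasses.fields(section):
                if f.name in coerced and isinstance(
                    getattr(section, f.name), tuple
                ):
                    val = coerced[f.name]
                    coerced[f.name] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in val
                    )
            setattr(
                cfg, name, type(section)(**{**dataclasses.asdict(section), **coerced})
            )
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
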