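"""YAML-backed pipeline configuration with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .alignment import AlignmentParams
from .conflicts import ConflictParams
from .digestion import DigestionParams
from .scaffolding import ScaffoldParams
from .qc import QcParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class SimulationParams:
    n_chrom: int = 2
    chrom_length_bp: int = 1_000_000
    n_breaks: int = 40
    n_misjoins: int = 0
    fragment_mean_bp: int = 350_000
    map_coverage: float = 2.0
    sizing_sd_coeff: float = 0.0
    missing_rate: float = 0.0
    false_rate: float = 0.0
    matepair_depth: float = 30.0
    markers_per_chrom: int = 30


@dataclass
class PipelineConfig:
    """Every module's parameter block plus the global seed.

    The global seed fans out to per-module child seeds via
    :func:`hybridscaf.pipeline.derive_seed`, so adding a stage never changes
    another stage's randomness.
    """

    digestion: DigestionParams = field(default_factory=DigestionParams)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    conflict: ConflictParams = field(default_factory=ConflictParams)
    scaffolding: ScaffoldParams = field(default_factory=ScaffoldParams)
    qc: QcParams = field(default_factory=QcParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, value in data.items():
            f = known[name]
            if dataclasses.is_dataclass(f.type) or name != "seed":
                sub_cls = {
                    "digestion": DigestionParams,
                    "alignment": AlignmentParams,
                    "conflict": ConflictParams,
                    "scaffolding": ScaffoldParams,
                    "qc": QcParams,
                    "simulation": SimulationParams,
                }[name]
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown keys in {name}: {sorted(sub_unknown)}")
                kwargs[name] = sub_cls(**value)
            else:
                kwargs[name] = int(value)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(data)
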