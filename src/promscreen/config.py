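"""Pipeline configuration: one YAML document driving every stage.

Every stochastic stage derives its effective seed from the global seed and
the stage name, so a single ``seed:`` key makes the whole pipeline
reproducible while keeping stage streams independent.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .landscape import LandscapeConfig

__all__ = ["PipelineConfig", "stage_seed", "load_config", "dump_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2**31)."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode("ascii"))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class DataConfig:
    path: str | None = None  # existing sequence/expression TSV, else synthesize
    n: int = 5000
    test_n: int = 2000
    seq_length: int = 80
    integer_contamination_rate: float = 0.05
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)


@dataclass
class PredictorConfig:
    kind: str = "kmer_ridge"
    k: int = 4
    ridge_penalty: float | None = None  # None -> GCV over the fixed grid


@dataclass
class MutationSection:
    min_mutations: int = 1
    max_mutations: int = 3
    generations: int = 100


@dataclass
class ScreenConfig:
    top_n: int = 1000
    n_clusters: int = 3
    min_final_quantile: float = 0.5
    max_drop_quantile: float = 0.25
    n_density_bins: int = 20


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "promscreen_out"
    data: DataConfig = field(default_factory=DataConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    mutation: MutationSection = field(default_factory=MutationSection)
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    ladder_sizes: tuple[int, ...] = (300, 3000, 30000)

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["ladder_sizes"] = list(self.ladder_sizes)
        doc["data"]["landscape"] = {
            "n_motifs": list(self.data.landscape.n_motifs),
            "motif_length": list(self.data.landscape.motif_length),
            "weight_range": list(self.data.landscape.weight_range),
            "baseline": self.data.landscape.baseline,
            "noise_sd": self.data.landscape.noise_sd,
        }
        return doc


_SECTIONS = {
    "data": DataConfig,
    "predictor": PredictorConfig,
    "mutation": MutationSection,
    "screen": ScreenConfig,
}


def _build_section(cls, doc: dict, context: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    return cls(**doc)


def load_config(path) -> PipelineConfig:
    """Load a pipeline config, rejecting unknown keys with their names."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> PipelineConfig:
    doc = dict(doc)
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        section = doc.pop(name, None)
        if section is None:
            continue
        section = dict(section)
        if name == "data" and "landscape" in section and section["landscape"] is not None:
            ls = dict(section["landscape"])
            unknown = set(ls) - set(LandscapeConfig.__dataclass_fields__)
            if unknown:
                raise ValueError(f"unknown config key(s) in data.landscape: {sorted(unknown)}")
            for key in ("n_motifs", "motif_length", "weight_range"):
                if key in ls:
                    ls[key] = tuple(ls[key])
            section["landscape"] = LandscapeConfig(**ls)
        kwargs[name] = _build_section(cls, section, name)
    top_valid = {"seed", "output_dir", "ladder_sizes"}
    unknown = set(doc) - top_valid
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    if "ladder_sizes" in doc:
        kwargs["ladder_sizes"] = tuple(int(s) for s in doc.pop("ladder_sizes"))
    kwargs.update(doc)
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
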