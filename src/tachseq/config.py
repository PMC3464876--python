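"""Run configuration: every tunable of the pipeline in one YAML-loadable tree."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .hotspots import HotspotParams

__all__ = ["GenomeConfig", "LandscapeConfig", "LibraryConfig", "RunConfig"]


@dataclass
class GenomeConfig:
    n_contigs: int = 1
    contig_len: int = 2_000_000
    gc_block_len: int = 10_000
    gc_levels: tuple = (0.3, 0.5, 0.7)
    n_cpg_islands: int = 10
    mito: bool = True

    def __post_init__(self):
        if min(self.n_contigs, self.contig_len, self.gc_block_len) <= 0:
            raise ValueError("genome lengths/counts must be positive")


@dataclass
class LandscapeConfig:
    n_regions: int = 100
    intensity_mean_log: float = 2.302585092994046  # ln 10
    intensity_sigma_log: float = 1.5
    promoter_fraction: float = 0.5
    expression_coupling: float = 1.0
    region_len_min: int = 250
    region_len_max: int = 1000


@dataclass
class LibraryConfig:
    label: str = "benzonase"
    bias: str = "benzonase"  # preset name
    n_fragments: int = 200_000
    mito_fraction: float = 0.05
    tag_len: int = 36
    fragment_min: int = 100
    fragment_max: int = 500


@dataclass
class RunConfig:
    """Top-level configuration; module defaults are the design defaults."""

    seed: int = 1
    outdir: str = "tachseq_run"
    stages: tuple = ("simulate", "callhotspots", "compare", "bias", "annotate")
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    libraries: tuple = (
        LibraryConfig(label="benzonase", bias="benzonase"),
        LibraryConfig(label="dnase1", bias="dnase1"),
    )
    hotspots: HotspotParams = field(default_factory=HotspotParams)
    bias_flank_k: int = 10
    gc_profile_flank: int = 2000
    gc_profile_bin: int = 10
    promoter_len: int = 2000
    downstream_len: int = 2000
    aggregation_flank: int = 3000
    aggregation_bin: int = 50

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs: dict = {}
        if "genome" in data:
            kwargs["genome"] = GenomeConfig(**data.pop("genome"))
        if "landscape" in data:
            kwargs["landscape"] = LandscapeConfig(**data.pop("landscape"))
        if "libraries" in data:
            kwargs["libraries"] = tuple(
                LibraryConfig(**lib) for lib in data.pop("libraries")
            )
        if "hotspots" in data:
            kwargs["hotspots"] = HotspotParams(**data.pop("hotspots"))
        if "stages" in data:
            kwargs["stages"] = tuple(data.pop("stages"))
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["genome"]["gc_levels"] = list(self.genome.gc_levels)
        d["libraries"] = [dataclasses.asdict(lib) for lib in self.libraries]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
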