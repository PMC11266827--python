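"""Pipeline configuration: every stage parameter in one YAML-serializable
dataclass, defaulting to the standard desk-scale clustering settings
(90% identity / 55 bp overlap, 0.01% cluster size threshold, 24-mer
organelle filter with a 2-hit cut-off, 2x101 bp reads, 123-329 bp inserts).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"

    # read simulation / pre-processing
    coverage: float = 0.1
    read_length: int = 101
    insert_min: int = 123
    insert_max: int = 329
    error_rate: float = 0.005

    # similarity graph
    min_identity: float = 0.90
    min_overlap: int = 55
    seed_k: int = 13
    size_threshold: float = 0.0001
    streaming_threshold: int = 20000  # reads above this use streaming clustering

    # organelle pre-filter
    organelle_filter: bool = False
    organelle_k: int = 24
    organelle_min_matches: int = 2

    # annotation
    annotation_k: int = 13
    min_vote: float = 0.5

    # tandem / 5S typing
    tandem_k_sweep: tuple = (11, 15, 19, 23, 27)
    min_gene_identity: float = 0.80
    min_gene_overlap: int = 40
    min_loop_fraction: float = 0.05

    # network
    min_support: float = 0.1

    def validate(self) -> None:
        if not 0 < self.coverage <= 0.5:
            raise ValueError("coverage must lie in (0, 0.5]")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")
        if self.min_overlap < 1 or self.min_overlap > self.read_length:
            raise ValueError("bad min_overlap")
        if self.insert_min < self.read_length or self.insert_min > self.insert_max:
            raise ValueError("bad insert range")
        if not 0 <= self.size_threshold < 1:
            raise ValueError("bad size_threshold")
        if not 0 <= self.min_support <= 1:
            raise ValueError("bad min_support")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tandem_k_sweep"] = list(self.tandem_k_sweep)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["tandem_k_sweep"] = tuple(d.get("tandem_k_sweep", (11, 15, 19, 23, 27)))
        cfg = cls(**d)
        cfg.validate()
        return cfg
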