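"""Pipeline configuration: one serializable object holding every threshold.

No stage uses a hidden numeric constant — everything tunable is reachable
from this object, and a config round-trips through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # reference tiers, in priority order (1 = consulted first)
    tiers: list[dict] = field(default_factory=list)  # {name, fasta, taxonomy}
    # read QC
    min_read_len: int = 50
    min_mean_quality: float = 20.0
    subsample_n: int | None = None
    # homology engine
    word_size: int = 11
    min_alignment_length: int = 30
    max_evalue_proxy: float = 1e-5
    min_identity: float = 0.0
    # stringent mapping (contaminant scrub, transmission)
    map_min_identity: float = 99.0
    map_min_read_cov: float = 90.0
    # contig classification
    contig_gate_nt: int = 5000
    min_orf_len_aa: int = 60
    # comparisons
    shared_taxa_min_abundance_pct: float = 0.01
    rank: str = "species"
    # simulation / error model
    error_rate: float = 0.01
    read_length: int = 150
    # misc
    seed: int = 0
    preset: str = "default"
    out_dir: str = "viromekit_out"

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.map_min_identity <= 100, "map_min_identity must be a percentage"),
            (0 <= self.map_min_read_cov <= 100, "map_min_read_cov must be a percentage"),
            (self.contig_gate_nt >= 0, "contig_gate_nt must be nonnegative"),
            (self.shared_taxa_min_abundance_pct >= 0, "shared-taxa threshold must be ≥ 0"),
            (0 <= self.error_rate < 0.25, "error_rate must be in [0, 0.25)"),
            (self.word_size >= 4, "word_size must be ≥ 4"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def alignment_params(self, protein: bool = False):
        from .align import AlignmentParams

        return AlignmentParams(
            k=4 if protein else self.word_size,
            min_identity=self.min_identity,
            min_alignment_length=self.min_alignment_length,
            max_evalue_proxy=self.max_evalue_proxy,
        )
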