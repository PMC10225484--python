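"""Pipeline configuration: every tunable constant in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Sequence


@dataclass
class PipelineConfig:
    """Tunables for the whole calling pipeline.

    Defaults follow the calling method's published operating point: 25-mers,
    50 bp bins, 20 kb high-confidence regions (20 per chromosome), 5 kb
    absorption with an 80% purity guard, a 60% unique-k-mer trim threshold,
    3 Mb consolidation distance and a 50 kb reporting floor.
    """

    k: int = 25
    bin_size: int = 50
    hc_region_min: int = 20_000
    hc_regions_per_chrom: int = 20
    absorb_len: int = 5_000
    purity: float = 0.8
    unique_kmer: float = 0.6
    trim_bins: int = 10
    max_gap: int = 3_000_000
    min_report_len: int = 50_000
    transition_t: float = 1e-8
    noise_floor: float = 0.05
    iqr_multiplier: float = 1.5
    aneuploid_low_ratio: float = 0.7
    aneuploid_high_ratio: float = 1.3
    exclude_chromosomes: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.exclude_chromosomes = tuple(self.exclude_chromosomes)
        positive = {
            "k": self.k,
            "bin_size": self.bin_size,
            "hc_region_min": self.hc_region_min,
            "hc_regions_per_chrom": self.hc_regions_per_chrom,
            "absorb_len": self.absorb_len,
            "trim_bins": self.trim_bins,
            "max_gap": self.max_gap,
            "min_report_len": self.min_report_len,
            "transition_t": self.transition_t,
            "iqr_multiplier": self.iqr_multiplier,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, value in (("purity", self.purity), ("unique_kmer", self.unique_kmer)):
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["exclude_chromosomes"] = list(self.exclude_chromosomes)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        return cls(**d)
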