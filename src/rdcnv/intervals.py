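"""Shared genomic-interval primitives.

Coordinates follow BED conventions throughout the package: 0-based start,
exclusive end, half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with another interval (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Genomic distance between two intervals; 0 if they touch or overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap between intervals on different chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))
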