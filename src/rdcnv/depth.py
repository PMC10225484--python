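"""Binned read depth, coverage baselining and aneuploidy screening.

Depth is summarised as the mean per-base depth of fixed-width bins
(default 50 bp). The overall coverage of a sample is estimated from the
longest high-confidence (uniquely mappable) regions of each chromosome,
and chromosomes whose coverage falls outside the Tukey fences of the
per-chromosome distribution are flagged as outliers: these are excluded
from the overall mean and, when their coverage ratio is consistent with a
whole-chromosome copy-number change, treated as aneuploid.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .intervals import GenomicInterval

# CIGAR operations that consume the reference
_REF_OPS = {0, 2, 3, 7, 8}  # M, D, N, =, X
# CIGAR operations counted as covering the reference (aligned span incl. deletions)
_COVER_OPS = {0, 2, 7, 8}


def n_bins(chrom_length: int, bin_size: int) -> int:
    return -(-chrom_length // bin_size)


@dataclass
class DepthTrack:
    """Mean read depth per fixed-width bin, one array per chromosome."""

    bin_size: int
    chrom_lengths: Dict[str, int]
    data: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, arr in self.data.items():
            expect = n_bins(self.chrom_lengths[chrom], self.bin_size)
            if arr.size != expect:
                raise ValueError(
                    f"{chrom}: {arr.size} bins but expected {expect} for length "
                    f"{self.chrom_lengths[chrom]} at bin size {self.bin_size}"
                )
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative depth values")

    @property
    def chrom_names(self) -> List[str]:
        return list(self.data)


@dataclass
class CoverageSummary:
    """Per-chromosome coverage, IQR outliers and the overall baseline."""

    per_chromosome: Dict[str, float]
    outliers: Dict[str, str]  # chrom -> "gain" | "loss"
    overall: float

    def aneuploid(
        self, low_ratio: float = 0.7, high_ratio: float = 1.3
    ) -> Dict[str, str]:
        """Outlier chromosomes whose coverage ratio to the overall baseline is
        consistent with a whole-chromosome copy-number change.

        An outlier at, say, 0.75x the baseline (a large heterozygous deletion
        on an otherwise diploid chromosome) is excluded from the baseline but
        still segmented; a chromosome at 0.5x or 1.5x is called aneuploid and
        sub-chromosomal calling on it is suppressed.
        """
        out: Dict[str, str] = {}
        for chrom, direction in self.outliers.items():
            ratio = self.per_chromosome[chrom] / self.overall
            if ratio < low_ratio:
                out[chrom] = "loss"
            elif ratio > high_ratio:
                out[chrom] = "gain"
        return out


def _bin_weights(start: int, end: int, bin_size: int, chrom_length: int):
    """Bins overlapped by [start, end) and the number of bases of overlap."""
    b0 = start // bin_size
    b1 = (end - 1) // bin_size
    idx = np.arange(b0, b1 + 1)
    bin_starts = idx * bin_size
    bin_ends = np.minimum(bin_starts + bin_size, chrom_length)
    w = np.minimum(bin_ends, end) - np.maximum(bin_starts, start)
    return idx, w.astype(np.float64)


def depth_from_alignments(
    alignment_path: Union[str, Path],
    bin_size: int = 50,
    reference_filename: Optional[str] = None,
) -> DepthTrack:
    """Per-bin mean depth from a coordinate-sorted, indexed BAM/CRAM.

    Unmapped, secondary, supplementary and duplicate-flagged reads are
    skipped; each remaining read covers its aligned reference span
    (CIGAR M/=/X/D; N introns are not covered).
    """
    import pysam

    af = pysam.AlignmentFile(str(alignment_path), reference_filename=reference_filename)
    try:
        so = af.header.get("HD", {}).get("SO", "unknown")
        if so != "coordinate":
            raise ValueError(
                f"{alignment_path}: sort order is {so!r}; coordinate-sorted "
                "input is required (samtools sort)"
            )
        try:
            has_index = af.check_index()
        except (ValueError, AttributeError):
            has_index = False
        if not has_index:
            raise ValueError(
                f"{alignment_path}: no index found; run samtools index first"
            )
        chrom_lengths = {name: af.get_reference_length(name) for name in af.references}
        data: Dict[str, np.ndarray] = {}
        for chrom, length in chrom_lengths.items():
            diff = np.zeros(length + 1, dtype=np.int64)
            for read in af.fetch(chrom):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                ):
                    continue
                pos = read.reference_start
                for op, ln in read.cigartuples or ():
                    if op in _COVER_OPS:
                        diff[pos] += 1
                        diff[min(pos + ln, length)] -= 1
                    if op in _REF_OPS:
                        pos += ln
            per_base = np.cumsum(diff[:-1]).astype(np.float64)
            nb = n_bins(length, bin_size)
            edges = np.arange(nb) * bin_size
            sums = np.add.reduceat(per_base, edges)
            widths = np.minimum(edges + bin_size, length) - edges
            data[chrom] = sums / widths
        return DepthTrack(bin_size=bin_size, chrom_lengths=chrom_lengths, data=data)
    finally:
        af.close()


def read_depth_bedgraph(
    source: Union[str, Path, io.TextIOBase],
    bin_size: int = 50,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> DepthTrack:
    """Resample a sorted, non-overlapping bedGraph onto the bin grid.

    Each bin's depth is the coverage-weighted mean of the intervals crossing
    it; bases not covered by any interval count as depth 0. Chromosome
    lengths default to the largest end coordinate seen per chromosome.
    """
    if isinstance(source, (str, Path)):
        fh = open(source)
        close = True
    else:
        fh = source
        close = False
    records: Dict[str, List[Tuple[int, int, float]]] = {}
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise ValueError(f"line {lineno}: empty interval {start}-{end}")
            recs = records.setdefault(chrom, [])
            if recs:
                pstart, pend, _ = recs[-1]
                if start < pstart:
                    raise ValueError(
                        f"line {lineno}: unsorted bedGraph ({chrom}:{start} after {pstart})"
                    )
                if start < pend:
                    raise ValueError(
                        f"line {lineno}: overlapping intervals on {chrom} "
                        f"({start} < previous end {pend})"
                    )
            recs.append((start, end, value))
    finally:
        if close:
            fh.close()

    lengths: Dict[str, int] = (
        dict(chrom_lengths)
        if chrom_lengths is not None
        else {c: recs[-1][1] for c, recs in records.items()}
    )
    data: Dict[str, np.ndarray] = {}
    for chrom, length in lengths.items():
        nb = n_bins(length, bin_size)
        sums = np.zeros(nb, dtype=np.float64)
        for start, end, value in records.get(chrom, ()):  # weighted accumulation
            if end > length:
                raise ValueError(f"{chrom}: interval end {end} beyond length {length}")
            idx, w = _bin_weights(start, end, bin_size, length)
            np.add.at(sums, idx, w * value)
        edges = np.arange(nb) * bin_size
        widths = np.minimum(edges + bin_size, length) - edges
        data[chrom] = sums / widths
    return DepthTrack(bin_size=bin_size, chrom_lengths=lengths, data=data)


def chromosome_coverage(
    depth: DepthTrack,
    hc_regions: Sequence[GenomicInterval],
    n_regions: int = 20,
) -> Dict[str, float]:
    """Mean coverage per chromosome over its longest high-confidence regions.

    For each chromosome the ``n_regions`` longest uniquely mappable regions
    (ties broken by coordinate; all of them if fewer exist) contribute a
    base-weighted mean of the bin depths they overlap. Chromosomes without
    any high-confidence region are absent from the result.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for r in hc_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: Dict[str, float] = {}
    for chrom, regions in by_chrom.items():
        if chrom not in depth.data:
            continue
        chosen = sorted(regions, key=lambda r: (-r.length, r.start))[:n_regions]
        length = depth.chrom_lengths[chrom]
        total_w = 0.0
        total = 0.0
        for r in chosen:
            idx, w = _bin_weights(r.start, min(r.end, length), depth.bin_size, length)
            total += float(np.dot(depth.data[chrom][idx], w))
            total_w += float(w.sum())
        if total_w > 0:
            out[chrom] = total / total_w
    return out


def detect_outlier_chromosomes(
    per_chromosome: Mapping[str, float], iqr_multiplier: float = 1.5
) -> CoverageSummary:
    """Flag per-chromosome coverages outside the Tukey IQR fences.

    Values strictly outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` (linear
    interpolation quartiles) are outliers, labelled gain above the upper
    fence and loss below the lower one. The overall sample coverage is the
    mean over the non-outlier chromosomes. With fewer than four chromosomes
    the IQR is not meaningful and no outliers are reported.
    """
    if not per_chromosome:
        raise ValueError("no per-chromosome coverages")
    chroms = list(per_chromosome)
    values = np.array([per_chromosome[c] for c in chroms], dtype=np.float64)
    if len(chroms) < 4:
        return CoverageSummary(dict(per_chromosome), {}, float(values.mean()))
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
    outliers = {
        c: ("gain" if v > hi else "loss")
        for c, v in zip(chroms, values)
        if v > hi or v < lo
    }
    kept = values[[c not in outliers for c in chroms]]
    if kept.size == 0:
        raise ValueError("all chromosomes flagged as coverage outliers")
    return CoverageSummary(dict(per_chromosome), outliers, float(kept.mean()))


def write_coverage_report(summary: CoverageSummary, destination: Union[str, Path]) -> None:
    """Tab-separated coverage report plus a single overall-coverage line."""
    aneuploid = summary.aneuploid()
    with open(destination, "w") as fh:
        fh.write("#chrom\tcoverage\toutlier\tdirection\taneuploid\n")
        for chrom, cov in summary.per_chromosome.items():
            flag = chrom in summary.outliers
            fh.write(
                f"{chrom}\t{cov:.4f}\t{int(flag)}\t"
                f"{summary.outliers.get(chrom, '.')}\t{aneuploid.get(chrom, '.')}\n"
            )
        fh.write(f"#overall\t{summary.overall:.4f}\n")
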