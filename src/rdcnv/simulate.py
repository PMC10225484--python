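"""Synthetic references and depth tracks with planted CNVs and aneuploidies.

The simulator produces everything the caller consumes, so the whole
pipeline is exercisable without external data: a pseudorandom
multi-chromosome reference (optionally with duplicated blocks that destroy
k-mer uniqueness), a per-bin depth track whose bins are independent Poisson
draws scaled by local copy number and per-chromosome aneuploidy
multipliers, and the matching truth intervals in BED. Depth-level
simulation is the default; a small read-level mode emitting a sorted BAM
exists for alignment-input integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .depth import DepthTrack, n_bins
from .intervals import GenomicInterval

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatBlock:
    """A source interval copied verbatim to a destination locus."""

    chrom: str
    start: int
    end: int
    dest_chrom: str
    dest_start: int


@dataclass(frozen=True)
class PlantedCnv:
    chrom: str
    start: int
    end: int
    cn: int  # copy number in {0, 1, 3, 4, 6}

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def type(self) -> str:
        return "loss" if self.cn < 2 else "gain"


@dataclass
class SimulationSpec:
    """Full description of one simulated sample."""

    chromosomes: Sequence[Tuple[str, int]]
    coverage: float
    seed: int
    repeat_blocks: Sequence[RepeatBlock] = ()
    planted_cnvs: Sequence[PlantedCnv] = ()
    aneuploidies: Mapping[str, float] = field(default_factory=dict)
    bin_size: int = 50
    noise_floor: float = 0.05  # CN0 rate as a fraction of coverage (mismapping)
    chrom_bias_sd: float = 0.0  # optional per-chromosome multiplicative bias

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        lengths = dict(self.chromosomes)
        by_chrom: Dict[str, List[PlantedCnv]] = {}
        for cnv in self.planted_cnvs:
            if cnv.chrom not in lengths:
                raise ValueError(f"planted CNV on unknown chromosome {cnv.chrom!r}")
            if not (0 <= cnv.start < cnv.end <= lengths[cnv.chrom]):
                raise ValueError(f"planted CNV out of bounds: {cnv}")
            if cnv.cn not in (0, 1, 3, 4, 6):
                raise ValueError(f"unsupported planted copy number {cnv.cn}")
            by_chrom.setdefault(cnv.chrom, []).append(cnv)
        for chrom, cnvs in by_chrom.items():
            cnvs = sorted(cnvs, key=lambda c: c.start)
            for a, b in zip(cnvs, cnvs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping planted CNVs on {chrom}")
        for chrom in self.aneuploidies:
            if chrom not in lengths:
                raise ValueError(f"aneuploidy on unknown chromosome {chrom!r}")

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return dict(self.chromosomes)


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def simulate_reference(spec: SimulationSpec) -> Dict[str, str]:
    """Pseudorandom reference with repeat blocks pasted at their destinations."""
    rng = _rng(spec, 0)
    seqs: Dict[str, np.ndarray] = {}
    for name, length in spec.chromosomes:
        seqs[name] = _ALPHABET[rng.integers(0, 4, size=length)]
    dests: Dict[str, List[Tuple[int, int]]] = {}
    for block in spec.repeat_blocks:
        src = seqs[block.chrom][block.start : block.end]
        d0, d1 = block.dest_start, block.dest_start + (block.end - block.start)
        if d1 > seqs[block.dest_chrom].size:
            raise ValueError(f"repeat destination out of bounds: {block}")
        for s, e in dests.get(block.dest_chrom, ()):  # overlap check
            if d0 < e and s < d1:
                raise ValueError(f"overlapping repeat destinations on {block.dest_chrom}")
        dests.setdefault(block.dest_chrom, []).append((d0, d1))
        seqs[block.dest_chrom][d0:d1] = src
    return {name: arr.tobytes().decode("ascii") for name, arr in seqs.items()}


def simulate_depth(spec: SimulationSpec) -> DepthTrack:
    """Per-bin depth: independent Poisson draws at coverage * CN/2 * multiplier.

    Homozygous-deletion (CN=0) regions keep a mismapping noise floor of
    ``noise_floor`` times the coverage. A bin straddling a CNV boundary uses
    the length-weighted mean rate of its bases.
    """
    rng = _rng(spec, 1)
    data: Dict[str, np.ndarray] = {}
    for name, length in spec.chromosomes:
        nb = n_bins(length, spec.bin_size)
        factor = np.ones(nb, dtype=np.float64)
        if spec.chrom_bias_sd > 0:
            factor *= rng.lognormal(0.0, spec.chrom_bias_sd)
        factor *= float(spec.aneuploidies.get(name, 1.0))
        cn_scale = np.ones(length, dtype=np.float64)
        for cnv in spec.planted_cnvs:
            if cnv.chrom != name:
                continue
            cn_scale[cnv.start : cnv.end] = (
                spec.noise_floor if cnv.cn == 0 else cnv.cn / 2.0
            )
        edges = np.arange(nb) * spec.bin_size
        widths = np.minimum(edges + spec.bin_size, length) - edges
        per_bin_cn = np.add.reduceat(cn_scale, edges) / widths
        rate = spec.coverage * per_bin_cn * factor
        data[name] = rng.poisson(rate).astype(np.float64)
    return DepthTrack(
        bin_size=spec.bin_size, chrom_lengths=spec.chrom_lengths, data=data
    )


def truth_intervals(spec: SimulationSpec) -> List[Tuple[GenomicInterval, str]]:
    """Planted CNVs plus whole-chromosome records for aneuploidies."""
    out = [(cnv.interval, cnv.type) for cnv in spec.planted_cnvs]
    lengths = spec.chrom_lengths
    for chrom, mult in spec.aneuploidies.items():
        if mult == 1.0:
            continue
        out.append(
            (GenomicInterval(chrom, 0, lengths[chrom]), "gain" if mult > 1 else "loss")
        )
    return out


def write_truth_bed(spec: SimulationSpec, destination: Union[str, Path]) -> None:
    with open(destination, "w") as fh:
        for iv, typ in sorted(truth_intervals(spec)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{typ}\n")


def write_depth_bedgraph(track: DepthTrack, destination: Union[str, Path]) -> None:
    """Dump a depth track as bedGraph at bin resolution (run-length merged)."""
    with open(destination, "w") as fh:
        for chrom in track.chrom_names:
            arr = track.data[chrom]
            length = track.chrom_lengths[chrom]
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{int(s) * track.bin_size}\t"
                    f"{min(int(e) * track.bin_size, length)}\t{arr[s]:g}\n"
                )


def write_reference_fasta(
    reference: Mapping[str, str], destination: Union[str, Path], width: int = 70
) -> None:
    with open(destination, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_alignments(
    spec: SimulationSpec,
    destination: Union[str, Path],
    read_length: int = 100,
) -> None:
    """Read-level mode: write a coordinate-sorted, indexed BAM of perfect reads.

    Read starts are uniform within each chromosome with the count drawn to
    hit the requested mean coverage; only used by alignment-input
    integration tests, where per-base depth rather than the Poisson bin law
    matters.
    """
    import pysam

    rng = _rng(spec, 2)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in spec.chromosomes],
    }
    destination = str(destination)
    unsorted = destination + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for tid, (name, length) in enumerate(spec.chromosomes):
            mult = float(spec.aneuploidies.get(name, 1.0))
            n_reads = rng.poisson(spec.coverage * mult * length / read_length)
            starts = np.sort(rng.integers(0, max(1, length - read_length), n_reads))
            for i, s in enumerate(starts):
                a = pysam.AlignedSegment()
                a.query_name = f"{name}_{i}"
                a.query_sequence = "A" * read_length
                a.reference_id = tid
                a.reference_start = int(s)
                a.mapping_quality = 60
                a.cigartuples = [(0, read_length)]
                a.flag = 0
                bam.write(a)
    pysam.sort("-o", destination, unsorted)
    Path(unsorted).unlink()
    pysam.index(destination)
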