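"""End-to-end orchestration: depth + k-mer track in, BED calls out.

The pipeline mirrors the three-step calling design: coverage baselining
over high-confidence regions with IQR aneuploidy screening, per-chromosome
Poisson-HMM segmentation against the overall baseline, then the merging /
trimming / DBSCAN consolidation cascade and the 50 kb reporting floor.
Chromosomes classified aneuploid are not segmented; each contributes a
single whole-chromosome gain or loss record instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from . import consolidate, refine, segmenter
from .config import PipelineConfig
from .depth import (
    CoverageSummary,
    DepthTrack,
    chromosome_coverage,
    detect_outlier_chromosomes,
    write_coverage_report,
)
from .intervals import GenomicInterval
from .kmer_track import KmerUniquenessTrack
from .refine import CnvCall
from .segmenter import CN1, CN3, CN0, CNGT3

log = logging.getLogger("rdcnv")


@dataclass
class PipelineResult:
    calls: List[CnvCall]
    summary: CoverageSummary
    aneuploid: Dict[str, str]
    candidates: List[consolidate.CandidateCnv] = field(default_factory=list)


def _check_consistency(track: KmerUniquenessTrack, depth: DepthTrack) -> None:
    track_chroms = {c: track.chrom_length(c) for c in track.chrom_names}
    depth_chroms = dict(depth.chrom_lengths)
    if track_chroms.keys() != depth_chroms.keys():
        only_t = sorted(track_chroms.keys() - depth_chroms.keys())
        only_d = sorted(depth_chroms.keys() - track_chroms.keys())
        raise ValueError(
            "chromosome names differ between k-mer track and depth input "
            f"(track only: {only_t}, depth only: {only_d})"
        )
    for chrom, length in track_chroms.items():
        if depth_chroms[chrom] != length:
            raise ValueError(
                f"{chrom}: track length {length} != depth length {depth_chroms[chrom]}"
            )


def _whole_chrom_call(
    chrom: str, length: int, direction: str, ratio: float, coverage: float
) -> CnvCall:
    if direction == "gain":
        state = CNGT3 if ratio >= 1.75 else CN3
    else:
        state = CN0 if ratio < 0.25 else CN1
    return CnvCall(
        interval=GenomicInterval(chrom, 0, length),
        type=direction,
        dominant_state=state,
        mean_depth=coverage,
    )


def call_cnvs(
    track: KmerUniquenessTrack,
    depth: DepthTrack,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full calling cascade on in-memory inputs."""
    config = config or PipelineConfig()
    _check_consistency(track, depth)

    hc_regions = track.find_high_confidence_regions(config.hc_region_min)
    per_chrom = chromosome_coverage(depth, hc_regions, config.hc_regions_per_chrom)
    for chrom in config.exclude_chromosomes:
        per_chrom.pop(chrom, None)
    if not per_chrom:
        raise ValueError("no chromosome has a high-confidence region; cannot baseline")
    summary = detect_outlier_chromosomes(per_chrom, config.iqr_multiplier)
    aneuploid = summary.aneuploid(
        config.aneuploid_low_ratio, config.aneuploid_high_ratio
    )
    log.info(
        "overall coverage %.2f (outliers: %s; aneuploid: %s)",
        summary.overall,
        sorted(summary.outliers) or "none",
        sorted(aneuploid) or "none",
    )

    model = segmenter.build_hmm(
        summary.overall,
        transition_t=config.transition_t,
        noise_floor=config.noise_floor,
    )
    calls: List[CnvCall] = []
    all_candidates: List[consolidate.CandidateCnv] = []
    for chrom in depth.chrom_names:
        length = depth.chrom_lengths[chrom]
        if chrom in aneuploid:
            ratio = summary.per_chromosome[chrom] / summary.overall
            calls.append(
                _whole_chrom_call(
                    chrom, length, aneuploid[chrom], ratio,
                    summary.per_chromosome[chrom],
                )
            )
            continue
        if chrom in config.exclude_chromosomes or chrom not in per_chrom:
            continue
        states = segmenter.decode_states(depth.data[chrom], model)
        segments = segmenter.segments_from_states(
            states, depth.data[chrom], depth.bin_size, chrom, length
        )
        absorbed = consolidate.absorb_short_runs(
            segments, config.absorb_len, config.purity
        )
        candidates = consolidate.candidates_from_segments(absorbed)
        candidates = consolidate.merge_by_length(candidates, config.max_gap)
        trimmed = [
            t
            for c in candidates
            if (
                t := refine.trim_low_uniqueness_tails(
                    c, track, config.trim_bins, config.unique_kmer
                )
            )
            is not None
        ]
        all_candidates.extend(trimmed)
        chrom_calls = refine.dbscan_consolidate(trimmed, config.max_gap)
        calls.extend(refine.apply_size_floor(chrom_calls, config.min_report_len))
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return PipelineResult(
        calls=calls, summary=summary, aneuploid=aneuploid, candidates=all_candidates
    )


def _checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    track_path: Union[str, Path],
    depth_source: Union[str, Path],
    out_dir: Union[str, Path],
    depth_format: str = "bedgraph",
) -> PipelineResult:
    """File-level pipeline: read inputs, call, write BED + report + manifest."""
    from .depth import depth_from_alignments, read_depth_bedgraph
    from .kmer_track import read_track

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    track = read_track(track_path)
    if depth_format == "bedgraph":
        lengths = {c: track.chrom_length(c) for c in track.chrom_names}
        depth = read_depth_bedgraph(depth_source, config.bin_size, lengths)
    elif depth_format in ("bam", "cram"):
        depth = depth_from_alignments(depth_source, config.bin_size)
    else:
        raise ValueError(f"unknown depth format {depth_format!r}")

    result = call_cnvs(track, depth, config)
    refine.write_bed(result.calls, out / "cnv_calls.bed")
    write_coverage_report(result.summary, out / "coverage.tsv")
    manifest = {
        "config": config.to_dict(),
        "inputs": {
            "track": {"path": str(track_path), "sha256": _checksum(track_path)},
            "depth": {
                "path": str(depth_source),
                "sha256": _checksum(depth_source),
                "format": depth_format,
            },
        },
        "n_calls": len(result.calls),
        "overall_coverage": result.summary.overall,
        "aneuploid": result.aneuploid,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote %d calls to %s", len(result.calls), out / "cnv_calls.bed")
    return result
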