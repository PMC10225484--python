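"""Final CNV refinement: mappability trimming, DBSCAN consolidation, reporting.

Candidate CNVs whose tails fall in low-mappability sequence are trimmed by
dividing each candidate into ten equal bins and stripping, from each end,
consecutive bins whose fraction of unique k-mers is below 60%. The trimmed
fragments are then consolidated: fragments of one type separated by less
than 3 Mb form raw clusters, DBSCAN over the inter-fragment gap distances
partitions each raw cluster, each partition is merged into one spanning
call, and the cycle repeats until the clustering stops changing. Calls
shorter than the reporting floor (50 kb) are dropped and the remainder is
written as BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .consolidate import CandidateCnv, Member, _candidate_from_members
from .intervals import GenomicInterval
from .kmer_track import KmerUniquenessTrack
from .segmenter import STATE_NAMES


@dataclass(frozen=True)
class CnvCall:
    """A reportable CNV: typed interval with dominant state and mean depth."""

    interval: GenomicInterval
    type: str  # "loss" | "gain"
    dominant_state: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.interval.length


def _trim_bins(start: int, end: int, n_bins: int) -> List[Tuple[int, int]]:
    """``n_bins`` equal-length bins; the last bin absorbs the remainder."""
    width = (end - start) // n_bins
    edges = [start + i * width for i in range(n_bins)] + [end]
    return list(zip(edges[:-1], edges[1:]))


def trim_low_uniqueness_tails(
    candidate: CandidateCnv,
    track: KmerUniquenessTrack,
    n_bins: int = 10,
    threshold: float = 0.6,
) -> Optional[CandidateCnv]:
    """Strip low-mappability bins from both ends of a candidate.

    The candidate is split into ``n_bins`` equal bins; consecutive bins with
    a unique-k-mer fraction below ``threshold`` are removed from the left
    end (stopping at the first bin meeting the threshold), then likewise
    from the right. Returns None when every bin is removed. Candidates
    shorter than ``n_bins`` bases are returned untrimmed.
    """
    iv = candidate.interval
    if iv.length < n_bins:
        return candidate
    bins = _trim_bins(iv.start, iv.end, n_bins)
    fracs = [
        track.fraction_unique(GenomicInterval(iv.chrom, s, e)) for s, e in bins
    ]
    left = 0
    while left < n_bins and fracs[left] < threshold:
        left += 1
    if left == n_bins:
        return None
    right = n_bins
    while right > left and fracs[right - 1] < threshold:
        right -= 1
    new_start, new_end = bins[left][0], bins[right - 1][1]
    if (new_start, new_end) == (iv.start, iv.end):
        return candidate
    members = [
        (max(s, new_start), min(e, new_end), st)
        for s, e, st in candidate.members
        if min(e, new_end) > max(s, new_start)
    ]
    if not members:
        members = [(new_start, new_end, candidate.dominant_state)]
    cand = _candidate_from_members(iv.chrom, members, candidate.type)
    object.__setattr__(cand, "mean_depth", candidate.mean_depth)
    return cand


def _raw_clusters(
    fragments: Sequence[CandidateCnv], max_gap: int
) -> List[List[CandidateCnv]]:
    """Maximal runs of same-type fragments with successive gaps < max_gap."""
    clusters: List[List[CandidateCnv]] = []
    for frag in sorted(
        fragments, key=lambda f: (f.interval.chrom, f.interval.start)
    ):
        if clusters:
            prev = clusters[-1][-1]
            same = (
                prev.interval.chrom == frag.interval.chrom
                and prev.type == frag.type
                and frag.interval.start - prev.interval.end < max_gap
            )
            if same:
                clusters[-1].append(frag)
                continue
        clusters.append([frag])
    return clusters


def _dbscan_partition(cluster: List[CandidateCnv]) -> List[List[CandidateCnv]]:
    """DBSCAN over inter-fragment gap distances; eps is the mean gap."""
    if len(cluster) == 1:
        return [cluster]
    from sklearn.cluster import DBSCAN

    gaps = [
        b.interval.start - a.interval.end for a, b in zip(cluster, cluster[1:])
    ]
    eps = max(float(np.mean(gaps)), 1.0)
    n = len(cluster)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = max(0, cluster[j].interval.start - cluster[i].interval.end)
            dist[i, j] = dist[j, i] = d
    labels = DBSCAN(eps=eps, min_samples=1, metric="precomputed").fit(dist).labels_
    groups: Dict[int, List[CandidateCnv]] = {}
    for lab, frag in zip(labels, cluster):
        groups.setdefault(int(lab), []).append(frag)
    return [groups[k] for k in sorted(groups)]


def _merge_group(group: List[CandidateCnv]) -> CandidateCnv:
    members: List[Member] = []
    depth_w = 0.0
    len_w = 0
    for frag in group:
        members.extend(frag.members)
        depth_w += frag.mean_depth * frag.length
        len_w += frag.length
    cand = _candidate_from_members(group[0].interval.chrom, members, group[0].type)
    object.__setattr__(cand, "mean_depth", depth_w / len_w)
    return cand


def dbscan_consolidate(
    fragments: Sequence[CandidateCnv],
    max_gap: int = 3_000_000,
    max_iter: int = 10,
) -> List[CnvCall]:
    """Consolidate trimmed fragments into final calls by iterated DBSCAN.

    Raw clusters (same type, successive gaps < ``max_gap``) are partitioned
    by DBSCAN with eps set to the raw cluster's mean inter-fragment gap and
    every fragment a core point; each partition merges into one spanning
    fragment. The cluster-and-merge cycle repeats until it reaches a fixed
    point (bounded by ``max_iter`` as a termination guard).
    """
    current = sorted(
        fragments, key=lambda f: (f.interval.chrom, f.interval.start)
    )
    for _ in range(max_iter):
        merged: List[CandidateCnv] = []
        for cluster in _raw_clusters(current, max_gap):
            for group in _dbscan_partition(cluster):
                merged.append(_merge_group(group))
        merged.sort(key=lambda f: (f.interval.chrom, f.interval.start))
        if [f.interval for f in merged] == [f.interval for f in current]:
            break
        current = merged
    return [
        CnvCall(
            interval=f.interval,
            type=f.type,
            dominant_state=f.dominant_state,
            mean_depth=f.mean_depth,
        )
        for f in current
    ]


def apply_size_floor(calls: Sequence[CnvCall], min_len: int = 50_000) -> List[CnvCall]:
    """Drop calls shorter than the reporting floor (default 50 kb)."""
    return [c for c in calls if c.length >= min_len]


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/|a|, overlap/|b|); two intervals 'match' at >= 0.5."""
    ov = a.overlap(b)
    return min(ov / a.length, ov / b.length)


def write_bed(calls: Sequence[CnvCall], destination: Union[str, Path]) -> None:
    """BED4+ output: chrom, start, end, type:state, mean depth."""
    ordered = sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start))
    with open(destination, "w") as fh:
        for c in ordered:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.type}:{STATE_NAMES[c.dominant_state]}\t{c.mean_depth:.3f}\n"
            )


def sensitivity(
    truth: Sequence[Tuple[GenomicInterval, str]],
    calls: Sequence[CnvCall],
    min_overlap: float = 0.5,
) -> float:
    """Fraction of truth intervals matched by a same-type call at 50% RO."""
    if not truth:
        return 1.0
    hit = 0
    for iv, typ in truth:
        for c in calls:
            if c.type == typ and reciprocal_overlap(iv, c.interval) >= min_overlap:
                hit += 1
                break
    return hit / len(truth)
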