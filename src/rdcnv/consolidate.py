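"""CNV candidate consolidation: short-run absorption and length-ordered merging.

With 50 bp bins the decoded state path oscillates inside real CNVs, so
segments are consolidated in two stages. First, a left-to-right sweep
absorbs status runs shorter than 5 kb into the growing previous cluster,
guarded by an 80% purity rule: an absorption only stands once a run of the
cluster's own status extends the cluster past it, and a failing purity
check reinstates the absorbed runs unchanged. Second, candidate CNVs are
merged across intervening normal (CN=2) stretches in decreasing length
order: each seed walks outward, consuming every same-type (loss/gain)
candidate it reaches, halting at the first opposite-type candidate or at a
normal gap of 3 Mb or more.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .intervals import GenomicInterval
from .segmenter import CN2, Segment, state_type

# a member run: (start, end, state) within one chromosome
Member = Tuple[int, int, int]


@dataclass(frozen=True)
class CandidateCnv:
    """A loss or gain candidate with provenance of its member runs.

    ``purity`` is the fraction of the interval covered by members of the
    candidate's own type; ``dominant_state`` is the member state covering
    the most typed length.
    """

    interval: GenomicInterval
    type: str  # "loss" | "gain"
    dominant_state: int
    members: Tuple[Member, ...]
    purity: float
    mean_depth: float

    @property
    def length(self) -> int:
        return self.interval.length


def _typed_members(members: Sequence[Member], cnv_type: str) -> List[Member]:
    return [m for m in members if state_type(m[2]) == cnv_type]


def _candidate_from_members(
    chrom: str, members: Sequence[Member], cnv_type: str
) -> CandidateCnv:
    start = min(m[0] for m in members)
    end = max(m[1] for m in members)
    typed = _typed_members(members, cnv_type)
    typed_len = sum(m[1] - m[0] for m in typed)
    by_state: Dict[int, int] = {}
    for s, e, st in typed:
        by_state[st] = by_state.get(st, 0) + (e - s)
    dominant = max(sorted(by_state), key=lambda st: by_state[st])
    return CandidateCnv(
        interval=GenomicInterval(chrom, start, end),
        type=cnv_type,
        dominant_state=dominant,
        members=tuple(sorted(members)),
        purity=typed_len / (end - start),
        mean_depth=0.0,
    )


def _check_tiling(segments: Sequence[Segment]) -> None:
    for prev, cur in zip(segments, segments[1:]):
        if prev.interval.chrom != cur.interval.chrom:
            raise ValueError("absorb_short_runs operates on a single chromosome")
        if prev.interval.end != cur.interval.start:
            raise ValueError(
                f"segments do not tile: gap/overlap at "
                f"{cur.interval.chrom}:{prev.interval.end} vs {cur.interval.start}"
            )


def _merge_runs(runs: Sequence[Segment], state: int) -> Segment:
    chrom = runs[0].interval.chrom
    start = runs[0].interval.start
    end = runs[-1].interval.end
    total_bins = sum(r.n_bins for r in runs)
    weight = sum(r.mean_depth * r.interval.length for r in runs)
    return Segment(
        interval=GenomicInterval(chrom, start, end),
        state=state,
        n_bins=total_bins,
        mean_depth=weight / (end - start),
    )


def absorb_short_runs(
    segments: Sequence[Segment],
    min_len: int = 5_000,
    purity_floor: float = 0.8,
) -> List[Segment]:
    """Absorb status runs shorter than ``min_len`` into the previous cluster.

    Absorbed runs are pending until a run of the cluster's own status
    extends the cluster: at that point the cluster (seed status) must still
    cover at least ``purity_floor`` of the extended length, otherwise the
    pending runs are reinstated unchanged and the cluster closes. Pending
    runs left unvalidated when the cluster closes are also reinstated, so
    absorption only ever bridges oscillations between same-status runs.
    A short run at the chromosome start is absorbed into the following
    cluster under the same rule. The output remains an exact tiling.
    """
    if not segments:
        return []
    _check_tiling(segments)

    out: List[Segment] = []
    lead: Optional[Segment] = None  # unvalidated short chromosome-leading run
    committed: List[Segment] = []  # contiguous runs owned by the seed status
    pending: List[Segment] = []  # unvalidated absorbed runs after the committed block
    seed_state: Optional[int] = None

    def close() -> None:
        nonlocal lead, committed, pending, seed_state
        if lead is not None:
            out.append(lead)
            lead = None
        if committed:
            out.append(_merge_runs(committed, seed_state))
        out.extend(pending)
        committed, pending, seed_state = [], [], None

    for i, run in enumerate(segments):
        if seed_state is None:
            committed, pending, seed_state = [run], [], run.state
            continue
        if run.state == seed_state:
            trial = ([lead] if lead is not None else []) + committed + pending + [run]
            total = trial[-1].interval.end - trial[0].interval.start
            seed_len = sum(r.interval.length for r in trial if r.state == seed_state)
            if seed_len / total >= purity_floor:
                committed, pending, lead = trial, [], None
            else:
                close()  # reinstates lead and pending, emits the committed block
                committed, seed_state = [run], run.state
            continue
        if run.interval.length < min_len:
            pending.append(run)
            continue
        # a long different-status run closes the cluster and reseeds; a short
        # chromosome-leading run instead rides along into the new cluster
        if i == 1 and committed[0].interval.length < min_len and not pending:
            lead = committed[0]
            committed, pending, seed_state = [run], [], run.state
            continue
        close()
        committed, seed_state = [run], run.state
    close()
    return out


def candidates_from_segments(segments: Sequence[Segment]) -> List[CandidateCnv]:
    """Promote non-normal segments to typed CNV candidates with provenance."""
    out: List[CandidateCnv] = []
    for seg in segments:
        if seg.state == CN2:
            continue
        cand = _candidate_from_members(
            seg.interval.chrom,
            [(seg.interval.start, seg.interval.end, seg.state)],
            state_type(seg.state),
        )
        out.append(replace(cand, mean_depth=seg.mean_depth))
    return out


def merge_by_length(
    candidates: Sequence[CandidateCnv], max_gap: int = 3_000_000
) -> List[CandidateCnv]:
    """Merge same-type candidates across normal stretches, longest seed first.

    Seeds are taken in decreasing length order (ties by chromosome then
    start). Each seed walks outward over the coordinate-sorted candidate
    list in both directions, merging every same-type candidate whose gap to
    the current span is below ``max_gap`` and halting that direction at the
    first opposite-type candidate (or at a larger gap). Merged candidates
    are consumed and cannot seed. The pass repeats until a fixed point, so
    the operation is idempotent.
    """
    current = sorted(candidates, key=lambda c: (c.interval.chrom, c.interval.start))
    while True:
        merged_any = False
        order = sorted(
            range(len(current)),
            key=lambda i: (
                -current[i].length,
                current[i].interval.chrom,
                current[i].interval.start,
            ),
        )
        consumed = [False] * len(current)
        result: Dict[int, CandidateCnv] = {}
        for idx in order:
            if consumed[idx]:
                continue
            seed = current[idx]
            consumed[idx] = True
            members = list(seed.members)
            depth_w = seed.mean_depth * seed.length
            len_w = seed.length
            span_start, span_end = seed.interval.start, seed.interval.end
            chrom = seed.interval.chrom
            for step in (1, -1):
                j = idx + step
                while 0 <= j < len(current):
                    other = current[j]
                    if consumed[j] or other.interval.chrom != chrom:
                        break
                    gap = (
                        other.interval.start - span_end
                        if step == 1
                        else span_start - other.interval.end
                    )
                    if other.type != seed.type or gap >= max_gap:
                        break
                    consumed[j] = True
                    merged_any = True
                    members.extend(other.members)
                    depth_w += other.mean_depth * other.length
                    len_w += other.length
                    span_start = min(span_start, other.interval.start)
                    span_end = max(span_end, other.interval.end)
                    j += step
            cand = _candidate_from_members(chrom, members, seed.type)
            result[idx] = replace(cand, mean_depth=depth_w / len_w)
        current = sorted(
            result.values(), key=lambda c: (c.interval.chrom, c.interval.start)
        )
        if not merged_any:
            return current
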