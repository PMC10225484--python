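# Methods

This note documents the model behind `rdcnv`, the defaults that matter,
what the simulator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Signal model

Read depth in a whole-genome sequencing sample is approximately
proportional to local copy number: a locus at copy number `CN` in an
otherwise diploid genome is expected at `CN/2` times the sample's overall
coverage. `rdcnv` summarises depth as the mean per-base depth of
non-overlapping 50 bp bins and treats the rounded bin values as Poisson
counts. Small bins keep boundary resolution high at the cost of a noisy
state sequence; the consolidation cascade (below) is what turns that
noisy sequence into few, large calls.

Mappability is handled through a k-mer uniqueness track rather than
alignment filters: a position whose 25-mer occurs exactly once in the
reference can be mapped reliably, and only long (> 20 kb) runs of such
positions are trusted for estimating coverage. 25 is a compromise — long
enough that most of a typical genome is unique, short enough to count
cheaply — and is configurable (`k`, 1–31 with the 2-bit integer
encoding).

## Coverage baseline and the aneuploidy screen

Per chromosome, coverage is the base-weighted mean bin depth over the 20
longest high-confidence regions (ties broken by coordinate; all regions
if fewer exist). Longest-first selection minimises the variance of the
estimate. Quartiles of the per-chromosome coverages use linear
interpolation (numpy's default, type 7) for reproducibility; values
strictly outside the Tukey fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are
outliers. Values exactly on a fence are kept, so an all-equal coverage
vector yields no outliers. With fewer than four chromosomes the IQR is
meaningless and no outliers are reported. All-outlier input raises an
error (it cannot arise from the fence definition, which always contains
the middle half, but is guarded against).

Outliers are excluded from the overall-coverage mean unconditionally.
Suppressing CNV calling on them is a separate decision: an IQR outlier is
classified aneuploid only when its ratio to the overall baseline is below
0.7 or above 1.3, i.e. closer to a whole-chromosome integer copy change
(0.5×, 1.5×, 2×…) than to 1.0. The distinction matters because the IQR of
a clean sample is very small, so a chromosome carrying one large
sub-chromosomal CNV is almost always an *outlier* — excluding it from the
baseline is correct, but suppressing segmentation on it would discard
exactly the call of interest. Aneuploid chromosomes are reported as a
single whole-chromosome gain/loss record (state CN>3 above 1.75×, CN0
below 0.25×, else CN3/CN1) and are not segmented. The 0.7/1.3 bands are
configurable (`aneuploid_low_ratio` / `aneuploid_high_ratio`). Sex
chromosomes get no special casing; in a male sample X and Y will
legitimately appear as loss outliers, and an exclusion list
(`exclude_chromosomes`) is available when that is unwanted.

## The hidden Markov model

Five states: CN 0 and 1 (loss), CN 2 (diploid), CN 3 and > 3 (gain).
Emissions are Poisson on the rounded per-bin depth with rates

- `λ(CN0) = 0.05 × overall` — never zero, so mismapping noise inside a
  homozygous deletion does not forbid the state;
- `λ(CN) = overall × CN/2` for CN 1–3;
- `λ(CN>3) = 2 × overall` — the state is a catch-all for higher
  amplifications and reports no exact copy number.

The percentile view of depth (overall coverage ≡ 50th percentile,
saturating at 200, with 180–200 covering states above two extra copies)
is a monotone rescaling kept for reporting and plots; decoding uses depth
counts directly, so both orderings agree by construction.

Transitions keep probability `1 − 4t` on the diagonal with uniform
off-diagonal `t = 1e-8` per 50 bp bin — a prior mean segment length far
above the 50 kb reporting scale, which suppresses single-bin excursions
(a state switch costs ~18.4 nats each way) while leaving multi-kilobase
signals untouched. The initial distribution (0.001, 0.009, 0.98, 0.009,
0.001) encodes a diploid prior. Decoding is exact log-space Viterbi with
deterministic tie-breaking toward the state closer to CN 2, then the
lower copy number (conservative calling); depth is rounded half-to-even
(unbiased). The decoder kernel is JIT-compiled when numba is available
and falls back to the identical pure-Python loop otherwise. Learning
(Baum–Welch) and posterior decoding are deliberately out of scope.

## Consolidation cascade

**Absorption (5 kb, 80% purity).** Maximal same-state runs shorter than
5 kb are absorbed into the growing previous cluster regardless of their
own state. An absorption is provisional until a run of the cluster's own
status extends the cluster past it; at that point the cluster's seed
status must still cover ≥ 80% of the extended length, otherwise the
provisional absorptions are reinstated unchanged and the cluster closes.
Provisional absorptions never validated by the end of the chromosome are
likewise reinstated, so absorption only ever bridges oscillations between
same-status runs — it cannot relabel trailing material. A short run at
the chromosome start, having no previous cluster, rides into the
following cluster under the same rule rather than being dropped. The
output remains an exact tiling of the chromosome.

**Length-ordered merging.** Candidates (non-diploid clusters typed
loss/gain; CN0 with CN1 and CN3 with CN>3 merge freely within a type, the
reported state being the majority by covered length) are seeded from
longest to shortest, ties broken by chromosome then start. Each seed
walks outward in both directions over the coordinate-sorted candidates,
merging every same-type candidate it reaches — the merged interval spans
the crossed diploid sequence — and halting that direction at the first
opposite-type candidate or at a diploid gap of ≥ 3 Mb. The gap bound
(sharing the raw-cluster distance used below) is what prevents two
genuinely separate CNVs from being fused across arbitrarily long diploid
stretches; a purity-style bound was considered instead but rejected
because legitimate merges routinely span > 20% diploid sequence. The
pass repeats to a fixed point, making the operation idempotent.

**Mappability trimming (10 bins, 60%).** Each candidate is split into ten
equal-length bins (integer division; the last bin absorbs the
remainder). From the left, consecutive bins whose unique-k-mer fraction
is below 60% are removed, stopping at the first bin meeting the
threshold; then the same from the right. A candidate losing all ten bins
is discarded; candidates shorter than ten bases are returned untrimmed.
Trimming is contractive and never touches interior bins — its purpose is
tails that leak into repeat sequence, where breakpoints from depth are
not trustworthy.

**Iterated DBSCAN.** Trimmed fragments are grouped into raw clusters:
maximal same-type runs with successive gaps < 3 Mb. Within a raw cluster
DBSCAN runs on the pairwise inter-fragment gap matrix with
`eps = max(mean successive gap, 1)` and `min_samples = 1` (every fragment
a core point, so nothing is discarded as noise; singletons allowed).
Each DBSCAN cluster merges into one spanning fragment and the whole
cycle repeats until the clustering stops changing (a 10-iteration guard
ensures termination; in practice 2–3 passes reach the fixed point). Note
the fixed point of this procedure merges each raw cluster completely —
a two-fragment cluster has `eps` equal to its own gap — so the mean-gap
DBSCAN shapes intermediate groupings, while the 3 Mb raw-cluster distance
and the type condition are what ultimately separate calls.

Calls shorter than 50 kb are then dropped (the reporting floor), and
output is BED4+ with `type:state` as the name column and mean depth as
the score. Two intervals are considered the same event when their
reciprocal overlap `min(overlap/|a|, overlap/|b|)` is at least 0.5.

## Simulator

`rdcnv.simulate` emulates exactly the signal the caller consumes:

- pseudorandom ACGT references (uniform base composition) in which
  designated blocks are copy-pasted verbatim, destroying k-mer uniqueness
  at both loci;
- per-bin depth as independent Poisson draws at
  `coverage × CN/2 × aneuploidy multiplier`, with `0.05 × coverage` for
  CN 0 (matching the decoder's noise floor) and length-weighted rates for
  bins straddling a CNV boundary; an optional per-chromosome lognormal
  bias factor (default off) mimics GC/mappability variation between
  chromosomes;
- truth BED records for planted CNVs and whole-chromosome records for
  aneuploidies.

All randomness flows from a single integer seed through
`numpy.random.default_rng` with fixed stream offsets, so identical specs
give bit-identical outputs. A minimal read-level mode writes a sorted,
indexed BAM of perfect uniform reads for exercising the alignment input
path.

What the simulator does **not** model: GC bias along the genome,
mapping-quality structure, insert-size effects, sequencing error,
segmental-duplication mosaicism or breakpoint microhomology. Passing
tests therefore demonstrate the statistical machinery — baselining,
decoding, consolidation, screening — under the Poisson depth model, not
robustness to every artefact of real sequencers; on real data the
uneven-depth oscillations the cascade exists for are stronger, and the
aneuploidy screen sees more inter-chromosome spread.

## Test problem sizes

The heavier checks run at sizes chosen to keep the full suite fast while
leaving no scientific content untested: the Viterbi-vs-enumeration check
uses 200 random instances of 2–12 bins (the oracle scores all `5^n`
paths explicitly, so 11- and 12-bin instances are sampled more sparsely);
k-mer counting is cross-checked against a dictionary scan on 100 random
references up to 100 kb; the coverage-robustness experiment uses 50
replicates of a 20 Mb five-chromosome genome with three planted CNVs of
300 kb–5 Mb each (one deletion, one duplication, one random), called at
30×, 20×, 15× and 10×, requiring every planted event to be recovered at
50% reciprocal overlap at every coverage; the aneuploidy screen is
checked on 100 replicates of a six-chromosome genome at 10× with one
chromosome at 1.5×.

## Known limitations

- Copy numbers above 3 are reported only as the CN>3 state; no exact
  copy-number refinement is attempted.
- Breakpoints are bin-resolution (50 bp) at best and inherit the HMM's
  boundary uncertainty (tens of bins at 10×); no split-read refinement.
- Chromosomes without any high-confidence region are skipped entirely —
  there is no mappability-weighted fallback baseline.
- The canonical/forward-only counting choice must match between track
  building and any externally produced count table.
- Balanced events (inversions, translocations) are invisible to a pure
  read-depth method.
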