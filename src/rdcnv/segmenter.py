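"""Five-state Poisson hidden Markov segmentation of binned read depth.

The copy-number states are CN=0 and CN=1 (loss), CN=2 (normal diploid),
CN=3 and CN>3 (gain). Emissions are Poisson on the rounded per-bin mean
depth with rates proportional to copy number: lambda(CN) = overall * CN/2,
except CN=0 which uses a small mismapping noise floor and CN>3 which uses
2x the overall coverage as a catch-all representative. The percentile
transform (overall coverage mapped to the 50th percentile, saturating at
200) is a monotone rescaling of depth retained for reporting; decoding
works on depth counts directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Union

import numpy as np
from scipy.special import gammaln

from .intervals import GenomicInterval
from .depth import DepthTrack

STATE_NAMES = ("CN0", "CN1", "CN2", "CN3", "CN>3")
CN0, CN1, CN2, CN3, CNGT3 = range(5)
LOSS_STATES = frozenset({CN0, CN1})
GAIN_STATES = frozenset({CN3, CNGT3})

# tie-break preference: toward the state closer to CN2, then the lower CN
_TIE_PREFERENCE = np.array([CN2, CN1, CN3, CN0, CNGT3], dtype=np.int64)


def state_type(state: int) -> str:
    """'loss', 'normal' or 'gain' for a state index."""
    if state in LOSS_STATES:
        return "loss"
    if state in GAIN_STATES:
        return "gain"
    return "normal"


def depth_to_percentile(bin_depth, overall: float):
    """Map a bin's depth onto the percentile scale of the sample.

    The overall coverage sits at the 50th percentile, so a bin at twice the
    overall coverage maps to 100; values saturate at 200 (the band above 180
    is reserved for copy numbers above two).
    """
    if overall <= 0:
        raise ValueError(f"overall coverage must be positive, got {overall}")
    arr = np.asarray(bin_depth, dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("negative bin depth")
    out = np.minimum(200.0, arr / overall * 50.0)
    return float(out) if np.isscalar(bin_depth) or out.ndim == 0 else out


def percentile_track(depth: DepthTrack, overall: float) -> Dict[str, np.ndarray]:
    """Percentile arrays for every chromosome of a depth track."""
    return {c: depth_to_percentile(a, overall) for c, a in depth.data.items()}


@dataclass
class HmmModel:
    """Frozen five-state Poisson HMM: emission rates, transitions, start."""

    rates: np.ndarray  # (5,) strictly increasing Poisson means, depth units
    transitions: np.ndarray  # (5, 5) row-stochastic
    initial: np.ndarray  # (5,) simplex

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        if self.rates.shape != (5,) or not (np.diff(self.rates) > 0).all():
            raise ValueError("emission rates must be 5 strictly increasing values")
        if self.transitions.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1 within 1e-12")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    def log_emissions(self, counts: np.ndarray) -> np.ndarray:
        """Poisson log-pmf of integer counts under every state, shape (n, 5)."""
        c = counts[:, None].astype(np.float64)
        lam = self.rates[None, :]
        return c * np.log(lam) - lam - gammaln(c + 1.0)


def build_hmm(
    overall: float,
    transition_t: float = 1e-8,
    noise_floor: float = 0.05,
    initial: Sequence[float] = (0.001, 0.009, 0.98, 0.009, 0.001),
) -> HmmModel:
    """Default model at a given overall coverage.

    Rates are (noise_floor, 0.5, 1, 1.5, 2) x overall; the transition matrix
    keeps probability 1 - 4t on the diagonal with t uniform off-diagonal
    (default 1e-8 per bin, a prior mean segment length far above the 50 kb
    reporting scale); the initial distribution encodes a diploid prior.
    """
    if overall <= 0:
        raise ValueError(f"overall coverage must be positive, got {overall}")
    rates = overall * np.array([noise_floor, 0.5, 1.0, 1.5, 2.0])
    trans = np.full((5, 5), transition_t, dtype=np.float64)
    np.fill_diagonal(trans, 1.0 - 4.0 * transition_t)
    return HmmModel(rates=rates, transitions=trans, initial=np.asarray(initial))


def _viterbi_impl(log_emit, log_trans, log_init, pref):
    n, S = log_emit.shape
    back = np.zeros((n, S), dtype=np.int64)
    score = log_init + log_emit[0]
    for t in range(1, n):
        new = np.empty(S)
        for j in range(S):
            best = -np.inf
            arg = pref[0]
            for pi in range(S):
                i = pref[pi]
                v = score[i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            new[j] = best + log_emit[t, j]
            back[t, j] = arg
        score = new
    best = -np.inf
    last = pref[0]
    for pi in range(S):
        j = pref[pi]
        if score[j] > best:
            best = score[j]
            last = j
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = last
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _viterbi_kernel = njit(cache=False)(_viterbi_impl)
except Exception:  # pragma: no cover
    _viterbi_kernel = _viterbi_impl


def decode_states(depth: Union[np.ndarray, DepthTrack], model: HmmModel):
    """Viterbi maximum-a-posteriori copy-number path for binned depth.

    Depth is rounded half-to-even to integer counts for the Poisson
    emissions. Ties are broken toward the state closer to CN2, then the
    lower copy number, so the decoding is deterministic. Accepts a single
    per-chromosome array (returns an int array) or a whole DepthTrack
    (returns a dict of arrays).
    """
    if isinstance(depth, DepthTrack):
        return {c: decode_states(a, model) for c, a in depth.data.items()}
    arr = np.asarray(depth, dtype=np.float64)
    if arr.size == 0:
        return np.zeros(0, dtype=np.int64)
    counts = np.rint(arr)
    log_emit = model.log_emissions(counts)
    with np.errstate(divide="ignore"):
        log_trans = np.log(model.transitions)
        log_init = np.log(model.initial)
    return _viterbi_kernel(log_emit, log_trans, log_init, _TIE_PREFERENCE)


@dataclass(frozen=True)
class Segment:
    """A maximal run of bins sharing one decoded copy-number state."""

    interval: GenomicInterval
    state: int
    n_bins: int
    mean_depth: float

    @property
    def type(self) -> str:
        return state_type(self.state)


def segments_from_states(
    states: np.ndarray,
    depth: np.ndarray,
    bin_size: int,
    chrom: str,
    chrom_length: int | None = None,
) -> List[Segment]:
    """Collapse a per-bin state path into maximal same-state segments.

    The returned segments tile the chromosome exactly; the last segment is
    clipped to the chromosome length when it does not end on a bin boundary.
    """
    states = np.asarray(states)
    if states.size != np.asarray(depth).size:
        raise ValueError("states and depth must align bin-for-bin")
    if states.size == 0:
        return []
    if chrom_length is None:
        chrom_length = states.size * bin_size
    breaks = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [states.size]))
    out = []
    for s, e in zip(starts, ends):
        out.append(
            Segment(
                interval=GenomicInterval(
                    chrom, int(s) * bin_size, min(int(e) * bin_size, chrom_length)
                ),
                state=int(states[s]),
                n_bins=int(e - s),
                mean_depth=float(np.mean(depth[s:e])),
            )
        )
    return out
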