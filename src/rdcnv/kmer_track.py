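"""k-mer multiplicity ("uniqueness") tracks over a reference genome.

A position is uniquely mappable when the k-mer starting there occurs exactly
once in the reference. The track stores, for every position of every
chromosome, one printable ASCII character encoding ``floor(log2(m)) + 33``
where ``m`` is the multiplicity of the k-mer beginning at that position.
Multiplicity 1 therefore encodes to ``'!'`` (code 33), the first printable
character. Positions with no defined k-mer (windows containing N, and the
last k-1 positions of each chromosome) carry the pad character ``'{'``
(code 123); the pad is documented in the file header and would only collide
with a real multiplicity of at least 2^90, which no physical genome reaches.

Counting uses the canonical form of each k-mer (the lexicographic minimum of
the forward sequence and its reverse complement) by default, matching the
convention of standard k-mer counters; forward-only counting is available
for tests and controlled experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Union

import numpy as np

from .intervals import GenomicInterval

ENCODE_OFFSET = 33  # code of the first printable ASCII character
ENCODE_CAP = 126  # last printable ASCII character
PAD_CODE = 123  # '{' -- positions with no defined k-mer
PAD_CHAR = chr(PAD_CODE)

_BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODES[_b] = _i
    _BASE_CODES[_b + 32] = _i  # lower case


def encode_multiplicity(m: int) -> str:
    """Encode a k-mer multiplicity as a single printable character.

    Returns the character with code ``floor(log2(m)) + 33``, saturating at
    code 126. Multiplicity zero is represented by the pad character and is
    rejected here.
    """
    if m < 1:
        raise ValueError(f"multiplicity must be >= 1, got {m}; zero is the pad")
    return chr(min(ENCODE_CAP, ENCODE_OFFSET + (int(m).bit_length() - 1)))


def decode_code(code: int) -> int:
    """Inverse of the encoding up to the log2 class: returns floor(log2(m))."""
    if not ENCODE_OFFSET <= code <= ENCODE_CAP:
        raise ValueError(f"character code {code} outside printable encoding range")
    return code - ENCODE_OFFSET


def _sequence_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODES[arr]


def _window_codes(codes: np.ndarray, k: int):
    """Forward codes, reverse-complement codes and a validity mask for every
    full window. Uses a vectorised base-4 rolling encoding; k <= 31 keeps
    codes within uint64 exactly.
    """
    n = codes.size - k + 1
    valid_base = codes < 4
    # windows containing any non-ACGT base are undefined
    cs = np.concatenate(([0], np.cumsum(~valid_base)))
    valid = (cs[k:] - cs[:-k]) == 0
    safe = np.where(valid_base, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd *= np.uint64(4)
        fwd += safe[j : j + n]
    rc = np.zeros(n, dtype=np.uint64)
    comp = np.uint64(3) - safe
    for j in range(k - 1, -1, -1):
        rc *= np.uint64(4)
        rc += comp[j : j + n]
    return np.where(valid, fwd, np.uint64(0)), np.where(valid, rc, np.uint64(0)), valid  # type: ignore[return-value]


def count_kmers(
    reference: Mapping[str, str], k: int, canonical: bool = True
) -> Dict[str, np.ndarray]:
    """Per-position k-mer multiplicities over a whole reference.

    For every position that begins a full k-length window with no ambiguous
    base, the returned value is the number of occurrences of that k-mer in
    the entire reference (canonical-form counting by default). Undefined
    windows, and the trailing k-1 positions of each chromosome, get 0.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not reference:
        raise ValueError("reference is empty")
    if k > 31:
        raise ValueError(f"k={k} exceeds the 31-mer limit of the 2-bit encoding")
    longest = max(len(s) for s in reference.values())
    if k > longest:
        raise ValueError(
            f"k={k} is larger than the longest chromosome ({longest} bp); "
            "no k-mer window fits"
        )

    # pool every window across chromosomes; undefined windows get a sentinel
    # key that no real <=31-mer code (< 4^31) can collide with
    sentinel = np.uint64(0xFFFFFFFFFFFFFFFF)
    keys: List[np.ndarray] = []
    offsets: Dict[str, tuple[int, int]] = {}
    pos = 0
    for name, seq in reference.items():
        if len(seq) < k:
            offsets[name] = (pos, pos)
            continue
        codes = _sequence_to_codes(seq)
        fwd, rc, valid = _window_codes(codes, k)
        key = np.minimum(fwd, rc) if canonical else fwd
        key = np.where(valid, key, sentinel)
        keys.append(key)
        offsets[name] = (pos, pos + key.size)
        pos += key.size

    pooled = np.concatenate(keys) if keys else np.zeros(0, dtype=np.uint64)
    uniq, inverse, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    mult_all = counts[inverse].astype(np.uint32)
    mult_all[pooled == sentinel] = 0

    result: Dict[str, np.ndarray] = {}
    for name, seq in reference.items():
        lo, hi = offsets[name]
        mult = np.zeros(len(seq), dtype=np.uint32)
        mult[: hi - lo] = mult_all[lo:hi]
        result[name] = mult
    return result


@dataclass
class KmerUniquenessTrack:
    """Per-chromosome ASCII-encoded k-mer multiplicity signal.

    ``encoded`` maps chromosome name to a uint8 array of character codes,
    one per position; chromosome order is preserved.
    """

    k: int
    encoded: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chrom_names(self) -> List[str]:
        return list(self.encoded)

    def chrom_length(self, chrom: str) -> int:
        return int(self.encoded[chrom].size)

    def _codes(self, region: GenomicInterval) -> np.ndarray:
        if region.chrom not in self.encoded:
            raise KeyError(f"unknown chromosome {region.chrom!r}")
        arr = self.encoded[region.chrom]
        if region.end > arr.size:
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {arr.size}"
            )
        return arr[region.start : region.end]

    def fraction_unique(self, region: GenomicInterval) -> float:
        """Fraction of defined positions in ``region`` whose k-mer is unique.

        Pad positions do not count toward the denominator; an all-pad region
        returns 0.0.
        """
        codes = self._codes(region)
        defined = int(np.count_nonzero(codes != PAD_CODE))
        if defined == 0:
            return 0.0
        unique = int(np.count_nonzero(codes == ENCODE_OFFSET))
        return unique / defined

    def find_high_confidence_regions(
        self, min_size: int = 20_000
    ) -> List[GenomicInterval]:
        """Maximal runs of strictly unique positions longer than ``min_size``.

        These are the regions used for unbiased coverage estimation: every
        k-mer inside occurs exactly once in the reference.
        """
        if min_size < 1:
            raise ValueError("min_size must be >= 1")
        out: List[GenomicInterval] = []
        for chrom in self.chrom_names:
            mask = self.encoded[chrom] == ENCODE_OFFSET
            if not mask.any():
                continue
            padded = np.concatenate(([False], mask, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            starts, ends = edges[::2], edges[1::2]
            for s, e in zip(starts, ends):
                if e - s > min_size:
                    out.append(GenomicInterval(chrom, int(s), int(e)))
        return out


def build_track(
    reference: Mapping[str, str], k: int = 25, canonical: bool = True
) -> KmerUniquenessTrack:
    """Count k-mers over ``reference`` and encode them into a track."""
    mult = count_kmers(reference, k, canonical=canonical)
    encoded: Dict[str, np.ndarray] = {}
    for name, m in mult.items():
        codes = np.full(m.size, PAD_CODE, dtype=np.uint8)
        defined = m > 0
        if defined.any():
            # floor(log2(m)): exact in float64 for counts far below 2^53
            logs = np.floor(np.log2(m[defined].astype(np.float64))).astype(np.int64)
            codes[defined] = np.minimum(logs + ENCODE_OFFSET, ENCODE_CAP).astype(np.uint8)
        encoded[name] = codes
    return KmerUniquenessTrack(k=k, encoded=encoded)


def write_track(track: KmerUniquenessTrack, destination: Union[str, Path]) -> None:
    """Serialize a track as a FASTA-dialect file (one record per chromosome)."""
    with open(destination, "w") as fh:
        for chrom in track.chrom_names:
            fh.write(f">{chrom} k={track.k} pad={PAD_CODE}\n")
            body = track.encoded[chrom].tobytes().decode("ascii")
            for i in range(0, len(body), 80):
                fh.write(body[i : i + 80])
                fh.write("\n")


class TrackParseError(ValueError):
    pass


def read_track(source: Union[str, Path]) -> KmerUniquenessTrack:
    """Read a track written by :func:`write_track`; validates every character."""
    k = None
    encoded: Dict[str, List[np.ndarray]] = {}
    order: List[str] = []
    current: str | None = None
    with open(source) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                fields = line[1:].split()
                if not fields:
                    raise TrackParseError(f"line {lineno}: empty FASTA header")
                current = fields[0]
                if current in encoded:
                    raise TrackParseError(
                        f"line {lineno}: duplicate chromosome {current!r}"
                    )
                for f in fields[1:]:
                    if f.startswith("k="):
                        k = int(f[2:])
                encoded[current] = []
                order.append(current)
                continue
            if current is None:
                raise TrackParseError(f"line {lineno}: sequence before any header")
            arr = np.frombuffer(line.encode("latin-1"), dtype=np.uint8)
            bad = (arr < ENCODE_OFFSET) | (arr > ENCODE_CAP)
            if bad.any():
                pos = int(np.flatnonzero(bad)[0])
                raise TrackParseError(
                    f"line {lineno}: character code {int(arr[pos])} at column "
                    f"{pos + 1} outside printable encoding range"
                )
            encoded[current].append(arr)
    if k is None:
        raise TrackParseError("no 'k=' attribute found in any header")
    return KmerUniquenessTrack(
        k=k,
        encoded={
            c: (np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8))
            for c, parts in encoded.items()
        },
    )
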