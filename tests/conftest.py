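"""Shared fixtures: small synthetic references, tracks and depth data."""

import numpy as np
import pytest

from rdcnv.intervals import GenomicInterval
from rdcnv.kmer_track import ENCODE_OFFSET, PAD_CODE, KmerUniquenessTrack
from rdcnv.segmenter import Segment


def make_track(chrom_specs, k=25):
    """Build a track directly from (chrom, [(code, run_length), ...]) specs."""
    encoded = {}
    for chrom, runs in chrom_specs.items():
        parts = [np.full(n, code, dtype=np.uint8) for code, n in runs]
        encoded[chrom] = np.concatenate(parts)
    return KmerUniquenessTrack(k=k, encoded=encoded)


def make_segments(chrom, runs, bin_size=50, depth_by_state=None):
    """Tiling Segments from (state, length) runs starting at coordinate 0."""
    depth_by_state = depth_by_state or {0: 1.5, 1: 15.0, 2: 30.0, 3: 45.0, 4: 60.0}
    out = []
    pos = 0
    for state, length in runs:
        out.append(
            Segment(
                interval=GenomicInterval(chrom, pos, pos + length),
                state=state,
                n_bins=length // bin_size,
                mean_depth=depth_by_state[state],
            )
        )
        pos += length
    return out


@pytest.fixture(scope="session")
def unique_reference():
    """A two-chromosome random reference; k-mers are unique w.h.p."""
    rng = np.random.default_rng(2024)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        name: bases[rng.integers(0, 4, size=n)].tobytes().decode()
        for name, n in [("chrA", 60_000), ("chrB", 40_000)]
    }
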