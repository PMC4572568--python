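import numpy as np
import pytest

from goshift.intervals import AnnotationTrack, GenomicInterval
from goshift.simulate import SimConfig, simulate_genome


def random_track(rng, n, span=10_000, chrom="chr1", max_len=60):
    ivs = []
    for _ in range(n):
        s = int(rng.integers(0, span - 2))
        e = int(rng.integers(s + 1, min(s + max_len, span) + 1))
        ivs.append(GenomicInterval(chrom, s, e))
    return AnnotationTrack("t", ivs)


def coverage_oracle(track, span=10_000, chrom="chr1"):
    """Per-base boolean union — the brute-force coverage oracle."""
    hit = np.zeros(span, dtype=bool)
    for iv in track.intervals:
        if iv.chrom == chrom:
            hit[iv.start : iv.end] = True
    return hit


@pytest.fixture(scope="session")
def small_genome():
    """A tiny synthetic genome for unit-level checks (seconds to build)."""
    cfg = SimConfig(
        n_chromosomes=4,
        chrom_length=1_000_000,
        n_variants=2_000,
        ld_block_length=20_000,
        seed=11,
    )
    return simulate_genome(cfg)
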