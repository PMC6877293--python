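import numpy as np
import pytest

from htaseq import covtrack, synthgen
from htaseq.seqio import Fragment, Genome


@pytest.fixture(scope="session")
def random_genome() -> Genome:
    """10 kb circular i.i.d. genome at 50% GC."""
    return synthgen.generate_genome(synthgen.GenomeSpec(length=10_000, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_coverage(fragments, genome_length: int) -> np.ndarray:
    """Independent per-base counting oracle (circular)."""
    cov = np.zeros(genome_length)
    for f in fragments:
        for p in range(f.start, f.end):
            cov[p % genome_length] += 1
    return cov


def random_fragments(rng, genome_length: int, n: int, chrom: str = "g",
                     min_len: int = 20, max_len: int = 120) -> list[Fragment]:
    starts = rng.integers(0, genome_length, size=n)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return [Fragment(chrom=chrom, start=int(s), end=int(s + L))
            for s, L in zip(starts, lengths)]
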