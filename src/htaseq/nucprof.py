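"""Dyad-relative nucleotide-class profiles.

Histone-like DNA benders leave a sequence signature in protected
fragments: strong/strong (SS = CC|CG|GC|GG) and weak/weak
(WW = AA|AT|TA|TT) dinucleotide proportions oscillate symmetrically
around the dyad, while purine/purine (RR) vs pyrimidine/pyrimidine
(YY) steps and A|T vs G|C mononucleotides are asymmetric across it.
Profiles are computed on the reference strand over reads of a defined
length, after quality/duplicate/peak-overlap filtering, and compared
against a background expectation from uniformly sampled genomic
regions.

Offsets are indexed so the dyad base is offset 0; the dinucleotide at
offset d spans genomic positions [dyad+d, dyad+d+2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .peakcall import Peak
from .seqio import Fragment, Genome

#: Dinucleotide and mononucleotide class membership.
CLASS_MEMBERS: dict[str, frozenset[str]] = {
    "SS": frozenset({"CC", "CG", "GC", "GG"}),
    "WW": frozenset({"AA", "AT", "TA", "TT"}),
    "RR": frozenset({"AA", "AG", "GA", "GG"}),
    "YY": frozenset({"CC", "CT", "TC", "TT"}),
    "RY": frozenset({"AC", "AT", "GC", "GT"}),
    "YR": frozenset({"CA", "CG", "TA", "TG"}),
    "SW": frozenset({"CA", "CT", "GA", "GT", "AC", "AG", "TC", "TG"}),
    "mono_A": frozenset({"A"}),
    "mono_T": frozenset({"T"}),
    "mono_G": frozenset({"G"}),
    "mono_C": frozenset({"C"}),
    "mono_AT": frozenset({"A", "T"}),
    "mono_GC": frozenset({"G", "C"}),
}


def _is_mono(cls: str) -> bool:
    return cls.startswith("mono")


@dataclass(frozen=True)
class ReadFilterConfig:
    """Read selection before profiling: mean base quality >= 30, >= 90%
    of the fragment inside a called peak, duplicates collapsed."""

    min_mean_quality: float = 30.0
    min_peak_overlap_fraction: float = 0.9
    deduplicate: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_peak_overlap_fraction <= 1:
            raise ValueError("overlap fraction must be in (0, 1]")


def filter_reads(
    fragments: Sequence[Fragment],
    peaks: Sequence[Peak],
    config: ReadFilterConfig = ReadFilterConfig(),
) -> list[Fragment]:
    """Apply the profiling read filter.

    Fragments with null quality are retained (quality unknown, not
    failing). Overlap = max over peaks of (intersection length /
    fragment length). First occurrence of each (chrom, start, end)
    kept when deduplicating.
    """
    starts = np.array([p.start for p in peaks], dtype=np.int64)
    ends = np.array([p.end for p in peaks], dtype=np.int64)
    kept: list[Fragment] = []
    seen: set[tuple[str, int, int]] = set()
    for f in fragments:
        if f.mean_quality is not None and f.mean_quality < config.min_mean_quality:
            continue
        if starts.size:
            inter = np.minimum(ends, f.end) - np.maximum(starts, f.start)
            best = inter.max() / f.length if inter.size else 0.0
        else:
            best = 0.0
        if best < config.min_peak_overlap_fraction:
            continue
        key = (f.chrom, f.start, f.end)
        if config.deduplicate:
            if key in seen:
                continue
            seen.add(key)
        kept.append(f)
    return kept


def _class_indicator(genome: Genome, cls: str) -> np.ndarray:
    """indicator[p] = 1 when the (di)nucleotide starting at p is in cls.

    Positions involving N are 0 (excluded from k-mer statistics).
    Dinucleotides wrap circularly on circular genomes.
    """
    members = CLASS_MEMBERS[cls]
    seq = genome.sequence
    n = len(seq)
    if _is_mono(cls):
        return np.fromiter((b in members for b in seq), dtype=bool, count=n)
    ext = seq + (seq[0] if genome.circular else "N")
    return np.fromiter(
        (ext[i : i + 2] in members for i in range(n)), dtype=bool, count=n
    )


def positional_class_profile(
    fragments: Sequence[Fragment],
    genome: Genome,
    cls: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Proportion of fragments whose (di)nucleotide at each dyad-relative
    offset belongs to ``cls``.

    All fragments must share one length L; offsets run
    [−⌊L/2⌋, +⌊L/2⌋−1]. Returns (offsets, proportions).
    """
    if not fragments:
        raise ValueError("no fragments")
    L = fragments[0].length
    if any(f.length != L for f in fragments):
        raise ValueError("all fragments must have the same length")
    if not _is_mono(cls) and L < 2:
        raise ValueError("dinucleotide classes need fragment length >= 2")
    half = L // 2
    offsets = np.arange(-half, half)
    ind = _class_indicator(genome, cls)
    n = len(genome)
    dyads = np.array([f.dyad % n for f in fragments], dtype=np.int64)
    pos = (dyads[:, None] + offsets[None, :]) % n
    props = ind[pos].mean(axis=0)
    return offsets, props


def background_expectation(
    genome: Genome,
    region_size: int,
    cls: str,
    n: int = 25_000,
    seed: int = 0,
) -> float:
    """Expected class proportion from ``n`` uniformly placed regions of
    ``region_size`` bp (chance line for the dyad profiles)."""
    if region_size > len(genome):
        raise ValueError("region size exceeds genome")
    rng = np.random.default_rng(seed)
    ind = _class_indicator(genome, cls)
    glen = len(genome)
    span = region_size if _is_mono(cls) else region_size - 1
    if span < 1:
        raise ValueError("region too small for a dinucleotide class")
    if genome.circular:
        starts = rng.integers(0, glen, size=n)
    else:
        starts = rng.integers(0, glen - span + 1, size=n)
    # region proportions via prefix sums; circular regions wrap
    csum = np.concatenate([[0], np.cumsum(np.concatenate([ind, ind[:span]]))])
    region_counts = csum[starts + span] - csum[starts]
    return float((region_counts / span).mean())


def peak_gc_profile(
    peaks: Sequence[Peak],
    genome: Genome,
    flank: int,
) -> np.ndarray:
    """Mean G|C indicator by offset across (re-oriented) peak windows."""
    if not peaks:
        raise ValueError("no peaks")
    ind = _class_indicator(genome, "mono_GC").astype(float)
    n = len(genome)
    offsets = np.arange(-flank, flank + 1)
    rows = np.empty((len(peaks), offsets.size))
    for i, p in enumerate(peaks):
        window = ind[(p.center + offsets) % n]
        rows[i] = window[::-1] if p.orientation == "flipped" else window
    return rows.mean(axis=0)


def write_profile(offsets: np.ndarray, props: np.ndarray, cls: str,
                  n_fragments: int, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tproportion\tclass\tn_fragments\n")
        for o, p in zip(offsets, props):
            fh.write(f"{o}\t{p:.6f}\t{cls}\t{n_fragments}\n")
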