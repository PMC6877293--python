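"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the features of an archaeal MNase-seq
experiment that the downstream modules rely on: a circular genome with
spatially varying GC, an occupancy landscape driven by planted k-mer
weights (ground truth for the LASSO model), a bimodal protected-
fragment length mixture (~50 bp minimal and ~85 bp extended
footprints), edge-biased small fragments inside broad footprints
(nucleation-extension asymmetry), an origin-terminus replication
copy-number gradient, PCR-duplicate structure, and EMSA oligo pools
whose slow/fast band split follows a planted composition affinity.

Every generator is a pure function of its spec plus a seed; sub-streams
are derived deterministically per operation from one global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .covtrack import CoverageTrack
from .kmerlasso import KmerFeatureSet
from .seqio import Fragment, Genome

# fixed per-operation stream identifiers (sub-stream derivation)
_OP_GENOME = 1
_OP_FRAGMENTS = 2
_OP_FOOTPRINTS = 3
_OP_EMSA = 4

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, op: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), op]))


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GenomeSpec:
    """A circular genome as GC-homogeneous segments tiling [0, length)."""

    length: int
    gc_profile: tuple[tuple[int, int, float], ...] = ()
    circular: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        profile = tuple(self.gc_profile) or ((0, self.length, 0.5),)
        object.__setattr__(self, "gc_profile", profile)
        pos = 0
        for start, end, gc in profile:
            if start != pos or end <= start:
                raise ValueError("gc_profile segments must tile [0, length) in order")
            if not 0 <= gc <= 1:
                raise ValueError(f"gc fraction {gc} outside [0, 1]")
            pos = end
        if pos != self.length:
            raise ValueError("gc_profile does not cover the genome")


def generate_genome(spec: GenomeSpec, id: str = "synth") -> Genome:
    """Draw an i.i.d. sequence with per-segment GC composition."""
    rng = _rng(spec.seed, _OP_GENOME)
    arr = np.empty(spec.length, dtype=np.uint8)
    for start, end, gc in spec.gc_profile:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        arr[start:end] = BASES[rng.choice(4, size=end - start, p=p)]
    return Genome(id=id, sequence=arr.tobytes().decode("ascii"), circular=spec.circular)


# ---------------------------------------------------------------------------
# occupancy


@dataclass(frozen=True)
class PlantedOccupancyModel:
    """Ground-truth linear sequence model: occupancy(p) = intercept +
    sum of weight(kmer) * windowed frequency(kmer at p)."""

    kmer_weights: dict[str, float]
    window: int = 51
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2 == 0:
            raise ValueError("window must be odd and positive")
        for kmer in self.kmer_weights:
            if not 1 <= len(kmer) <= 4 or set(kmer) - set("ACGT"):
                raise ValueError(f"invalid k-mer {kmer!r} (k <= 4 over ACGT)")


def plant_occupancy(genome: Genome, model: PlantedOccupancyModel) -> CoverageTrack:
    """Evaluate the planted model per bp; shift/clip to non-negative."""
    if model.window > len(genome):
        raise ValueError("window exceeds genome length")
    fs = KmerFeatureSet(genome, kmers=list(model.kmer_weights), window_sizes=(model.window,))
    values = np.full(len(genome), float(model.intercept))
    for kmer, weight in model.kmer_weights.items():
        values += weight * fs.feature(kmer, model.window)
    lo = values.min()
    if lo < 0:
        values = values - lo
    values = np.clip(values, 0.0, None)
    return CoverageTrack(genome_id=genome.id, values=values, size_class="all",
                         normalization="raw")


# ---------------------------------------------------------------------------
# fragment sampling


@dataclass(frozen=True)
class FragmentMixtureSpec:
    """Bimodal protected-fragment length mixture.

    Defaults follow the observed footprint classes: small mode ~50 bp,
    large mode ~85 bp, with the twin large sub-modes treated jointly.
    """

    small_mode: int = 50
    large_mode: int = 85
    small_sd: float = 5.0
    large_sd: float = 7.0
    p_small: float = 0.5
    n_fragments: int = 100_000
    duplicate_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_small <= 1:
            raise ValueError("p_small must be a probability")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        for mode in (self.small_mode, self.large_mode):
            if not 20 <= mode <= 200:
                raise ValueError("length modes must lie within [20, 200]")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")


@dataclass(frozen=True)
class ReplicationGradientSpec:
    """Linear copy-number decay with circular distance from the origin."""

    origin: int
    max_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.max_ratio < 1:
            raise ValueError("max_ratio must be >= 1")

    def multiplier(self, length: int) -> np.ndarray:
        """Per-bp copy-number multiplier (max_ratio at origin, 1 at terminus)."""
        if not 0 <= self.origin < length:
            raise ValueError("origin outside genome")
        pos = np.arange(length)
        d = np.abs(pos - self.origin)
        d = np.minimum(d, length - d)
        dmax = length // 2
        return self.max_ratio - (self.max_ratio - 1.0) * d / dmax


def _truncated_lengths(rng: np.random.Generator, mode: float, sd: float,
                       size: int, lo: int = 20, hi: int = 200) -> np.ndarray:
    """Discretized Gaussian truncated to [lo, hi] by resampling."""
    out = np.rint(rng.normal(mode, sd, size=size)).astype(np.int64)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.rint(rng.normal(mode, sd, size=int(bad.sum()))).astype(np.int64)
        bad = (out < lo) | (out > hi)
    return out


def sample_fragments(
    occupancy: CoverageTrack,
    mix: FragmentMixtureSpec,
    gradient: ReplicationGradientSpec | None = None,
    chrom: str | None = None,
) -> list[Fragment]:
    """Draw fragments with centers proportional to occupancy x gradient.

    Exactly ``mix.n_fragments`` records are returned; a
    ``duplicate_rate`` fraction are exact coordinate copies of other
    sampled fragments (PCR-duplicate structure). Fragments crossing the
    origin of the circular genome keep end > genome length.
    """
    weights = occupancy.values.astype(float).copy()
    if gradient is not None:
        weights = weights * gradient.multiplier(weights.size)
    total = weights.sum()
    if total <= 0:
        raise ValueError("occupancy landscape is all zero; nothing to sample")
    rng = _rng(mix.seed, _OP_FRAGMENTS)
    n = mix.n_fragments
    n_dup = int(round(n * mix.duplicate_rate))
    n_unique = n - n_dup
    p = weights / total
    glen = weights.size
    centers = rng.choice(glen, size=n_unique, p=p)
    is_small = rng.random(n_unique) < mix.p_small
    lengths = np.empty(n_unique, dtype=np.int64)
    lengths[is_small] = _truncated_lengths(rng, mix.small_mode, mix.small_sd,
                                           int(is_small.sum()))
    lengths[~is_small] = _truncated_lengths(rng, mix.large_mode, mix.large_sd,
                                            int((~is_small).sum()))
    name = chrom or occupancy.genome_id
    starts = (centers - lengths // 2) % glen
    frags = [
        Fragment(chrom=name, start=int(s), end=int(s + L))
        for s, L in zip(starts, lengths)
    ]
    if n_dup:
        for idx in rng.integers(0, n_unique, size=n_dup):
            frags.append(frags[int(idx)])
    return frags


# ---------------------------------------------------------------------------
# broad footprints with edge-biased small fragments


@dataclass(frozen=True)
class FootprintTruth:
    """Per-site ground truth for orientation tests."""

    site: int
    preferred_edge: str  # "left" | "right"


def sample_broad_footprints(
    nucleation_sites: Sequence[int],
    n_per_site: int,
    small_len: int = 50,
    large_len: int = 84,
    edge_bias: float = 1.0,
    seed: int = 0,
    genome_length: int | None = None,
    chrom: str = "synth",
) -> tuple[list[Fragment], list[FootprintTruth]]:
    """Emit large fragments centered on each site plus small fragments
    whose centers sit at one footprint edge with probability edge_bias.

    Each site's preferred edge is drawn once and recorded in the
    returned truth metadata. Small-fragment centers sit at offset
    +/- (large_len - small_len) / 2 from the site.
    """
    if not 0.5 <= edge_bias <= 1:
        raise ValueError("edge_bias must be in [0.5, 1]")
    rng = _rng(seed, _OP_FOOTPRINTS)
    offset = (large_len - small_len) // 2
    frags: list[Fragment] = []
    truth: list[FootprintTruth] = []
    glen = genome_length

    def make(center: int, length: int) -> Fragment:
        start = center - length // 2
        if glen is not None:
            start %= glen
        return Fragment(chrom=chrom, start=int(start), end=int(start + length))

    for site in nucleation_sites:
        preferred = "left" if rng.random() < 0.5 else "right"
        truth.append(FootprintTruth(site=int(site), preferred_edge=preferred))
        sign = -1 if preferred == "left" else 1
        for _ in range(n_per_site):
            frags.append(make(site, large_len))
        for _ in range(n_per_site):
            s = sign if rng.random() < edge_bias else -sign
            frags.append(make(site + s * offset, small_len))
    return frags, truth


def write_footprint_truth(truth: Sequence[FootprintTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tpreferred_edge\n")
        for t in truth:
            fh.write(f"{t.site}\t{t.preferred_edge}\n")


# ---------------------------------------------------------------------------
# EMSA oligo pools


@dataclass(frozen=True)
class EmsaDesign:
    """Backbone oligos with randomized dinucleotide slots.

    backbones: (id, 100 bp sequence) pairs; randomized_positions maps
    each backbone id to its 8 non-overlapping dinucleotide start
    offsets; planted_affinity maps composition features ("GpC_count",
    "GC_content", "intercept") to logistic weights for band assignment
    (used only when generating synthetic pools).
    """

    backbones: tuple[tuple[str, str], ...]
    randomized_positions: dict[str, tuple[int, ...]]
    planted_affinity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.backbones:
            raise ValueError("design needs at least one backbone")
        for bid, seq in self.backbones:
            offs = self.randomized_positions.get(bid)
            if offs is None:
                raise ValueError(f"no randomized positions for backbone {bid}")
            if len(offs) != 8:
                raise ValueError(f"backbone {bid}: need exactly 8 dinucleotide slots")
            spans = sorted(offs)
            for i, o in enumerate(spans):
                if o < 0 or o + 2 > len(seq):
                    raise ValueError(f"backbone {bid}: slot {o} outside oligo")
                if i and spans[i - 1] + 2 > o:
                    raise ValueError(f"backbone {bid}: overlapping slots")

    def fixed_mask(self, backbone_id: str) -> np.ndarray:
        """Boolean mask of non-randomized positions of one backbone."""
        seq = dict(self.backbones)[backbone_id]
        mask = np.ones(len(seq), dtype=bool)
        for o in self.randomized_positions[backbone_id]:
            mask[o : o + 2] = False
        return mask

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("backbone_id\tsequence\trandomized_offsets\n")
            for bid, seq in self.backbones:
                offs = ",".join(str(o) for o in self.randomized_positions[bid])
                fh.write(f"{bid}\t{seq}\t{offs}\n")

    @classmethod
    def from_tsv(cls, path) -> "EmsaDesign":
        backbones: list[tuple[str, str]] = []
        positions: dict[str, tuple[int, ...]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("backbone_id"):
                raise ValueError(f"{path}: missing design header")
            for line in fh:
                if not line.strip():
                    continue
                bid, seq, offs = line.rstrip("\n").split("\t")
                backbones.append((bid, seq.upper()))
                positions[bid] = tuple(int(o) for o in offs.split(","))
        return cls(backbones=tuple(backbones), randomized_positions=positions)


def make_emsa_design(
    n_backbones: int = 5,
    oligo_length: int = 100,
    gc_fractions: Sequence[float] = (0.25, 0.35, 0.45, 0.55, 0.65),
    planted_affinity: dict[str, float] | None = None,
    seed: int = 0,
) -> EmsaDesign:
    """Random backbones spanning a GC-content range (mirroring oligos
    picked from genomic regions of very low to very high occupancy),
    each with 8 evenly spaced dinucleotide slots."""
    if len(gc_fractions) != n_backbones:
        raise ValueError("one gc fraction per backbone")
    rng = _rng(seed, _OP_EMSA)
    slots = tuple(range(10, 10 + 8 * 10, 10))  # 8 non-overlapping dinucleotides
    backbones = []
    positions = {}
    for i, gc in enumerate(gc_fractions):
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = BASES[rng.choice(4, size=oligo_length, p=p)].tobytes().decode("ascii")
        bid = f"backbone{i + 1}"
        backbones.append((bid, seq))
        positions[bid] = slots
    return EmsaDesign(
        backbones=tuple(backbones),
        randomized_positions=positions,
        planted_affinity=dict(planted_affinity or {}),
    )


def count_gpc(sequence: str) -> int:
    """Occurrences of the GpC step (G immediately followed by C)."""
    return sum(1 for i in range(len(sequence) - 1) if sequence[i : i + 2] == "GC")


def gc_content(sequence: str) -> float:
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class EmsaPool:
    """A synthetic sequenced pool: per-read oligo sequence, band label,
    and ground truth (source backbone, slow-band probability)."""

    sequences: list[str]
    bands: list[str]                  # "slow" | "fast"
    true_backbones: list[str]
    slow_probabilities: np.ndarray

    def __len__(self) -> int:
        return len(self.sequences)


def generate_emsa_pool(design: EmsaDesign, n_reads: int, seed: int = 0) -> EmsaPool:
    """Fill randomized slots uniformly and assign bands by the planted
    affinity: P(slow) = logistic(intercept + sum weight_f * feature_f)."""
    rng = _rng(seed, _OP_EMSA)
    aff = design.planted_affinity
    n_bb = len(design.backbones)
    oligo_len = len(design.backbones[0][1])
    bb_idx = rng.integers(0, n_bb, size=n_reads)
    random_bases = BASES[rng.integers(0, 4, size=(n_reads, 16))]
    mat = np.empty((n_reads, oligo_len), dtype=np.uint8)
    for b, (bid, backbone) in enumerate(design.backbones):
        rows = bb_idx == b
        mat[rows] = np.frombuffer(backbone.encode("ascii"), dtype=np.uint8)
        for j, o in enumerate(design.randomized_positions[bid]):
            mat[rows, o] = random_bases[rows, 2 * j]
            mat[rows, o + 1] = random_bases[rows, 2 * j + 1]
    g, c = ord("G"), ord("C")
    score = np.full(n_reads, aff.get("intercept", 0.0))
    if "GpC_count" in aff:
        gpc = ((mat[:, :-1] == g) & (mat[:, 1:] == c)).sum(axis=1)
        score += aff["GpC_count"] * gpc
    if "GC_content" in aff:
        gcfrac = ((mat == g) | (mat == c)).mean(axis=1)
        score += aff["GC_content"] * gcfrac
    probs = 1.0 / (1.0 + np.exp(-score))
    slow = rng.random(n_reads) < probs
    blob = mat.tobytes().decode("ascii")
    sequences = [blob[i * oligo_len : (i + 1) * oligo_len] for i in range(n_reads)]
    bands = ["slow" if s else "fast" for s in slow]
    ids = [bid for bid, _ in design.backbones]
    true_backbones = [ids[i] for i in bb_idx]
    return EmsaPool(sequences=sequences, bands=bands,
                    true_backbones=true_backbones, slow_probabilities=probs)


def write_emsa_pool_truth(pool: EmsaPool, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_index\tbackbone\tband\tp_slow\n")
        for i, (bb, band, p) in enumerate(
            zip(pool.true_backbones, pool.bands, pool.slow_probabilities)
        ):
            fh.write(f"{i}\t{bb}\t{band}\t{p:.6f}\n")
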