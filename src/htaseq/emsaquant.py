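"""Quantification of EMSA band-sequencing (band-shift) experiments.

A library of 100 bp oligos — five genomic backbones, each diversified
at eight randomized dinucleotide slots — is incubated with limiting
protein and separated on a gel; the slow-migrating (protein-bound) and
fast bands are excised and sequenced. Each read is assigned to its
backbone by exact match at the non-randomized positions, and binding
preference is summarized as P_slow = n_slow / (n_slow + n_fast) per
composition class (oligo G+C content or GpC step count), with a
read-count-weighted Pearson correlation between composition and
P_slow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .synthgen import EmsaDesign, EmsaPool, count_gpc, gc_content


@dataclass(frozen=True)
class EmsaRead:
    """One sequenced oligo with its gel band."""

    sequence: str
    band: str  # "slow" | "fast"
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.band not in {"slow", "fast"}:
            raise ValueError(f"band must be 'slow' or 'fast', got {self.band!r}")


@dataclass(frozen=True)
class AssignedRead:
    read: EmsaRead
    backbone_id: str
    dinucleotides: tuple[str, ...]  # the 8 randomized slots, 5'->3'


def read_band_fastx(path, band: str, format: str = "fasta",
                    replicate: str = "r1") -> list[EmsaRead]:
    """Load one excised band's reads (FASTA or FASTQ)."""
    return [
        EmsaRead(sequence=str(rec.seq).upper(), band=band, replicate=replicate)
        for rec in SeqIO.parse(str(path), format)
    ]


def reads_from_pool(pool: EmsaPool, replicate: str = "r1") -> list[EmsaRead]:
    """Adapt a synthetic pool to the read interface."""
    return [
        EmsaRead(sequence=s, band=b, replicate=replicate)
        for s, b in zip(pool.sequences, pool.bands)
    ]


def _check_design_unambiguous(design: EmsaDesign) -> None:
    """Two backbones identical at their fixed positions cannot be told
    apart by any read; refuse such designs at load."""
    keys = []
    for bid, seq in design.backbones:
        mask = design.fixed_mask(bid)
        keys.append((len(seq), tuple(np.flatnonzero(mask)),
                     "".join(c for c, m in zip(seq, mask) if m)))
    if len(set(keys)) != len(keys):
        raise ValueError("ambiguous design: two backbones share all fixed positions")


def assign_reads(
    reads: Sequence[EmsaRead],
    design: EmsaDesign,
) -> tuple[list[AssignedRead], int]:
    """Assign each read to the unique backbone matching exactly at all
    non-randomized positions; extract the 8 randomized dinucleotides.

    Returns (assigned reads, number unassigned). Reads matching no
    backbone or more than one are unassigned — no mismatch tolerance,
    because the randomized slots make edit-distance assignment
    ambiguous.
    """
    _check_design_unambiguous(design)
    assigned: list[AssignedRead] = []
    n_unassigned = 0
    # group reads by length, compare fixed positions as byte matrices
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.sequence), []).append(i)
    for length, idxs in by_len.items():
        bbs = [(bid, seq) for bid, seq in design.backbones if len(seq) == length]
        if not bbs:
            n_unassigned += len(idxs)
            continue
        blob = "".join(reads[i].sequence for i in idxs).encode("ascii")
        mat = np.frombuffer(blob, dtype=np.uint8).reshape(len(idxs), length)
        hit_count = np.zeros(len(idxs), dtype=np.int64)
        hit_bid = np.full(len(idxs), -1, dtype=np.int64)
        for b, (bid, seq) in enumerate(bbs):
            fidx = np.flatnonzero(design.fixed_mask(bid))
            ref = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[fidx]
            match = (mat[:, fidx] == ref).all(axis=1)
            hit_count += match
            hit_bid[match] = b
        for row, i in enumerate(idxs):
            if hit_count[row] != 1:
                n_unassigned += 1
                continue
            bid, _ = bbs[hit_bid[row]]
            seq = reads[i].sequence
            dinucs = tuple(seq[o : o + 2] for o in design.randomized_positions[bid])
            assigned.append(AssignedRead(read=reads[i], backbone_id=bid,
                                         dinucleotides=dinucs))
    return assigned, n_unassigned


def composition_value(sequence: str, composition: str) -> float:
    """Composition statistic of a full oligo.

    GC_content: integer percent over the whole oligo (backbone context
    included); GpC_count: number of GpC steps.
    """
    if composition == "GC_content":
        return float(round(100 * gc_content(sequence)))
    if composition == "GpC_count":
        return float(count_gpc(sequence))
    raise ValueError(f"unknown composition: {composition}")


def _batch_composition(sequences: Sequence[str], composition: str) -> np.ndarray:
    """Vectorized :func:`composition_value` for equal-length sequences."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        return np.array([composition_value(s, composition) for s in sequences])
    L = lengths.pop()
    mat = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(len(sequences), L)
    g, c = ord("G"), ord("C")
    if composition == "GpC_count":
        return ((mat[:, :-1] == g) & (mat[:, 1:] == c)).sum(axis=1).astype(float)
    if composition == "GC_content":
        return np.round(100 * ((mat == g) | (mat == c)).mean(axis=1))
    raise ValueError(f"unknown composition: {composition}")


def compute_pslow(
    assigned: Sequence[AssignedRead],
    composition: str = "GpC_count",
    exclude_backbones: Sequence[str] = (),
) -> pd.DataFrame:
    """P_slow per composition class, pooled over retained backbones.

    Returns a DataFrame with columns [x, n_slow, n_fast, p_slow]
    sorted by x. Excluded backbones (e.g. an AT-rich outlier whose
    behaviour is context-dependent) are dropped before grouping.
    """
    excluded = set(exclude_backbones)
    kept = [a for a in assigned if a.backbone_id not in excluded]
    if not kept:
        raise ValueError("no assigned reads after backbone exclusion")
    xs = _batch_composition([a.read.sequence for a in kept], composition)
    df = pd.DataFrame({"x": xs, "band": [a.read.band for a in kept]})
    table = (
        df.assign(slow=lambda d: d["band"] == "slow")
        .groupby("x", as_index=False)
        .agg(n_slow=("slow", "sum"), n_fast=("slow", lambda s: int((~s).sum())))
    )
    table["p_slow"] = table["n_slow"] / (table["n_slow"] + table["n_fast"])
    return table.sort_values("x", ignore_index=True)


def per_backbone_pslow(assigned: Sequence[AssignedRead]) -> pd.DataFrame:
    """P_slow per backbone (reproducibility / backbone-rank checks)."""
    rows = [(a.backbone_id, a.read.band) for a in assigned]
    df = pd.DataFrame(rows, columns=["backbone", "band"])
    table = (
        df.assign(slow=lambda d: d["band"] == "slow")
        .groupby("backbone", as_index=False)
        .agg(n_slow=("slow", "sum"), n_fast=("slow", lambda s: int((~s).sum())))
    )
    table["p_slow"] = table["n_slow"] / (table["n_slow"] + table["n_fast"])
    return table.sort_values("backbone", ignore_index=True)


def weighted_correlation(table: pd.DataFrame) -> float:
    """Pearson r between composition x and P_slow, weighted by the
    number of reads in each composition class."""
    if len(table) < 3:
        raise ValueError("need at least 3 composition groups")
    x = table["x"].to_numpy(dtype=float)
    p = table["p_slow"].to_numpy(dtype=float)
    w = (table["n_slow"] + table["n_fast"]).to_numpy(dtype=float)
    wsum = w.sum()
    xbar = (w * x).sum() / wsum
    pbar = (w * p).sum() / wsum
    cov = (w * (x - xbar) * (p - pbar)).sum()
    vx = (w * (x - xbar) ** 2).sum()
    vp = (w * (p - pbar) ** 2).sum()
    if vx <= 0 or vp <= 0:
        raise ValueError("zero weighted variance; correlation undefined")
    return float(cov / np.sqrt(vx * vp))


def bootstrap_correlation_ci(
    assigned: Sequence[AssignedRead],
    composition: str = "GpC_count",
    exclude_backbones: Sequence[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the weighted correlation, resampling
    reads with replacement."""
    rng = np.random.default_rng(seed)
    excluded = set(exclude_backbones)
    kept = [a for a in assigned if a.backbone_id not in excluded]
    xs = _batch_composition([a.read.sequence for a in kept], composition)
    slow = np.array([a.read.band == "slow" for a in kept])
    stats_out = []
    n = len(kept)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        df = pd.DataFrame({"x": xs[idx], "slow": slow[idx]})
        tb = df.groupby("x", as_index=False).agg(
            n_slow=("slow", "sum"), n_fast=("slow", lambda s: int((~s).sum()))
        )
        tb["p_slow"] = tb["n_slow"] / (tb["n_slow"] + tb["n_fast"])
        if len(tb) < 3:
            continue
        try:
            stats_out.append(weighted_correlation(tb))
        except ValueError:
            continue
    lo, hi = np.percentile(stats_out, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
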