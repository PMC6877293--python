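"""Canonical in-memory records and file I/O for the pipeline.

Internal convention: 0-based half-open coordinates everywhere. GFF3
(1-based closed) is converted at the boundary. Genomes may be circular;
a fragment spanning the origin of a circular genome is represented as a
single record with ``end > len(genome)`` and stays a single record on
write so that write∘read is the identity.

Readers are total on their format grammar: every input line either
parses or raises :class:`FormatError` carrying the line number. Nothing
is silently skipped.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

MAX_FRAGMENT_LENGTH = 1000


class FormatError(ValueError):
    """Malformed record in an input file; message carries the location."""


@dataclass(frozen=True)
class Genome:
    """A single (optionally circular) nucleotide sequence.

    Sequences are canonicalized to uppercase; only A/C/G/T/N allowed.
    """

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) == 0:
            raise ValueError("genome sequence must be non-empty")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in genome {self.id!r}: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at ``pos``, wrapping circularly when the genome is circular."""
        n = len(self.sequence)
        if self.circular:
            return self.sequence[pos % n]
        if not 0 <= pos < n:
            raise IndexError(f"position {pos} outside linear genome of length {n}")
        return self.sequence[pos]

    def window(self, start: int, end: int) -> str:
        """Subsequence [start, end), wrapping circularly if allowed."""
        if end <= start:
            raise ValueError("window end must exceed start")
        n = len(self.sequence)
        if 0 <= start and end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise IndexError(
                f"window [{start},{end}) outside linear genome of length {n}"
            )
        length = end - start
        start %= n
        reps = (start + length) // n + 1
        return (self.sequence * reps)[start : start + length]


@dataclass(frozen=True)
class Fragment:
    """A mapped protected fragment (merged read pair), 0-based half-open."""

    chrom: str
    start: int
    end: int
    mean_quality: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"fragment start {self.start} < 0")
        if self.start >= self.end:
            raise ValueError(
                f"fragment start {self.start} >= end {self.end} on {self.chrom}"
            )
        if not 1 <= self.length <= MAX_FRAGMENT_LENGTH:
            raise ValueError(
                f"fragment length {self.length} outside [1, {MAX_FRAGMENT_LENGTH}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def dyad(self) -> int:
        """Footprint center; floor convention for even lengths."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class SiteAnnotation:
    """A stranded genomic landmark (TSS, TES or coding start)."""

    chrom: str
    position: int
    strand: str
    kind: str = "TSS"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.position < 0:
            raise ValueError("site position must be >= 0")


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path, circular: bool = True) -> Genome:
    """Read a single-record FASTA as a :class:`Genome`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq), circular=circular)


def write_genome(genome: Genome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


# ---------------------------------------------------------------------------
# Fragments: BED6 (lingua franca) and optional BAM-like alignments


def read_fragments(path, format: str = "BED", genome: Genome | None = None) -> list[Fragment]:
    """Read mapped fragments.

    Parameters
    ----------
    format
        ``"BED"`` (3+ columns; column 5 is reused as mean quality when
        numeric and non-zero) or ``"BAM"`` (requires pysam at runtime).
    genome
        When given, coordinates are validated against its bounds
        (circular genomes accept ``end > len`` as origin-spanning).
    """
    fmt = format.upper()
    if fmt == "BED":
        return _read_fragments_bed(path, genome)
    if fmt in {"BAM", "SAM"}:
        return _read_fragments_alignment(path, genome)
    raise ValueError(f"unsupported fragment format: {format}")


def _validate_bounds(frag: Fragment, genome: Genome | None, where: str) -> None:
    if genome is None:
        return
    n = len(genome)
    limit = 2 * n if genome.circular else n
    if frag.start >= n or frag.end > limit:
        raise FormatError(
            f"{where}: fragment {frag.chrom}:{frag.start}-{frag.end} outside "
            f"genome of length {n}"
        )


def _read_fragments_bed(path, genome: Genome | None) -> list[Fragment]:
    frags: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            quality: float | None = None
            if len(cols) >= 5:
                try:
                    q = float(cols[4])
                    quality = q if q > 0 else None
                except ValueError:
                    quality = None
            try:
                frag = Fragment(chrom=chrom, start=start, end=end, mean_quality=quality)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            _validate_bounds(frag, genome, f"{path}:{lineno}")
            frags.append(frag)
    return frags


def _read_fragments_alignment(path, genome: Genome | None) -> list[Fragment]:
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("BAM/SAM fragment input requires pysam") from exc
    frags: list[Fragment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for i, aln in enumerate(fh):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            qual = None
            if aln.query_qualities is not None and len(aln.query_qualities) > 0:
                qual = float(np.mean(aln.query_qualities))
            try:
                frag = Fragment(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    mean_quality=qual,
                )
            except ValueError as exc:
                raise FormatError(f"{path}: record {i} ({aln.query_name}): {exc}") from exc
            _validate_bounds(frag, genome, f"{path}: record {i}")
            frags.append(frag)
    return frags


def write_fragments(frags: Iterable[Fragment], path, size_class_of=None) -> None:
    """Write fragments as BED6.

    name column = length class (via ``size_class_of(length)`` when given,
    else the length itself), score = mean quality (0 when absent),
    strand = "." (merged fragments are unstranded).
    """
    with open(path, "w") as fh:
        for f in frags:
            name = size_class_of(f.length) if size_class_of else str(f.length)
            score = f.mean_quality if f.mean_quality is not None else 0
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t{score:g}\t.\n")


# ---------------------------------------------------------------------------
# Coverage tracks: bedGraph and wiggle (fixedStep)


def write_track(values: np.ndarray, genome_id: str, path, format: str = "bedGraph") -> None:
    """Write a per-bp track; adjacent equal values are run-length merged
    in bedGraph. Values are written with 6 decimals so a round-trip read
    reproduces them to 1e-6."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("track must be a non-empty 1-D vector")
    fmt = format.lower()
    with open(path, "w") as fh:
        if fmt == "bedgraph":
            fh.write("track type=bedGraph\n")
            # run-length encode
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [values.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{genome_id}\t{s}\t{e}\t{values[s]:.6f}\n")
        elif fmt in {"wiggle", "wig"}:
            fh.write(f"fixedStep chrom={genome_id} start=1 step=1\n")
            for v in values:
                fh.write(f"{v:.6f}\n")
        else:
            raise ValueError(f"unsupported track format: {format}")


def read_track(path, genome_length: int | None = None) -> tuple[str, np.ndarray]:
    """Read a bedGraph or fixedStep wiggle track back into a per-bp vector."""
    intervals: list[tuple[str, int, int, float]] = []
    wig_chrom = None
    wig_values: list[float] = []
    mode = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                mode = "wig"
                fields = dict(kv.split("=") for kv in line.split()[1:])
                wig_chrom = fields["chrom"]
                continue
            if mode == "wig":
                try:
                    wig_values.append(float(line))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad wiggle value") from exc
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                intervals.append((cols[0], int(cols[1]), int(cols[2]), float(cols[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad bedGraph record") from exc
    if mode == "wig":
        return wig_chrom or "", np.asarray(wig_values, dtype=float)
    if not intervals:
        raise FormatError(f"{path}: empty track")
    chrom = intervals[0][0]
    n = genome_length if genome_length is not None else max(e for _, _, e, _ in intervals)
    values = np.zeros(n, dtype=float)
    for c, s, e, v in intervals:
        if c != chrom:
            raise FormatError(f"{path}: multiple chromosomes in single-genome track")
        values[s:e] = v
    return chrom, values


# ---------------------------------------------------------------------------
# Site annotations: BED6 and GFF3


def read_sites(path, format: str = "BED", genome: Genome | None = None,
               feature_types: Sequence[str] = ("gene",)) -> list[SiteAnnotation]:
    """Read stranded landmarks.

    BED6: position = ``start``, strand from column 6 ("." is rejected —
    the downstream site-relative analyses require an orientation).
    GFF3: for the requested feature types, the TSS is the 5' end of the
    feature (``start`` on +, ``end`` on −), converted to 0-based.
    """
    fmt = format.upper()
    sites: list[SiteAnnotation] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            cols = line.split("\t")
            if fmt == "BED":
                if len(cols) < 6:
                    raise FormatError(f"{path}:{lineno}: stranded sites need BED6")
                chrom, start, _end, name, _score, strand = cols[:6]
                if strand not in {"+", "-"}:
                    raise FormatError(
                        f"{path}:{lineno}: strand {strand!r} unusable for "
                        "site-relative analyses"
                    )
                try:
                    pos = int(start)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad coordinate") from exc
                site = SiteAnnotation(chrom=chrom, position=pos, strand=strand,
                                      kind="TSS", gene_id=name)
            elif fmt == "GFF":
                if len(cols) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
                if ftype not in feature_types:
                    continue
                if strand not in {"+", "-"}:
                    raise FormatError(f"{path}:{lineno}: strand {strand!r} unusable")
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
                gene_id = ""
                for kv in attrs.split(";"):
                    kv = kv.strip()
                    if kv.startswith("ID=") or kv.startswith("gene_id="):
                        gene_id = kv.split("=", 1)[1]
                        break
                # 1-based closed -> 0-based; 5' end depends on strand
                pos = start_i - 1 if strand == "+" else end_i - 1
                site = SiteAnnotation(chrom=chrom, position=pos, strand=strand,
                                      kind="TSS", gene_id=gene_id)
            else:
                raise ValueError(f"unsupported site format: {format}")
            if genome is not None and site.position >= len(genome):
                raise FormatError(
                    f"{path}:{lineno}: site at {site.position} outside genome "
                    f"of length {len(genome)}"
                )
            if site.gene_id and site.gene_id in seen_ids:
                warnings.warn(f"duplicate gene_id {site.gene_id!r} at {path}:{lineno}")
            seen_ids.add(site.gene_id)
            sites.append(site)
    return sites


def write_sites(sites: Iterable[SiteAnnotation], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.gene_id or s.kind}"
                f"\t0\t{s.strand}\n"
            )
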