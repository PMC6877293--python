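"""Fragment-size-resolved coverage and its normalizations.

MNase-protected fragments fall into two footprint classes — small
(40–65 bp, minimal binding unit) and large (70–100 bp, extended
footprints) — and coverage is computed per class. Raw coverage is
scaled to 1x genome coverage (RPGC) and corrected for the
origin-to-terminus copy-number gradient of replicating cells by
dividing by a heavily smoothed sonicated-input track (or by a smoothed
copy of the signal itself when no input exists) and standard-scoring
the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, stats

from .seqio import Fragment, Genome, SiteAnnotation

#: Inclusive fragment-length bounds of the two footprint classes.
SIZE_CLASS_BOUNDS: dict[str, tuple[int, int]] = {
    "small": (40, 65),
    "large": (70, 100),
}


@dataclass(frozen=True)
class CoverageTrack:
    """Per-bp coverage aligned to one genome."""

    genome_id: str
    values: np.ndarray
    size_class: str = "all"
    normalization: str = "raw"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("coverage values must be a non-empty 1-D vector")
        if self.normalization in {"raw", "RPGC"} and np.any(values < 0):
            raise ValueError(f"{self.normalization} coverage must be non-negative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, normalization: str | None = None) -> "CoverageTrack":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            normalization=normalization or self.normalization,
        )


def size_class_of(length: int, bounds: dict[str, tuple[int, int]] = SIZE_CLASS_BOUNDS) -> str | None:
    """Footprint class of a fragment length, or None when between classes."""
    for name, (lo, hi) in bounds.items():
        if lo <= length <= hi:
            return name
    return None


def _in_size_class(length: int, size_class: str | tuple[int, int]) -> bool:
    if size_class == "all":
        return True
    if isinstance(size_class, tuple):
        lo, hi = size_class
    else:
        lo, hi = SIZE_CLASS_BOUNDS[size_class]
    return lo <= length <= hi


def compute_coverage(
    fragments: Iterable[Fragment],
    genome: Genome,
    size_class: str | tuple[int, int] = "all",
) -> CoverageTrack:
    """Per-bp fragment pileup for one size class.

    ``values[p]`` counts retained fragments with ``start <= p < end``.
    Origin-spanning fragments of a circular genome (end > length) wrap.
    """
    n = len(genome)
    diff = np.zeros(n + 1, dtype=float)
    for frag in fragments:
        if not _in_size_class(frag.length, size_class):
            continue
        start, end = frag.start, frag.end
        if end <= n:
            diff[start] += 1
            diff[end] -= 1
        else:
            if not genome.circular:
                raise ValueError(
                    f"fragment {frag.start}-{frag.end} beyond linear genome end"
                )
            diff[start] += 1
            diff[n] -= 1
            diff[0] += 1
            diff[end - n] -= 1
    values = np.cumsum(diff[:-1])
    label = size_class if isinstance(size_class, str) else f"custom{size_class}"
    return CoverageTrack(genome_id=genome.id, values=values, size_class=label)


def rpgc_normalize(track: CoverageTrack, effective_genome_size: int) -> CoverageTrack:
    """Scale to 1x coverage: mean coverage over the effective genome size
    becomes 1 (reads-per-genome-coverage normalization)."""
    total = float(track.values.sum())
    if total <= 0:
        raise ValueError("cannot RPGC-normalize an all-zero track")
    scaled = track.values * (effective_genome_size / total)
    return track.with_values(scaled, normalization="RPGC")


def smooth(track: CoverageTrack, window: int) -> CoverageTrack:
    """Circular running mean over an odd window; preserves the track mean."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window > len(track):
        raise ValueError(f"window {window} exceeds genome length {len(track)}")
    smoothed = ndimage.uniform_filter1d(track.values, size=window, mode="wrap")
    return track.with_values(smoothed)


def _smooth_values(values: np.ndarray, window: int) -> np.ndarray:
    if window >= values.size:
        return np.full_like(values, values.mean())
    if window % 2 == 0:
        window += 1
    return ndimage.uniform_filter1d(values, size=window, mode="wrap")


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd < 1e-12:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def normalize_by_input(
    mnase: CoverageTrack,
    input_track: CoverageTrack,
    smooth_window: int = 10_000,
    pseudocount: float = 0.0,
) -> CoverageTrack:
    """Remove replication-associated copy-number bias.

    The sonicated-input coverage is smoothed over ``smooth_window`` (so
    input noise does not propagate), the MNase track is divided by it,
    and the ratio is converted to a Z-score (mean 0, sd 1). Zeros in the
    smoothed input abort unless a pseudocount is configured — silent
    pseudocounts distort ratios.
    """
    if len(mnase) != len(input_track):
        raise ValueError("signal and input tracks must align to the same genome")
    denom = _smooth_values(input_track.values, smooth_window) + pseudocount
    if np.any(denom <= 0):
        raise ValueError(
            "smoothed input contains zeros; configure a pseudocount "
            "(input_pseudocount) to proceed"
        )
    ratio = mnase.values / denom
    return mnase.with_values(_zscore(ratio), normalization="input_normalized_z")


def self_normalize(track: CoverageTrack, smooth_window: int = 250_000) -> CoverageTrack:
    """Input-free bias removal: divide by a long-range smoothed copy of
    the track itself, then Z-score. Used when no sonicated input exists."""
    denom = _smooth_values(track.values, smooth_window)
    if np.any(denom <= 0):
        raise ValueError(
            "self-smoothed track contains zeros; a pseudocount or deeper "
            "coverage is required"
        )
    ratio = track.values / denom
    return track.with_values(_zscore(ratio), normalization="self_normalized")


def cap_percentile(track: CoverageTrack, percentile: float = 99.0) -> CoverageTrack:
    """Threshold per-base values at an upper percentile (duplicate-bias guard)."""
    cap = np.percentile(track.values, percentile)
    return track.with_values(np.minimum(track.values, cap))


def length_correlation_matrix(
    fragments: Sequence[Fragment],
    genome: Genome,
    length_bins: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Genome-wide Spearman correlation of raw coverage between fragment
    length bins (inclusive bounds), at base-pair resolution."""
    if len(length_bins) < 2:
        raise ValueError("need at least two length bins")
    tracks = []
    for lo, hi in length_bins:
        cov = compute_coverage(fragments, genome, size_class=(lo, hi))
        tracks.append(cov.values)
    k = len(tracks)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        mat[i, i] = 1.0
        for j in range(i + 1, k):
            if tracks[i].sum() == 0 or tracks[j].sum() == 0:
                warnings.warn(
                    f"empty coverage in length bin {length_bins[i] if tracks[i].sum() == 0 else length_bins[j]}"
                )
                continue
            rho = stats.spearmanr(tracks[i], tracks[j]).statistic
            mat[i, j] = mat[j, i] = rho
    return mat


def aggregate_around_sites(
    track: CoverageTrack,
    sites: Sequence[SiteAnnotation],
    flank: int,
    statistic: str = "median",
    circular: bool = True,
) -> np.ndarray:
    """Site-relative positional profile over offsets [-flank, +flank].

    Minus-strand site windows are reversed before aggregation so the
    profile is always 5'→3' relative to the site. On a linear genome,
    out-of-bounds positions are excluded per site (NaN-aware statistic).
    """
    if not sites:
        raise ValueError("no usable sites")
    if statistic not in {"median", "mean"}:
        raise ValueError("statistic must be 'median' or 'mean'")
    n = len(track)
    width = 2 * flank + 1
    rows = np.full((len(sites), width), np.nan)
    for i, site in enumerate(sites):
        offs = site.position + np.arange(-flank, flank + 1)
        if circular:
            rows[i] = track.values[offs % n]
        else:
            ok = (offs >= 0) & (offs < n)
            rows[i, ok] = track.values[offs[ok]]
        if site.strand == "-":
            rows[i] = rows[i][::-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        agg = np.nanmedian(rows, axis=0) if statistic == "median" else np.nanmean(rows, axis=0)
    return agg
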