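"""Predicting protein occupancy from sequence with a k-mer LASSO model.

Per-bp features are k-mer frequencies (k = 1..4) within centered
windows of 21 and 51 bp — the short window captures read-internal
composition, the long one the footprint neighbourhood. Features are
pre-selected by absolute Pearson correlation with normalized MNase
coverage over the training region (the first third of the genome, so
held-out evaluation is spatially disjoint), and an L1-penalized linear
model is fitted with 10-fold cross-validation over contiguous genomic
blocks (adjacent base pairs are near-duplicates; random folds would
leak). Genome-wide predictions are evaluated by Spearman correlation
on trained and untrained regions.

Feature vectors are computed lazily, one k-mer at a time: the full
design over all 680 (k-mer, window) pairs is never materialized; only
the selected columns are.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV

from .covtrack import CoverageTrack
from .seqio import Genome

ALPHABET = "ACGT"
DEFAULT_WINDOWS = (21, 51)

_BASE_CODE = {ord(b): i for i, b in enumerate("ACGTN")}


def all_kmers(ks: Sequence[int] = (1, 2, 3, 4)) -> list[str]:
    """All k-mers over {A,C,G,T} for the given k values (340 for k=1..4)."""
    out: list[str] = []
    for k in ks:
        out.extend("".join(t) for t in itertools.product(ALPHABET, repeat=k))
    return out


def _encode(genome: Genome) -> np.ndarray:
    return np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)


def _circular_window_sum(ind: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """sum of ind[(p+lo) .. (p+hi)] (inclusive, circular) for every p."""
    n = ind.size
    width = hi - lo + 1
    ext = np.concatenate([ind, ind[: width + 1]])
    cs = np.concatenate([[0], np.cumsum(ext)])
    start = (np.arange(n) + lo) % n
    return cs[start + width] - cs[start]


class KmerFeatureSet:
    """Lazy per-bp k-mer window-frequency features for one genome.

    feature(p; kmer, w) = (# kmer occurrences fully inside the w-window
    centered at p) / (w − k + 1), wrapping circularly. Windows touching
    an N are NaN and excluded downstream.
    """

    def __init__(self, genome: Genome, kmers: Sequence[str] | None = None,
                 window_sizes: Sequence[int] = DEFAULT_WINDOWS):
        for w in window_sizes:
            if w % 2 == 0 or w < 1:
                raise ValueError("windows must be odd and positive")
        self.genome = genome
        self.kmers = list(kmers) if kmers is not None else all_kmers()
        self.window_sizes = tuple(window_sizes)
        self._arr = _encode(genome)
        self._has_n = "N" in genome.sequence
        self._n_mask_cache: dict[int, np.ndarray] = {}
        self._start_cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return self._arr.size

    @property
    def pairs(self) -> list[tuple[str, int]]:
        return [(kmer, w) for w in self.window_sizes for kmer in self.kmers]

    def _occurrence_indicator(self, kmer: str) -> np.ndarray:
        """ind[q] = 1 iff the k-mer starts at genomic position q (circular)."""
        cached = self._start_cache.get(kmer)
        if cached is not None:
            return cached
        arr = self._arr
        match = arr == ord(kmer[0])
        for i, base in enumerate(kmer[1:], start=1):
            match = match & (np.roll(arr, -i) == ord(base))
        ind = match.astype(np.int64)
        if len(self._start_cache) < 16:
            self._start_cache[kmer] = ind
        return ind

    def _n_window_mask(self, w: int) -> np.ndarray:
        """True where the w-window centered at p contains an N."""
        if w not in self._n_mask_cache:
            is_n = (self._arr == ord("N")).astype(np.int64)
            h = (w - 1) // 2
            self._n_mask_cache[w] = _circular_window_sum(is_n, -h, h) > 0
        return self._n_mask_cache[w]

    def feature(self, kmer: str, window: int) -> np.ndarray:
        k = len(kmer)
        if k > window:
            raise ValueError(f"k-mer {kmer!r} longer than window {window}")
        if window not in self.window_sizes:
            raise ValueError(f"window {window} not in feature set {self.window_sizes}")
        ind = self._occurrence_indicator(kmer)
        h = (window - 1) // 2
        # a start q is inside the window centered at p iff q in [p-h, p+h-k+1]
        counts = _circular_window_sum(ind, -h, h - k + 1)
        values = counts / (window - k + 1)
        if self._has_n:
            values = values.astype(float)
            values[self._n_window_mask(window)] = np.nan
        return values

    def matrix(self, pairs: Sequence[tuple[str, int]]) -> np.ndarray:
        """Materialize selected feature columns as an (n, len(pairs)) array."""
        out = np.empty((len(self), len(pairs)))
        for j, (kmer, w) in enumerate(pairs):
            out[:, j] = self.feature(kmer, w)
        return out


def kmer_features(genome: Genome, kmers: Sequence[str] | None = None,
                  window_sizes: Sequence[int] = DEFAULT_WINDOWS) -> KmerFeatureSet:
    """Build the (lazy) k-mer feature set for a genome."""
    return KmerFeatureSet(genome, kmers=kmers, window_sizes=window_sizes)


def training_slice(n: int, training_region: tuple[int, int] | None = None) -> slice:
    """Default training region: the first third of the genome."""
    if training_region is None:
        return slice(0, n // 3)
    return slice(*training_region)


def select_features(
    features: KmerFeatureSet,
    coverage: CoverageTrack,
    training_region: tuple[int, int] | None = None,
    top_n: int = 80,
) -> list[tuple[str, int, float]]:
    """Rank (k-mer, window) pairs by |Pearson r| with coverage over the
    training region; return the top_n as (kmer, window, r).

    Constant features get r = 0; ties broken by lexicographic k-mer
    then the smaller window.
    """
    sl = training_slice(len(features), training_region)
    y = coverage.values[sl]
    ranked: list[tuple[str, int, float]] = []
    for kmer in features.kmers:
        for w in features.window_sizes:
            x = features.feature(kmer, w)[sl]
            ok = ~np.isnan(x)
            xv, yv = x[ok], y[ok]
            if xv.size < 2 or xv.std() < 1e-15 or yv.std() < 1e-15:
                r = 0.0
            else:
                r = float(np.corrcoef(xv, yv)[0, 1])
            ranked.append((kmer, w, r))
    ranked.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return ranked[:top_n]


@dataclass(frozen=True)
class KmerLassoModel:
    """Fitted sparse linear occupancy model on the original feature scale."""

    features: tuple[tuple[str, int], ...]
    weights: tuple[float, ...]
    intercept: float
    penalty: float
    cv_folds: int
    training_region: tuple[int, int]
    subsample: int = 1

    def __post_init__(self) -> None:
        if len(self.features) != len(self.weights):
            raise ValueError("feature/weight length mismatch")
        if len(self.features) > 80:
            raise ValueError("at most 80 selected features")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")

    def weight_of(self, kmer: str, window: int) -> float:
        for (km, w), wt in zip(self.features, self.weights):
            if km == kmer and w == window:
                return wt
        raise KeyError((kmer, window))

    def to_json(self, path) -> None:
        obj = {
            "features": [[k, w] for k, w in self.features],
            "weights": list(self.weights),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "cv_folds": self.cv_folds,
            "training_region": list(self.training_region),
            "subsample": self.subsample,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "KmerLassoModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            features=tuple((k, int(w)) for k, w in obj["features"]),
            weights=tuple(float(x) for x in obj["weights"]),
            intercept=float(obj["intercept"]),
            penalty=float(obj["penalty"]),
            cv_folds=int(obj["cv_folds"]),
            training_region=tuple(obj["training_region"]),
            subsample=int(obj.get("subsample", 1)),
        )


def _contiguous_folds(n_samples: int, cv_folds: int):
    """(train, test) index pairs for contiguous equal blocks."""
    bounds = np.linspace(0, n_samples, cv_folds + 1).astype(int)
    idx = np.arange(n_samples)
    splits = []
    for i in range(cv_folds):
        test = idx[bounds[i] : bounds[i + 1]]
        train = np.concatenate([idx[: bounds[i]], idx[bounds[i + 1] :]])
        splits.append((train, test))
    return splits


def fit_lasso(
    features: KmerFeatureSet,
    selected: Sequence[tuple[str, int]] | Sequence[tuple[str, int, float]],
    coverage: CoverageTrack,
    training_region: tuple[int, int] | None = None,
    cv_folds: int = 10,
    n_penalties: int = 100,
    subsample: int = 1,
    selection_rule: str = "1se",
    penalty: float | None = None,
) -> KmerLassoModel:
    """Fit the L1-penalized occupancy model.

    Features are standardized for fitting; the penalty is chosen by
    cross-validated squared error on a 100-point log grid spanning
    [1e-4, 1]·lambda_max over contiguous-block folds. The default
    selection rule is the one-standard-error rule (largest penalty
    whose mean CV error is within one SE of the minimum) — the minimum
    rule ("min") systematically admits spurious features on noise.
    Returned weights are on the original feature scale. ``subsample``
    keeps every m-th training position (adjacent positions are nearly
    redundant). ``penalty`` bypasses cross-validation and fits at a
    fixed value (limit studies).
    """
    pairs = [(t[0], t[1]) for t in selected]
    sl = training_slice(len(features), training_region)
    X = features.matrix(pairs)[sl][::subsample]
    y = coverage.values[sl][::subsample]
    ok = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    X, y = X[ok], y[ok]
    if y.size < cv_folds:
        raise ValueError("fewer training positions than CV folds")
    if y.std() < 1e-15:
        raise ValueError("degenerate (zero-variance) response")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd < 1e-15, 1.0, sd)
    Xs = (X - mu) / sd_safe
    yc = y - y.mean()
    if penalty is not None:
        chosen = float(penalty)
        model = Lasso(alpha=max(chosen, 1e-15), fit_intercept=True,
                      max_iter=50_000).fit(Xs, y)
    else:
        lambda_max = np.max(np.abs(Xs.T @ yc)) / y.size
        if lambda_max <= 0:
            lambda_max = 1.0
        alphas = np.geomspace(1e-4 * lambda_max, lambda_max, n_penalties)
        cv_model = LassoCV(
            alphas=alphas,
            cv=_contiguous_folds(y.size, cv_folds),
            fit_intercept=True,
            max_iter=50_000,
        )
        cv_model.fit(Xs, y)
        if selection_rule == "min":
            chosen = float(cv_model.alpha_)
            model = cv_model
        elif selection_rule == "1se":
            mse = cv_model.mse_path_.mean(axis=1)
            se = cv_model.mse_path_.std(axis=1) / np.sqrt(cv_model.mse_path_.shape[1])
            i_min = int(np.argmin(mse))
            within = np.flatnonzero(mse <= mse[i_min] + se[i_min])
            chosen = float(cv_model.alphas_[within[0]])  # alphas_ descending
            model = Lasso(alpha=chosen, fit_intercept=True, max_iter=50_000).fit(Xs, y)
        else:
            raise ValueError("selection_rule must be 'min' or '1se'")
    coef_std = model.coef_
    weights = coef_std / sd_safe
    weights[sd < 1e-15] = 0.0
    intercept = float(model.intercept_ - np.sum(coef_std * mu / sd_safe))
    region = (sl.start, sl.stop)
    return KmerLassoModel(
        features=tuple(pairs),
        weights=tuple(float(w) for w in weights),
        intercept=intercept,
        penalty=chosen,
        cv_folds=cv_folds,
        training_region=region,
        subsample=subsample,
    )


def predict_coverage(model: KmerLassoModel, features: KmerFeatureSet) -> CoverageTrack:
    """Genome-wide linear prediction; NaN where any feature is NaN."""
    X = features.matrix(list(model.features))
    pred = X @ np.asarray(model.weights) + model.intercept
    return CoverageTrack(
        genome_id=features.genome.id,
        values=pred,
        size_class="all",
        normalization="predicted",
    )


def evaluate_prediction(
    predicted: CoverageTrack,
    observed: CoverageTrack,
    region: str = "untrained",
    training_region: tuple[int, int] | None = None,
) -> float:
    """Spearman rho between predicted and observed coverage over the
    trained region, the untrained complement, or the whole genome."""
    if len(predicted) != len(observed):
        raise ValueError("tracks must align to the same genome")
    n = len(predicted)
    sl = training_slice(n, training_region)
    mask = np.zeros(n, dtype=bool)
    mask[sl] = True
    if region == "trained":
        keep = mask
    elif region == "untrained":
        keep = ~mask
    elif region == "all":
        keep = np.ones(n, dtype=bool)
    else:
        raise ValueError("region must be 'trained', 'untrained' or 'all'")
    p, o = predicted.values[keep], observed.values[keep]
    ok = ~np.isnan(p) & ~np.isnan(o)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 usable positions")
    return float(stats.spearmanr(p[ok], o[ok]).statistic)


def display_name(kmer: str, window: int) -> str:
    """Report 'GC' (G followed by C) as 'GpC' etc. in human-facing output."""
    label = "p".join(kmer) if len(kmer) == 2 else kmer
    return f"{label}@{window}"
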