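import numpy as np
import pytest

from htaseq import covtrack, kmerlasso, synthgen
from htaseq.covtrack import CoverageTrack
from htaseq.seqio import Genome


class StubFeatures:
    """Minimal feature-set stand-in allowing direct matrix injection
    (synthetic columns, no genome)."""

    def __init__(self, columns: dict[tuple[str, int], np.ndarray]):
        self.columns = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
        self.n = len(next(iter(self.columns.values())))

    def __len__(self):
        return self.n

    def matrix(self, pairs):
        return np.column_stack([self.columns[tuple(p)] for p in pairs])


class TestKmerFeatures:
    def test_all_a_genome_aa_frequency_one(self):
        g = Genome(id="g", sequence="A" * 200)
        fs = kmerlasso.kmer_features(g, kmers=["AA"], window_sizes=(21,))
        np.testing.assert_allclose(fs.feature("AA", 21), 1.0)

    def test_absent_kmer_zero(self):
        g = Genome(id="g", sequence="A" * 200)
        fs = kmerlasso.kmer_features(g, kmers=["GC"], window_sizes=(21,))
        np.testing.assert_allclose(fs.feature("GC", 21), 0.0)

    def test_matches_naive_sliding_window_recount(self, rng):
        genome = synthgen.generate_genome(synthgen.GenomeSpec(length=2000, seed=17))
        fs = kmerlasso.kmer_features(genome, kmers=["G", "GC", "ATG", "GGCC"],
                                     window_sizes=(21, 51))
        seq3 = genome.sequence * 3
        n = len(genome)
        for kmer in ("G", "GC", "ATG", "GGCC"):
            k = len(kmer)
            for w in (21, 51):
                h = (w - 1) // 2
                got = fs.feature(kmer, w)
                for p in rng.integers(0, n, size=40):
                    window = seq3[p - h + n : p + h + 1 + n]
                    count = sum(1 for i in range(w - k + 1)
                                if window[i : i + k] == kmer)
                    assert got[p] == pytest.approx(count / (w - k + 1))

    def test_n_windows_are_nan(self):
        g = Genome(id="g", sequence="A" * 100 + "N" + "A" * 99)
        fs = kmerlasso.kmer_features(g, kmers=["AA"], window_sizes=(21,))
        vals = fs.feature("AA", 21)
        assert np.isnan(vals[100])
        assert np.isnan(vals[92]) and np.isnan(vals[108])
        assert not np.isnan(vals[50])

    def test_kmer_longer_than_window_rejected(self):
        g = Genome(id="g", sequence="A" * 100)
        fs = kmerlasso.KmerFeatureSet(g, kmers=["AAA"], window_sizes=(1,))
        with pytest.raises(ValueError, match="longer than window"):
            fs.feature("AAA", 1)

    def test_even_window_rejected(self):
        g = Genome(id="g", sequence="A" * 100)
        with pytest.raises(ValueError, match="odd"):
            kmerlasso.KmerFeatureSet(g, window_sizes=(20,))


class TestSelectFeatures:
    def test_coverage_equal_to_feature_ranked_first(self):
        genome = synthgen.generate_genome(synthgen.GenomeSpec(length=6000, seed=19))
        fs = kmerlasso.kmer_features(genome, kmers=["GC", "AA", "TA"],
                                     window_sizes=(21, 51))
        cov = CoverageTrack("synth", fs.feature("GC", 51),
                            normalization="input_normalized_z")
        ranked = kmerlasso.select_features(fs, cov, top_n=6)
        assert ranked[0][:2] == ("GC", 51)
        assert ranked[0][2] == pytest.approx(1.0)

    def test_top_n_exceeding_feature_count_returns_all(self):
        genome = synthgen.generate_genome(synthgen.GenomeSpec(length=2000, seed=19))
        fs = kmerlasso.kmer_features(genome, kmers=["GC"], window_sizes=(21, 51))
        cov = CoverageTrack("synth", np.random.default_rng(0).random(2000),
                            normalization="input_normalized_z")
        assert len(kmerlasso.select_features(fs, cov, top_n=80)) == 2

    def test_ranking_by_absolute_correlation(self):
        n = 3000
        rng = np.random.default_rng(2)
        y = rng.normal(size=n)
        cols = {
            ("A", 21): y + rng.normal(0, 0.5, n),      # r ~ +0.9
            ("C", 21): -y + rng.normal(0, 0.5, n),     # r ~ -0.9
            ("G", 21): y + rng.normal(0, 2.0, n),      # r ~ +0.45
        }
        stub = StubFeatures(cols)
        stub.kmers = ["A", "C", "G"]
        stub.window_sizes = (21,)
        stub.feature = lambda k, w: cols[(k, w)]
        cov = CoverageTrack("s", y, normalization="input_normalized_z")
        ranked = kmerlasso.select_features(stub, cov, training_region=(0, n), top_n=3)
        assert {ranked[0][0], ranked[1][0]} == {"A", "C"}
        assert ranked[2][0] == "G"


class TestFitLasso:
    def test_vanishing_penalty_recovers_slope(self):
        n = 2000
        rng = np.random.default_rng(3)
        x = rng.random(n)
        y = 2.5 * x + 1.0
        stub = StubFeatures({("GC", 51): x})
        cov = CoverageTrack("s", y, normalization="input_normalized_z")
        model = kmerlasso.fit_lasso(stub, [("GC", 51)], cov, training_region=(0, n),
                                    penalty=0.0)
        assert model.weight_of("GC", 51) == pytest.approx(2.5, abs=1e-6)
        assert model.intercept == pytest.approx(1.0, abs=1e-6)

    def test_infinite_penalty_zero_weights_mean_intercept(self):
        n = 1000
        rng = np.random.default_rng(30)
        x = rng.random(n)
        y = 2.0 * x + rng.normal(0, 0.1, n)
        stub = StubFeatures({("GC", 51): x})
        cov = CoverageTrack("s", y, normalization="input_normalized_z")
        model = kmerlasso.fit_lasso(stub, [("GC", 51)], cov, training_region=(0, n),
                                    penalty=1e9)
        assert model.weight_of("GC", 51) == 0.0
        assert model.intercept == pytest.approx(y.mean(), abs=1e-9)

    def test_noise_response_shrinks_to_sparse_model(self):
        """Fitting pure noise selects (almost) no features at the
        CV-chosen penalty."""
        n, m = 3000, 40
        rng = np.random.default_rng(4)
        cols = {("K%02d" % j, 21): rng.random(n) for j in range(m)}
        stub = StubFeatures(cols)
        y = rng.normal(size=n)
        cov = CoverageTrack("s", y, normalization="input_normalized_z")
        model = kmerlasso.fit_lasso(stub, list(cols), cov, training_region=(0, n))
        nonzero = sum(1 for w in model.weights if w != 0)
        assert nonzero <= 0.05 * m + 1

    def test_degenerate_response_rejected(self):
        stub = StubFeatures({("A", 21): np.random.default_rng(0).random(100)})
        cov = CoverageTrack("s", np.ones(100), normalization="input_normalized_z")
        with pytest.raises(ValueError, match="zero-variance"):
            kmerlasso.fit_lasso(stub, [("A", 21)], cov, training_region=(0, 100))

    def test_feature_scaling_invariance_of_predictions(self):
        """Standardize-then-invert: scaling a feature column leaves the
        fitted predictions unchanged."""
        n = 2000
        rng = np.random.default_rng(5)
        x = rng.random(n)
        y = 3.0 * x + rng.normal(0, 0.1, n)
        cov = CoverageTrack("s", y, normalization="input_normalized_z")
        base = kmerlasso.fit_lasso(StubFeatures({("A", 21): x}), [("A", 21)],
                                   cov, training_region=(0, n))
        scaled = kmerlasso.fit_lasso(StubFeatures({("A", 21): 1000 * x}), [("A", 21)],
                                     cov, training_region=(0, n))
        pred_base = base.weight_of("A", 21) * x + base.intercept
        pred_scaled = scaled.weight_of("A", 21) * 1000 * x + scaled.intercept
        np.testing.assert_allclose(pred_base, pred_scaled, atol=1e-6)


class TestPredictAndEvaluate:
    def test_zero_weight_model_constant_intercept(self):
        genome = synthgen.generate_genome(synthgen.GenomeSpec(length=1000, seed=23))
        fs = kmerlasso.kmer_features(genome, kmers=["GC"], window_sizes=(21, 51))
        model = kmerlasso.KmerLassoModel(
            features=(("GC", 21),), weights=(0.0,), intercept=2.0, penalty=1.0,
            cv_folds=10, training_region=(0, 333))
        pred = kmerlasso.predict_coverage(model, fs)
        np.testing.assert_allclose(pred.values, 2.0)

    def test_model_json_round_trip_identical_predictions(self, tmp_path):
        genome = synthgen.generate_genome(synthgen.GenomeSpec(length=1000, seed=23))
        fs = kmerlasso.kmer_features(genome, kmers=["GC", "AA"], window_sizes=(21, 51))
        model = kmerlasso.KmerLassoModel(
            features=(("GC", 51), ("AA", 21)), weights=(1.5, -0.5), intercept=0.3,
            penalty=0.01, cv_folds=10, training_region=(0, 333))
        p = tmp_path / "model.json"
        model.to_json(p)
        back = kmerlasso.KmerLassoModel.from_json(p)
        np.testing.assert_array_equal(
            kmerlasso.predict_coverage(model, fs).values,
            kmerlasso.predict_coverage(back, fs).values)

    def test_perfect_and_inverted_predictions(self, rng):
        y = rng.random(1000)
        obs = CoverageTrack("g", y, normalization="input_normalized_z")
        same = CoverageTrack("g", y.copy(), normalization="predicted")
        neg = CoverageTrack("g", -y, normalization="predicted")
        assert kmerlasso.evaluate_prediction(same, obs, "all") == pytest.approx(1.0)
        assert kmerlasso.evaluate_prediction(neg, obs, "all") == pytest.approx(-1.0)

    def test_permuted_prediction_uncorrelated(self):
        rng = np.random.default_rng(6)
        y = rng.random(100_000)
        perm = rng.permutation(y)
        obs = CoverageTrack("g", y, normalization="input_normalized_z")
        pred = CoverageTrack("g", perm, normalization="predicted")
        assert abs(kmerlasso.evaluate_prediction(pred, obs, "all")) < 0.05

    def test_untrained_is_complement_of_training_third(self, rng):
        n = 900
        y = rng.random(n)
        obs = CoverageTrack("g", y, normalization="input_normalized_z")
        pred_vals = y.copy()
        pred_vals[: n // 3] = rng.random(n // 3)  # scramble trained third only
        pred = CoverageTrack("g", pred_vals, normalization="predicted")
        assert kmerlasso.evaluate_prediction(pred, obs, "untrained") == pytest.approx(1.0)

    def test_display_name_gpc(self):
        assert kmerlasso.display_name("GC", 51) == "GpC@51"
        assert kmerlasso.display_name("GGC", 21) == "GGC@21"
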