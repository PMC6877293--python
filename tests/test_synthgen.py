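import numpy as np
import pytest
from scipy import stats

from htaseq import covtrack, synthgen
from htaseq.covtrack import CoverageTrack
from htaseq.synthgen import (
    EmsaDesign,
    FragmentMixtureSpec,
    GenomeSpec,
    PlantedOccupancyModel,
    ReplicationGradientSpec,
)


class TestGenerateGenome:
    def test_forced_gc_composition(self):
        g = synthgen.generate_genome(GenomeSpec(length=1000, gc_profile=((0, 1000, 1.0),)))
        assert set(g.sequence) <= {"G", "C"}

    def test_same_seed_identical(self):
        spec = GenomeSpec(length=10_000, seed=7)
        assert synthgen.generate_genome(spec).sequence == synthgen.generate_genome(spec).sequence

    def test_two_segment_gc_within_2pct(self):
        spec = GenomeSpec(length=20_000,
                          gc_profile=((0, 10_000, 0.3), (10_000, 20_000, 0.7)), seed=3)
        g = synthgen.generate_genome(spec)

        def gc(seq):
            return (seq.count("G") + seq.count("C")) / len(seq)

        assert 0.28 <= gc(g.sequence[:10_000]) <= 0.32
        assert 0.68 <= gc(g.sequence[10_000:]) <= 0.72

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            GenomeSpec(length=100, gc_profile=((0, 50, 0.5), (60, 100, 0.5)))
        with pytest.raises(ValueError, match="cover"):
            GenomeSpec(length=100, gc_profile=((0, 50, 0.5),))


class TestPlantOccupancy:
    def test_all_g_genome_single_base_weight(self):
        from htaseq.seqio import Genome
        g = Genome(id="g", sequence="G" * 200)
        model = PlantedOccupancyModel(kmer_weights={"G": 1.0}, window=21, intercept=0.0)
        track = synthgen.plant_occupancy(g, model)
        np.testing.assert_allclose(track.values, 1.0)

    def test_zero_weights_constant_intercept(self, random_genome):
        model = PlantedOccupancyModel(kmer_weights={"GC": 0.0}, window=21, intercept=5.0)
        track = synthgen.plant_occupancy(random_genome, model)
        np.testing.assert_allclose(track.values, 5.0)

    def test_matches_sliding_window_count_oracle(self):
        from htaseq.seqio import Genome
        g = Genome(id="g", sequence="ATGC" * 50)  # 200 bp
        w, kmer, weight = 21, "GC", 2.0
        model = PlantedOccupancyModel(kmer_weights={kmer: weight}, window=w, intercept=0.0)
        track = synthgen.plant_occupancy(g, model)
        n, h = len(g), (w - 1) // 2
        seq2 = g.sequence * 3  # circular context
        expected = np.empty(n)
        for p in range(n):
            window = seq2[p - h + n : p + h + 1 + n]
            count = sum(1 for i in range(len(window) - 1) if window[i : i + 2] == kmer)
            expected[p] = weight * count / (w - 1)
        expected -= expected.min() if expected.min() < 0 else 0
        np.testing.assert_allclose(track.values, expected, atol=1e-12)

    def test_negative_values_shifted_nonnegative(self, random_genome):
        model = PlantedOccupancyModel(kmer_weights={"AT": -5.0}, window=21)
        track = synthgen.plant_occupancy(random_genome, model)
        assert track.values.min() >= 0


class TestSampleFragments:
    def test_exact_fragment_count_with_duplicates(self, random_genome):
        occ = CoverageTrack("synth", np.ones(len(random_genome)))
        mix = FragmentMixtureSpec(n_fragments=5000, duplicate_rate=0.2, seed=1)
        frags = synthgen.sample_fragments(occ, mix)
        assert len(frags) == 5000
        coords = [(f.start, f.end) for f in frags]
        assert len(set(coords)) < 5000  # duplicates present

    def test_uniform_occupancy_uniform_centers(self):
        occ = CoverageTrack("synth", np.ones(10_000))
        mix = FragmentMixtureSpec(n_fragments=100_000, duplicate_rate=0.0, seed=2)
        frags = synthgen.sample_fragments(occ, mix)
        centers = np.array([f.dyad % 10_000 for f in frags])
        counts, _ = np.histogram(centers, bins=100, range=(0, 10_000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_p_small_one_all_lengths_in_small_support(self):
        occ = CoverageTrack("synth", np.ones(5000))
        mix = FragmentMixtureSpec(p_small=1.0, n_fragments=2000, seed=3,
                                  small_mode=50, small_sd=5.0)
        frags = synthgen.sample_fragments(occ, mix)
        lengths = np.array([f.length for f in frags])
        assert lengths.min() >= 20 and lengths.max() <= 200
        assert abs(lengths.mean() - 50) < 1.0

    def test_zero_occupancy_outside_region_confines_centers(self):
        vals = np.zeros(5000)
        vals[100:200] = 1.0
        occ = CoverageTrack("synth", vals)
        mix = FragmentMixtureSpec(n_fragments=1000, duplicate_rate=0.0, seed=4)
        frags = synthgen.sample_fragments(occ, mix)
        centers = np.array([(f.start + f.end) // 2 % 5000 for f in frags])
        assert ((centers >= 100) & (centers < 200)).all()

    def test_all_zero_occupancy_errors(self):
        occ = CoverageTrack("synth", np.zeros(100))
        with pytest.raises(ValueError, match="all zero"):
            synthgen.sample_fragments(occ, FragmentMixtureSpec(n_fragments=10))

    def test_same_seed_identical(self):
        occ = CoverageTrack("synth", np.ones(2000))
        mix = FragmentMixtureSpec(n_fragments=500, seed=5)
        a = synthgen.sample_fragments(occ, mix)
        b = synthgen.sample_fragments(occ, mix)
        assert [(f.start, f.end) for f in a] == [(f.start, f.end) for f in b]

    def test_center_density_tracks_planted_occupancy(self, random_genome):
        """Planted-model recoverability: empirical center density
        correlates with the landscape (Spearman, windowed)."""
        model = PlantedOccupancyModel(kmer_weights={"GC": 4.0}, window=51, intercept=0.5)
        occ = synthgen.plant_occupancy(random_genome, model)
        mix = FragmentMixtureSpec(n_fragments=100_000, duplicate_rate=0.0, seed=6)
        frags = synthgen.sample_fragments(occ, mix)
        n = len(random_genome)
        density = np.bincount([f.dyad % n for f in frags], minlength=n).astype(float)
        # smooth the empirical density at the occupancy window scale
        from scipy.ndimage import uniform_filter1d
        density = uniform_filter1d(density, size=51, mode="wrap")
        rho = stats.spearmanr(density, occ.values).statistic
        assert rho >= 0.8


class TestReplicationGradient:
    def test_multiplier_monotone_in_circular_distance(self):
        grad = ReplicationGradientSpec(origin=0, max_ratio=2.0)
        m = grad.multiplier(1000)
        assert m[0] == pytest.approx(2.0)
        assert m[500] == pytest.approx(1.0)
        d = np.minimum(np.arange(1000), 1000 - np.arange(1000))
        assert (np.diff(m[np.argsort(d, kind="stable")]) <= 1e-12).all()

    def test_max_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            ReplicationGradientSpec(origin=0, max_ratio=0.5)


class TestBroadFootprints:
    def test_edge_bias_one_single_sign_offset(self):
        frags, truth = synthgen.sample_broad_footprints(
            [1000], 50, small_len=50, large_len=84, edge_bias=1.0, seed=1)
        offset = (84 - 50) // 2
        small_centers = {f.dyad for f in frags if f.length == 50}
        sign = -1 if truth[0].preferred_edge == "left" else 1
        assert small_centers == {1000 + sign * offset}

    def test_edge_bias_half_splits_evenly(self):
        frags, truth = synthgen.sample_broad_footprints(
            [5000], 10_000, small_len=50, large_len=84, edge_bias=0.5, seed=2)
        offset = (84 - 50) // 2
        left = sum(1 for f in frags if f.length == 50 and f.dyad == 5000 - offset)
        right = sum(1 for f in frags if f.length == 50 and f.dyad == 5000 + offset)
        assert left + right == 10_000
        assert stats.binomtest(left, left + right, 0.5).pvalue > 0.01

    def test_zero_per_site_empty(self):
        frags, _ = synthgen.sample_broad_footprints([100], 0)
        assert frags == []

    def test_invalid_edge_bias_rejected(self):
        with pytest.raises(ValueError):
            synthgen.sample_broad_footprints([100], 1, edge_bias=0.3)


class TestEmsaPool:
    def test_null_affinity_slow_fraction_half(self):
        design = synthgen.make_emsa_design(planted_affinity={}, seed=1)
        pool = synthgen.generate_emsa_pool(design, 100_000, seed=2)
        frac = np.mean([b == "slow" for b in pool.bands])
        assert abs(frac - 0.5) <= 0.02

    def test_saturating_gpc_affinity_max_gpc_all_slow(self):
        design = synthgen.make_emsa_design(
            planted_affinity={"GpC_count": 100.0}, seed=1)
        pool = synthgen.generate_emsa_pool(design, 5000, seed=3)
        gpc = np.array([synthgen.count_gpc(s) for s in pool.sequences])
        slow = np.array([b == "slow" for b in pool.bands])
        assert slow[gpc >= 1].all()

    def test_same_seed_identical_pool(self):
        design = synthgen.make_emsa_design(seed=4)
        a = synthgen.generate_emsa_pool(design, 1000, seed=5)
        b = synthgen.generate_emsa_pool(design, 1000, seed=5)
        assert a.sequences == b.sequences and a.bands == b.bands

    def test_read_count_conservation(self):
        design = synthgen.make_emsa_design(seed=4)
        pool = synthgen.generate_emsa_pool(design, 777, seed=6)
        assert len(pool) == 777

    def test_design_slot_validation(self):
        with pytest.raises(ValueError, match="overlapping"):
            EmsaDesign(backbones=(("b1", "A" * 100),),
                       randomized_positions={"b1": (0, 1, 10, 20, 30, 40, 50, 60)})
        with pytest.raises(ValueError, match="exactly 8"):
            EmsaDesign(backbones=(("b1", "A" * 100),),
                       randomized_positions={"b1": (0, 10, 20)})

    def test_design_tsv_round_trip(self, tmp_path):
        design = synthgen.make_emsa_design(seed=7)
        p = tmp_path / "design.tsv"
        design.to_tsv(p)
        back = EmsaDesign.from_tsv(p)
        assert back.backbones == design.backbones
        assert back.randomized_positions == design.randomized_positions
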