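"""Composite LD, decay curves and Sved Ne estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popgenkit import (
    LdConfig,
    WrightFisherConfig,
    adjacent_r2,
    composite_d,
    ld_decay,
    marker_density,
    ne_from_bin,
    ne_trajectory,
    pair_r2,
    simulate_wright_fisher,
    sved_expected_r2,
)
from popgenkit.genotypes import SampleMetadata
from popgenkit.ld import LDBin, correct_r2, decay_distance

from conftest import make_matrix


def burrows_direct(table):
    """Independent class-count evaluation of the Burrows composite estimator."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    # joint genotype classes by alt-allele dosage (2,2)=AABB etc.
    x = 2 * t[2, 2] + t[2, 1] + t[1, 2] + t[1, 1] / 2.0
    pa = (2 * t[2, :].sum() + t[1, :].sum()) / (2 * n)
    pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    return n / (n - 1.0) * (x / n - 2.0 * pa * pb)


class TestCompositeD:
    def test_hand_traced_four_sample_table(self):
        # two AABB and two aabb: x = sum(XY)/2 = 4, inner = 1 - 0.5
        table = np.zeros((3, 3))
        table[2, 2] = 2
        table[0, 0] = 2
        assert composite_d(table) == pytest.approx((4 / 3) * 0.5)

    def test_positive_association_by_construction(self):
        table = np.diag([3.0, 2.0, 3.0])  # identical dosages at both loci
        assert composite_d(table) > 0

    def test_monomorphic_rejected(self):
        table = np.zeros((3, 3))
        table[0, 0] = 4
        table[0, 2] = 3
        with pytest.raises(ValueError, match="monomorphic"):
            composite_d(table)

    def test_linkage_equilibrium_mean_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(1000):
            x = rng.binomial(2, 0.4, 40)
            y = rng.binomial(2, 0.6, 40)
            t = np.zeros((3, 3))
            np.add.at(t, (x, y), 1)
            try:
                vals.append(composite_d(t))
            except ValueError:
                continue
        assert np.mean(vals) == pytest.approx(0.0, abs=0.01)

    @given(st.lists(st.integers(0, 2), min_size=4, max_size=30),
           st.lists(st.integers(0, 2), min_size=4, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_evaluation(self, xs, ys):
        m = min(len(xs), len(ys))
        x, y = np.array(xs[:m]), np.array(ys[:m])
        t = np.zeros((3, 3))
        np.add.at(t, (x, y), 1)
        if x.sum() in (0, 2 * m) or y.sum() in (0, 2 * m):
            return
        assert composite_d(t) == pytest.approx(burrows_direct(t), abs=1e-12)


class TestPairR2:
    def test_correction_fixed_points(self):
        assert correct_r2(1.0, 50) == 1.0
        assert correct_r2(1 / 50, 50) == pytest.approx(0.0, abs=1e-15)
        assert correct_r2(0.5, 50) == pytest.approx((0.5 - 0.02) / 0.98)

    def test_perfect_ld_duplicated_column(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=30)
        gm = make_matrix(np.column_stack([col, col]).astype(np.int8))
        assert pair_r2(gm, 0, 1) == pytest.approx(1.0)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, size=40)
        y = rng.integers(0, 3, size=40)
        gm = make_matrix(np.column_stack([x, y]).astype(np.int8))
        flipped = make_matrix(np.column_stack([2 - x, y]).astype(np.int8))
        assert pair_r2(gm, 0, 1) == pytest.approx(pair_r2(gm, 1, 0))
        assert pair_r2(gm, 0, 1) == pytest.approx(pair_r2(flipped, 0, 1))

    def test_cross_scaffold_pairs_rejected(self):
        gm = make_matrix([[0, 1], [1, 2], [2, 0]], scaffolds=["c1", "c2"],
                         positions=[100, 100])
        with pytest.raises(ValueError, match="scaffold"):
            pair_r2(gm, 0, 1)

    def test_too_few_shared_samples(self):
        from popgenkit.genotypes import MISSING
        gm = make_matrix([[0, MISSING], [MISSING, 1], [1, MISSING]])
        with pytest.raises(ValueError, match="shared"):
            pair_r2(gm, 0, 1)

    def test_phase_unambiguous_composite_equals_scaled_haplotype_d(self):
        # without double heterozygotes the composite estimator equals
        # 2N/(N-1) times the haplotype-count D, exactly
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = 20
            h1 = rng.integers(0, 2, size=(n, 2))
            h2 = rng.integers(0, 2, size=(n, 2))
            x, y = h1.sum(axis=1), h2.sum(axis=1)
            keep = ~((x == 1) & (y == 1))
            x, y = x[keep], y[keep]
            m = len(x)
            if m < 3 or x.sum() in (0, 2 * m) or y.sum() in (0, 2 * m):
                continue
            t = np.zeros((3, 3))
            np.add.at(t, (x, y), 1)
            # enumerate haplotypes (phase is unambiguous)
            hapA, hapB = [], []
            for xi, yi in zip(x, y):
                a = [1] * xi + [0] * (2 - xi)
                b = [1] * yi + [0] * (2 - yi)
                hapA += a
                hapB += b
            hapA, hapB = np.array(hapA), np.array(hapB)
            d_hap = (hapA & hapB).mean() - hapA.mean() * hapB.mean()
            assert composite_d(t) == pytest.approx(2 * m / (m - 1) * d_hap, abs=1e-12)


class TestAdjacent:
    def test_identical_adjacent_columns_contribute_one(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, 30)
        other = rng.integers(0, 3, 30)
        gm = make_matrix(np.column_stack([col, col, other]).astype(np.int8))
        mean, sd, dist = adjacent_r2(gm)
        assert mean >= 0.5  # first pair is exactly 1
        gm2 = make_matrix(np.column_stack([col, col]).astype(np.int8))
        with pytest.raises(ValueError):
            adjacent_r2(gm2)  # a single usable pair is not enough

    def test_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(25, 40)).astype(np.int8)
        gm = make_matrix(d)
        perm = rng.permutation(25)
        gm2 = gm.take_samples(perm)
        assert adjacent_r2(gm) == pytest.approx(adjacent_r2(gm2))

    def test_adjacent_exceeds_distant_in_wf_simulation(self):
        near, far = [], []
        for seed in range(3):
            cfg = WrightFisherConfig(ne=50, n_generations=100, n_start_loci=800,
                                     sample_size=40, seed=seed)
            gm, _ = simulate_wright_fisher(cfg)
            mean, _, _ = adjacent_r2(gm)
            cfgld = LdConfig(n_snps=10**6, min_scaffold_length=0, seed=seed)
            bins = ld_decay(gm, None, None, 2_000_000, 1_000_000, cfgld)
            near.append(mean)
            far.append(bins[1].mean_r2)
        assert np.mean(near) > np.mean(far)


class TestDecay:
    def test_bin_count_arithmetic(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        gm = make_matrix(d, positions=(np.arange(50) + 1) * 2_000)
        bins = ld_decay(gm, None, None, 100_000, 10_000, LdConfig(min_scaffold_length=0))
        assert len(bins) == 10
        assert bins[0].low == 0 and bins[-1].high == 100_000

    def test_bin_size_must_divide_range(self):
        gm = make_matrix([[0, 1, 2]])
        with pytest.raises(ValueError, match="divide"):
            ld_decay(gm, None, None, 100_000, 30_000, LdConfig(min_scaffold_length=0))

    def test_unlinked_loci_show_no_trend(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 300), size=(50, 300)).astype(np.int8)
        gm = make_matrix(d, positions=(np.arange(300) + 1) * 10_000)
        bins = ld_decay(gm, None, None, 1_000_000, 100_000, LdConfig(min_scaffold_length=0))
        means = [b.mean_r2 for b in bins if b.n_pairs > 10]
        rho = stats.spearmanr(np.arange(len(means)), means).statistic
        assert abs(rho) < 0.75  # no systematic decay for independent loci

    def test_wf_decay_is_monotone_decreasing(self):
        from scipy import stats
        rhos = []
        for seed in range(3):
            cfg = WrightFisherConfig(ne=100, n_generations=100, n_start_loci=1_000,
                                     sample_size=50, seed=seed + 50)
            gm, _ = simulate_wright_fisher(cfg)
            bins = ld_decay(gm, None, None, 10_000_000, 1_000_000,
                            LdConfig(min_scaffold_length=0, seed=seed))
            means = [b.mean_r2 for b in bins if b.n_pairs > 0]
            rhos.append(stats.spearmanr(np.arange(len(means)), means).statistic)
        assert np.mean(rhos) < 0

    def test_subsampling_is_seeded_and_restricted(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
        scafs = ["long"] * 100 + ["short"] * 100
        pos = list((np.arange(100) + 1) * 200_000) + list((np.arange(100) + 1) * 1_000)
        gm = make_matrix(d, positions=pos, scaffolds=scafs)
        cfg = LdConfig(n_snps=50, min_scaffold_length=10_000_000, seed=3)
        from popgenkit.ld import _subsample_columns
        cols = _subsample_columns(gm, cfg)
        assert len(cols) == 50
        assert set(gm.scaffolds[cols]) == {"long"}
        np.testing.assert_array_equal(cols, _subsample_columns(gm, cfg))


class TestNe:
    def test_closed_form_arithmetic(self):
        assert ne_from_bin(0.2, 0.01) == pytest.approx(100.0)
        assert ne_from_bin(0.25, 0.05) == pytest.approx(15.0)

    def test_r2_near_one_gives_tiny_ne(self):
        assert ne_from_bin(0.999999, 0.01) < 1e-4

    def test_round_trip_identity(self):
        for ne in (50, 100, 500, 1000):
            for c in (0.001, 0.01, 0.1):
                assert ne_from_bin(sved_expected_r2(ne, c), c) == pytest.approx(ne)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ne_from_bin(0.0, 0.01)
        with pytest.raises(ValueError):
            ne_from_bin(1.2, 0.01)
        with pytest.raises(ValueError):
            ne_from_bin(0.2, 0.0)

    def test_trajectory_targets_correct_distances(self):
        # build synthetic bins with exact Sved means for Ne=200 at 1 cM/Mb
        cfg = LdConfig(cm_per_mb=1.0, generations=(200, 5))
        bins = []
        for k in range(100):
            mid = (k + 0.5) * 100_000
            bins.append(LDBin(k * 100_000, (k + 1) * 100_000, 100,
                              sved_expected_r2(200, mid * 1e-8), 0.0, mid))
        pts = ne_trajectory(bins, cfg)
        by_t = {p.generations_ago: p for p in pts}
        # t=200 -> 250 kb target, t=5 -> 10 Mb target
        assert by_t[200.0].c_morgans == pytest.approx(250_000 * 1e-8, rel=0.25)
        assert by_t[5.0].c_morgans == pytest.approx(10_000_000 * 1e-8, rel=0.25)
        for p in pts:
            assert p.ne == pytest.approx(200.0, rel=1e-6)

    def test_trajectory_omits_unreachable_targets(self):
        bins = [LDBin(0, 100_000, 50, 0.4, 0.1, 50_000.0)]
        cfg = LdConfig(generations=(5,))  # target 10 Mb; only a 50 kb bin exists
        assert ne_trajectory(bins, cfg) == []


class TestMarkerDensity:
    @pytest.mark.parametrize(
        "genome,decay,expected",
        [(2.4e9, 20_000, 120_000), (2.4e9, 100_000, 24_000), (2.4e9, 10_000, 240_000)],
    )
    def test_genome_over_decay_distance(self, genome, decay, expected):
        assert marker_density(genome, decay) == expected

    def test_decay_distance_crossing(self):
        bins = [
            LDBin(0, 10_000, 10, 0.5, 0.1, 5_000),
            LDBin(10_000, 20_000, 10, 0.25, 0.1, 15_000),
            LDBin(20_000, 30_000, 10, 0.15, 0.1, 25_000),
        ]
        assert decay_distance(bins, 0.2) == 20_000
        assert decay_distance(bins, 0.6) is None
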