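"""Ground-truth generators: structure, drift/LD, planted ROH, pedigrees."""

import numpy as np
import pytest

from popgenkit import (
    RohTract,
    StructureSimConfig,
    WrightFisherConfig,
    gene_drop,
    nei_distance,
    plant_roh,
    simulate_pedigree,
    simulate_structured,
    simulate_wright_fisher,
    wc_fst,
)
from popgenkit.genotypes import MISSING


class TestStructured:
    def test_reproducible(self):
        cfg = StructureSimConfig(k=2, fst=[0.1, 0.1], n_loci=200, seed=42)
        a = simulate_structured(cfg, {"A": 5, "B": 5})[0]
        b = simulate_structured(cfg, {"A": 5, "B": 5})[0]
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_no_structure_limit_is_binomial_sampling(self):
        # K=1, Fst -> 0: across-replicate variance of the realized sample
        # frequency matches binomial sampling around the drawn frequency
        cfg = StructureSimConfig(k=1, fst=[0.0], maf_range=(0.3, 0.3), n_loci=4000, seed=3)
        gm, _, truth = simulate_structured(cfg, {"A": 25})
        realized = gm.alt_freq()
        expected_var = 0.3 * 0.7 / (2 * 25)
        assert np.var(realized - truth["ancestral_freq"]) == pytest.approx(
            expected_var, rel=0.15
        )

    def test_fst_parameter_recovery(self):
        thetas = []
        for seed in range(3):
            cfg = StructureSimConfig(k=2, fst=[0.1, 0.1], n_loci=20_000, seed=seed)
            gm, meta, _ = simulate_structured(cfg, {"A": 50, "B": 50})
            thetas.append(wc_fst(gm, meta, ("A", "B")))
        assert np.mean(thetas) == pytest.approx(0.10, abs=0.02)

    def test_admixed_group_sits_between_parents(self):
        cfg = StructureSimConfig(k=2, fst=[0.15, 0.15], n_loci=5_000, seed=11)
        gm, meta, _ = simulate_structured(
            cfg,
            {"A": 20, "B": 20, "AB": 20},
            group_admixture={
                "A": np.array([1.0, 0.0]),
                "B": np.array([0.0, 1.0]),
                "AB": np.array([0.5, 0.5]),
            },
        )
        d_ab = nei_distance(gm, meta, "A", "B")
        assert nei_distance(gm, meta, "AB", "A") < d_ab
        assert nei_distance(gm, meta, "AB", "B") < d_ab

    def test_degenerate_sampler_errors(self):
        cfg = StructureSimConfig(k=1, fst=[0.0], maf_range=(0.0, 0.0), n_loci=10, seed=0)
        with pytest.raises(RuntimeError, match="fixed in every population"):
            simulate_structured(cfg, {"A": 4})


class TestWrightFisher:
    def test_reproducible(self):
        cfg = WrightFisherConfig(ne=20, n_generations=5, n_start_loci=100,
                                 sample_size=10, seed=9)
        a = simulate_wright_fisher(cfg)[0]
        b = simulate_wright_fisher(cfg)[0]
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_no_recombination_gives_distance_free_ld(self):
        # with zero recombination r2 should be high everywhere, near and far
        from popgenkit.ld import _cross_stats, _prepare

        cfg = WrightFisherConfig(ne=30, n_generations=60, recomb_rate=0.0,
                                 n_start_loci=300, sample_size=30, seed=4)
        gm, _ = simulate_wright_fisher(cfg)
        maf = gm.maf()
        keep = np.flatnonzero(maf > 0.1)
        z, w = _prepare(gm.dosages[:, keep])
        r2 = _cross_stats(z, w, z, w)
        pos = gm.positions[keep]
        iu = np.triu_indices(keep.size, k=1)
        dist = (pos[None, :] - pos[:, None])[iu]
        vals = r2[iu]
        near = np.nanmean(vals[dist < 1_000_000])
        far = np.nanmean(vals[dist > 5_000_000])
        assert near > 0.25 and far > 0.25
        assert abs(near - far) < 0.15

    def test_one_generation_drift_variance(self):
        # var of the frequency change after one generation ~ p(1-p)/(2Ne)
        p = 0.5
        cfg = WrightFisherConfig(ne=50, n_generations=1, n_start_loci=2_000,
                                 init_freq_range=(p, p), sample_size=50, seed=8)
        gm, truth = simulate_wright_fisher(cfg)
        delta = truth["final_pop_freq"] - truth["init_realized_freq"]
        assert np.var(delta) == pytest.approx(p * (1 - p) / (2 * 50), rel=0.2)

    def test_all_fixed_raises(self):
        cfg = WrightFisherConfig(ne=2, n_generations=400, n_start_loci=5,
                                 sample_size=2, seed=1)
        with pytest.raises(RuntimeError, match="fixed before sampling"):
            simulate_wright_fisher(cfg)


class TestPlantRoh:
    @pytest.fixture
    def background(self):
        cfg = StructureSimConfig(k=1, fst=[0.0], maf_range=(0.2, 0.5), n_loci=1_000,
                                 seed=5, n_scaffolds=1, spacing_bp=10_000)
        return simulate_structured(cfg, {"A": 5})[0]

    def test_tract_is_homozygous(self, background):
        t = RohTract("A_1", "scaffold_1", 2_000_000, 4_000_000)
        gm = plant_roh(background, [t])
        si = gm.sample_index("A_1")
        mask = (gm.positions >= t.start) & (gm.positions <= t.end)
        assert set(np.unique(gm.dosages[si, mask])) <= {0, 2}

    def test_error_rate_injects_heterozygotes(self, background):
        t = RohTract("A_1", "scaffold_1", 1_000_000, 9_000_000)
        gm = plant_roh(background, [t], error_rate=0.05, seed=2)
        si = gm.sample_index("A_1")
        mask = (gm.positions >= t.start) & (gm.positions <= t.end)
        het = (gm.dosages[si, mask] == 1).mean()
        assert het == pytest.approx(0.05, abs=0.02)

    def test_empty_spec_is_identity(self, background):
        gm = plant_roh(background, [])
        np.testing.assert_array_equal(gm.dosages, background.dosages)

    def test_outside_tract_unchanged(self, background):
        t = RohTract("A_1", "scaffold_1", 2_000_000, 4_000_000)
        gm = plant_roh(background, [t])
        mask = (gm.positions < t.start) | (gm.positions > t.end)
        np.testing.assert_array_equal(gm.dosages[:, mask], background.dosages[:, mask])

    def test_overlapping_tracts_rejected(self, background):
        tracts = [
            RohTract("A_1", "scaffold_1", 1_000_000, 2_000_000),
            RohTract("A_1", "scaffold_1", 1_500_000, 3_000_000),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            plant_roh(background, tracts)

    def test_out_of_bounds_rejected(self, background):
        with pytest.raises(ValueError, match="bounds"):
            plant_roh(background, [RohTract("A_1", "scaffold_1", 1, 99_000_000)])


class TestPedigree:
    @pytest.mark.parametrize(
        "scheme,expected",
        [("full-sib", 0.25), ("half-sib", 0.125), ("parent-offspring", 0.25)],
    )
    def test_designed_inbreeding(self, scheme, expected):
        ped, known = simulate_pedigree(depth=2, founders=4, scheme=scheme, seed=0)
        designed = {k: v for k, v in known.items() if k.startswith("X")}
        assert designed
        assert all(v == expected for v in designed.values())

    def test_founders_have_zero_f(self):
        _, known = simulate_pedigree(depth=1, founders=4, scheme="random", seed=0)
        assert all(v == 0.0 for k, v in known.items() if k.startswith("F"))

    def test_too_few_founders(self):
        with pytest.raises(ValueError, match="founders"):
            simulate_pedigree(depth=1, founders=1, scheme="random")

    def test_gene_drop_mendelian(self):
        # offspring dosage is consistent with parental alleles at every locus
        ped, _ = simulate_pedigree(depth=2, founders=2, scheme="full-sib", seed=1)
        gm = gene_drop(ped, n_loci=500, seed=3)
        assert gm.dosages.shape == (len(ped), 500)
        assert not np.any(gm.dosages == MISSING)
        # child of two hom-ref parents cannot carry alt alleles
        rows = {r.individual: (r.sire, r.dam) for r in ped.itertuples()}
        for child, (sire, dam) in rows.items():
            if sire is None:
                continue
            ci = gm.sample_index(child)
            si, di = gm.sample_index(sire), gm.sample_index(dam)
            both_ref = (gm.dosages[si] == 0) & (gm.dosages[di] == 0)
            assert np.all(gm.dosages[ci][both_ref] == 0)
            both_alt = (gm.dosages[si] == 2) & (gm.dosages[di] == 2)
            assert np.all(gm.dosages[ci][both_alt] == 2)
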