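"""Synthetic population generator: pedigree structure, meiosis, traits, panels."""

import numpy as np
import pandas as pd
import pytest

from gsduroc import (
    SimConfig,
    TraitArchitecture,
    annotate_variants,
    assign_qtl_effects,
    build_A,
    corrupt_genotypes,
    define_panels,
    drop_haplotypes,
    simulate_dataset,
    simulate_pedigree,
)
from gsduroc.containers import check_panel_nesting
from gsduroc.qc import hwe_chisq_per_variant
from gsduroc.simulate import (
    _final_cohort,
    make_variant_map,
    sample_founder_haplotypes,
    true_breeding_values,
)

from conftest import desk_config


class TestSimulatePedigree:
    def test_default_cohort_structure(self):
        """Default config: 1363 final-cohort boars from 63 sires and 439 dams."""
        cfg = SimConfig()
        ped = simulate_pedigree(cfg)
        cohort = _final_cohort(ped, cfg)
        assert len(cohort) == 1363
        idx = ped.index_of(cohort)
        assert len({ped.sire[i] for i in idx}) == 63
        assert len({ped.dam[i] for i in idx}) == 439
        # every non-founder has both parents recorded
        si, di = ped.parent_indices()
        nonfounder = ~np.char.startswith(ped.animal.astype(str), "F")
        assert np.all(si[nonfounder] >= 0) and np.all(di[nonfounder] >= 0)

    def test_default_cohort_mean_relationship(self):
        """Mean pairwise additive relationship of the cohort near 0.12."""
        cfg = SimConfig()
        ped = simulate_pedigree(cfg)
        idx = ped.index_of(_final_cohort(ped, cfg))
        A = build_A(ped)[np.ix_(idx, idx)]
        mean_off = A[~np.eye(len(idx), dtype=bool)].mean()
        assert 0.08 <= mean_off <= 0.16

    def test_zero_generations_founders_only(self):
        cfg = SimConfig(n_generations=0, n_founders=10)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 10
        assert all(s == "0" for s in ped.sire) and all(d == "0" for d in ped.dam)

    def test_too_many_parents_rejected(self):
        with pytest.raises(ValueError, match="candidates"):
            SimConfig(n_founders=10, n_generations=1, n_sires=8, n_dams=8, n_offspring=20)


class TestDropHaplotypes:
    def test_no_recombination_copies_a_parental_haplotype(self):
        cfg = desk_config(0, chrom_length_cM=0.0, n_seq_variants=200,
                          n_panel650_variants=100, n_panel80_variants=50,
                          n_generations=1, n_founders=10, n_sires=3, n_dams=5,
                          n_offspring=20)
        rng = cfg.rng()
        ped = simulate_pedigree(cfg, rng)
        variants = make_variant_map(cfg, rng)
        fh = sample_founder_haplotypes(cfg, variants, rng)
        geno, haps = drop_haplotypes(ped, fh, variants, cfg, rng, return_haplotypes=True)
        si, di = ped.parent_indices()
        chroms = variants["chrom"].to_numpy()
        slices = [np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms)]
        for i in np.flatnonzero(si >= 0):
            for slot, p in ((0, si[i]), (1, di[i])):
                for sl in slices:  # phase is drawn per chromosome
                    h = haps[i, slot][sl]
                    assert np.array_equal(h, haps[p, 0][sl]) or np.array_equal(
                        h, haps[p, 1][sl]
                    )

    def test_mendelian_consistency(self):
        """Every transmitted allele exists in the transmitting parent."""
        cfg = desk_config(4, n_seq_variants=500, n_panel650_variants=200,
                          n_panel80_variants=100)
        rng = cfg.rng()
        ped = simulate_pedigree(cfg, rng)
        variants = make_variant_map(cfg, rng)
        fh = sample_founder_haplotypes(cfg, variants, rng)
        _, haps = drop_haplotypes(ped, fh, variants, cfg, rng, return_haplotypes=True)
        si, di = ped.parent_indices()
        for i in np.flatnonzero(si >= 0):
            for slot, p in ((0, si[i]), (1, di[i])):
                ok = (haps[i, slot] == haps[p, 0]) | (haps[i, slot] == haps[p, 1])
                assert ok.all()

    def test_haldane_recombination_fraction(self):
        """Adjacent variants 10 cM apart recombine at c = (1 - e^-0.2)/2."""
        cfg = SimConfig(
            n_founders=2, n_generations=0, n_chromosomes=1, chrom_length_cM=10.0,
            n_seq_variants=2, n_panel650_variants=2, n_panel80_variants=2,
        )
        rng = np.random.default_rng(99)
        variants = make_variant_map(cfg, rng)
        variants.loc[0, "pos"] = 1
        variants.loc[1, "pos"] = 10_000_000  # 10 cM at 1 cM/Mb
        # heterozygous parent with alleles in repulsion
        from gsduroc.simulate import _meiosis

        parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
        cM = variants["pos"].to_numpy() / 1e6
        n_meioses = 20000
        rec = 0
        for _ in range(n_meioses):
            g = _meiosis(parent, [slice(0, 2)], cM, np.array([10.0]), rng)
            rec += g[0] != g[1]
        c_hat = rec / n_meioses
        c_exp = (1 - np.exp(-0.2)) / 2
        se = np.sqrt(c_exp * (1 - c_exp) / n_meioses)
        assert abs(c_hat - c_exp) < 3 * se

    def test_position_outside_map_rejected(self):
        cfg = desk_config(0)
        rng = cfg.rng()
        ped = simulate_pedigree(cfg, rng)
        variants = make_variant_map(cfg, rng)
        variants.loc[0, "pos"] = int(cfg.chrom_length_cM * 1e6) + 10_000_000
        variants = variants.sort_values(["chrom", "pos"], kind="stable")
        fh = sample_founder_haplotypes(cfg, variants, rng)
        with pytest.raises(ValueError, match="map"):
            drop_haplotypes(ped, fh, variants.reset_index(drop=True), cfg, rng)


class TestTraits:
    def test_oligogenic_qtl_on_designated_chromosomes(self, desk_data):
        eff = desk_data.truth.qtl_effects["OLI"]
        v = desk_data.variants.set_index("id")
        assert len(eff) == 10
        assert set(v.loc[eff.index, "chrom"]) <= {"1", "2"}

    def test_tbv_matches_dosage_times_effect(self, desk_data):
        tbv = true_breeding_values(desk_data.geno_true, desk_data.truth.qtl_effects)
        got = desk_data.truth.tbv.loc[tbv.index]
        assert np.allclose(tbv.to_numpy(), got.to_numpy())

    def test_target_genetic_variance_realized(self):
        """Realized var(TBV) within 10% of target at n >= 1000."""
        cfg = desk_config(
            31, n_offspring=(100, 100, 100, 200, 1200),
            trait_architectures=(
                TraitArchitecture("T", 50, "polygenic", target_genetic_variance=1.0),
            ),
            h2_targets={"T": 0.5},
        )
        data = simulate_dataset(cfg)
        v = float(np.var(data.truth.tbv.loc[data.cohort, "T"]))
        assert 0.9 <= v <= 1.1

    def test_zero_qtl_rejected(self):
        with pytest.raises(ValueError, match="n_qtl"):
            TraitArchitecture("T", 0, "polygenic")

    def test_infeasible_maf_range_rejected(self, desk_data):
        arch = TraitArchitecture("T", 500, "oligogenic", qtl_maf_range=(0.49, 0.5))
        with pytest.raises(ValueError, match="MAF range"):
            assign_qtl_effects(
                desk_data.variants, arch, desk_data.geno_true, np.random.default_rng(0)
            )

    def test_h2_one_means_zero_residual(self):
        cfg = desk_config(
            7, h2_targets={"OLI": 1.0, "POL": 1.0},
            n_contemporary_groups=None,
        )
        data = simulate_dataset(cfg)
        ph = data.phenotypes
        for trait in ("OLI", "POL"):
            ft = data.truth.fixed_truth[trait]
            cg_idx = ph["cg"].str.slice(2).astype(int).to_numpy()
            mach_idx = ph["machine"].str.slice(1).astype(int).to_numpy()
            fixed = (
                ft["cg_effects"][cg_idx]
                + ft["machine_effects"][mach_idx]
                + ft["age_slope"] * (ph["age"] - ph["age"].mean())
            )
            resid = ph[trait] - fixed
            tbv = data.truth.tbv.loc[ph["animal"], trait].to_numpy()
            assert np.corrcoef(resid, tbv)[0, 1] == pytest.approx(1.0, abs=1e-10)


class TestPanelsAndErrors:
    def test_panel_nesting_and_counts(self, desk_data):
        v = desk_data.variants
        check_panel_nesting(v)
        assert v["in_80k"].sum() == 300
        assert v["in_650k"].sum() == 800
        assert v["in_seq"].all()

    def test_ascertainment_biases_panel_maf_upward(self):
        means_80k, means_seq = [], []
        for seed in range(5):
            data = simulate_dataset(desk_config(seed))
            v = data.variants
            means_80k.append(v.loc[v["in_80k"], "maf"].mean())
            means_seq.append(v["maf"].mean())
        assert np.mean(means_80k) > np.mean(means_seq)

    def test_corrupt_zero_rate_identity(self, desk_data):
        g = desk_data.geno_true
        out = corrupt_genotypes(g, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.dosages, g.dosages)

    def test_corrupt_rate_recovers_concordance(self, desk_data):
        from gsduroc import imputation_accuracy

        g = desk_data.geno_true
        out = corrupt_genotypes(g, 0.1, np.random.default_rng(1))
        assert np.array_equal(g.dosages, desk_data.geno_true.dosages)  # input untouched
        _, _, mean_acc = imputation_accuracy(g, out)
        n = g.dosages.size
        se = 100 * np.sqrt(0.1 * 0.9 / n)
        assert abs(mean_acc - 90.0) < 3 * se + 0.05

    def test_maf_dependent_errors_hit_rare_variants_harder(self, desk_data):
        from gsduroc import imputation_accuracy
        from scipy.stats import spearmanr

        g = desk_data.geno_true
        out = corrupt_genotypes(g, 0.08, np.random.default_rng(2), maf_dependence=True)
        per_variant, _, _ = imputation_accuracy(g, out)
        maf = g.maf()
        ok = maf > 0
        rho = spearmanr(maf[ok], per_variant.to_numpy()[ok]).statistic
        assert rho > 0.2  # rarer variants less concordant


class TestAnnotation:
    def test_terms_partition_all_variants(self, desk_data):
        v = desk_data.variants
        assert v["annotation_term"].notna().all()
        assert (v["annotation_term"] != "unannotated").all()

    def test_enrichment_places_qtl_in_functional_terms(self):
        from gsduroc.simulate import NSC_TERMS, REG_TERMS

        func = set(NSC_TERMS) | set(REG_TERMS)
        frac_q, frac_b = [], []
        for seed in range(20):
            data = simulate_dataset(desk_config(seed), annotation_enrichment=10.0)
            v = data.variants
            isf = v["annotation_term"].isin(func)
            frac_q.append(isf[v["is_qtl"]].mean())
            frac_b.append(isf[~v["is_qtl"]].mean())
        assert np.mean(frac_q) > np.mean(frac_b)

    def test_null_enrichment_matches_background(self):
        rng = np.random.default_rng(5)
        data = simulate_dataset(desk_config(3))
        v = annotate_variants(data.variants, data.variants["id"][:50].to_numpy(), rng, enrichment=1.0)
        assert len(v) == len(data.variants)
        assert v["is_qtl"].sum() == 50


class TestReproducibility:
    def test_same_config_same_seed_bit_identical(self):
        cfg = desk_config(77)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        assert np.array_equal(d1.geno.dosages, d2.geno.dosages)
        assert d1.phenotypes.equals(d2.phenotypes)
        assert np.array_equal(d1.pedigree.animal, d2.pedigree.animal)
        pd.testing.assert_frame_equal(d1.variants, d2.variants)

    def test_founders_in_hardy_weinberg(self, desk_data):
        ped = desk_data.pedigree
        cfg = desk_data.config
        rng = np.random.default_rng(123)
        variants = make_variant_map(cfg, rng)
        fh = sample_founder_haplotypes(cfg, variants, rng)
        founders = ped.animal[np.char.startswith(ped.animal.astype(str), "F")]
        from gsduroc.containers import GenotypeMatrix

        dos = fh.sum(axis=1).astype(np.int8)
        gm = GenotypeMatrix(dos, founders[: dos.shape[0]], variants["id"].to_numpy())
        chis = hwe_chisq_per_variant(gm)
        # under HWE roughly 5% of 1-df chi-squares exceed 3.84
        assert (chis > 3.84).mean() < 0.09
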