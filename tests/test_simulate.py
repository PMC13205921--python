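"""Synthetic-data generator: determinism, planted moments, truth coverage."""

import numpy as np
import pandas as pd
import pytest

from hybridexpr.simulate import (SimulationConfig, simulate_all,
                                 simulate_allele_counts, simulate_expression,
                                 simulate_phenotypes_and_annotations,
                                 simulate_trios)


class TestConfigValidation:
    def test_zero_snps_rejected(self):
        cfg = SimulationConfig(n_snps=0)
        with pytest.raises(ValueError):
            simulate_trios(cfg)

    def test_inheritance_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="inheritance_mix"):
            SimulationConfig(inheritance_mix={"additive": 0.5,
                                              "dominantHP": 0.2})

    def test_case_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="case fractions"):
            SimulationConfig(frac_informative=0.9)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_spe=1.2)

    def test_replicate_minimum(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_replicates=1)

    def test_non_positive_depth_rejected(self):
        cfg = SimulationConfig(n_hybrids=2, n_snps=5, mean_depth=0)
        _, truth = simulate_trios(cfg)
        with pytest.raises(ValueError):
            simulate_allele_counts(truth, cfg)


class TestTrios:
    def test_all_informative_means_all_phaseable(self):
        cfg = SimulationConfig(n_hybrids=3, n_snps=50, frac_informative=1.0,
                               frac_uninformative=0.0, frac_parent_het=0.0,
                               frac_conflict=0.0, frac_missing=0.0, seed=1)
        _, truth = simulate_trios(cfg)
        assert truth["true_phase"].isin(["0|1", "1|0"]).all()

    def test_case_rates_within_binomial_error(self):
        cfg = SimulationConfig(n_hybrids=5, n_snps=1000, seed=2)
        _, truth = simulate_trios(cfg)
        n = len(truth)
        for case, frac in (("informative", cfg.frac_informative),
                           ("uninformative", cfg.frac_uninformative),
                           ("parent_het", cfg.frac_parent_het)):
            observed = (truth["true_case"] == case).mean()
            tol = 3 * np.sqrt(frac * (1 - frac) / n)
            assert abs(observed - frac) < tol, case

    def test_genotypes_consistent_with_case(self):
        cfg = SimulationConfig(n_hybrids=2, n_snps=400, seed=3)
        trios, truth = simulate_trios(cfg)
        merged = trios.merge(truth, on=["snp_id", "hybrid_id"])
        inf = merged[merged["true_case"] == "informative"]
        assert (inf["hybrid_gt"] == "0/1").all()
        assert (inf["female_gt"] != inf["male_gt"]).all()
        conf = merged[merged["true_case"] == "conflict"]
        assert (conf["female_gt"] == conf["male_gt"]).all()
        assert (conf["hybrid_gt"] == "0/1").all()


class TestAlleleCounts:
    def test_symmetric_null_alt_fraction_half(self):
        cfg = SimulationConfig(n_hybrids=10, n_snps=100, seed=4,
                               ase_effect_sd=0.0, density_effect_sd=0.0,
                               frac_informative=1.0, frac_uninformative=0.0,
                               frac_parent_het=0.0, frac_conflict=0.0,
                               frac_missing=0.0)
        _, truth = simulate_trios(cfg)
        counts, *_ = simulate_allele_counts(truth, cfg,
                                            true_ratios=np.full(100, 0.5))
        frac = counts["alt_count"].sum() / counts["total_count"].sum()
        n = counts["total_count"].sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n) * 3

    def test_planted_ratio_recovered_at_depth(self):
        cfg = SimulationConfig(n_hybrids=10, n_snps=50, seed=5,
                               ase_effect_sd=0.0, density_effect_sd=0.0,
                               mean_depth=5000, frac_informative=1.0,
                               frac_uninformative=0.0, frac_parent_het=0.0,
                               frac_conflict=0.0, frac_missing=0.0)
        _, truth = simulate_trios(cfg)
        counts, *_ = simulate_allele_counts(truth, cfg,
                                            true_ratios=np.full(50, 0.2))
        frac = counts["alt_count"].sum() / counts["total_count"].sum()
        assert frac == pytest.approx(0.2, abs=0.01)

    def test_alt_never_exceeds_total_and_zero_totals_kept(self):
        cfg = SimulationConfig(n_hybrids=4, n_snps=100, seed=6, mean_depth=3,
                               nb_dispersion=2.0)
        _, truth = simulate_trios(cfg)
        counts, *_ = simulate_allele_counts(truth, cfg)
        assert (counts["alt_count"] <= counts["total_count"]).all()
        assert (counts["total_count"] == 0).any()  # retained, not dropped


class TestExpression:
    def test_spe_count_binomial(self):
        cfg = SimulationConfig(n_hybrids=2, n_genes=1000, n_snps=1,
                               frac_spe=0.1, seed=7)
        *_, truth, _ = simulate_expression(cfg)
        n_spe = truth["true_spe"].sum()
        assert abs(n_spe - 100) < 3 * np.sqrt(1000 * 0.1 * 0.9)

    def test_planted_spe_silent_parent_below_threshold(self):
        cfg = SimulationConfig(n_hybrids=2, n_genes=400, n_snps=1,
                               frac_spe=0.1, seed=8)
        counts, fpkm, meta, gi, truth, _ = simulate_expression(cfg)
        spe = truth[truth["true_spe"]]
        fem_cols = meta.index[meta["genotype_id"] == "F_HYB01"]
        silent_f = spe[spe["true_spe_silent_parent"] == "female"]
        assert (fpkm.loc[silent_f.index, fem_cols].mean(axis=1) < 0.1).all()

    def test_planted_additive_gene_at_mid_parent(self):
        cfg = SimulationConfig(n_hybrids=1, n_genes=600, n_snps=1, seed=9,
                               expr_dispersion=0.01,
                               entropy_sharpening_range=(1.0, 1.0),
                               frac_density_de=0.0, frac_role_de=0.0,
                               stage_effect_sd=0.0)
        counts, fpkm, meta, gi, truth, _ = simulate_expression(cfg)
        add = truth.index[truth["true_mode"] == "additive"]
        cols = {g: meta.index[meta["genotype_id"] == g]
                for g in ("HYB01", "F_HYB01", "M_HYB01")}
        mh = counts.loc[add, cols["HYB01"]].mean(axis=1)
        mid = 0.5 * (counts.loc[add, cols["F_HYB01"]].mean(axis=1)
                     + counts.loc[add, cols["M_HYB01"]].mean(axis=1))
        ratio = (mh / mid).mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_planted_ahp_gene_above_high_parent(self):
        cfg = SimulationConfig(n_hybrids=1, n_genes=800, n_snps=1, seed=10,
                               entropy_sharpening_range=(1.0, 1.0))
        counts, fpkm, meta, gi, truth, _ = simulate_expression(cfg)
        ahp = truth.index[truth["true_mode"] == "overdominantAHP"]
        assert len(ahp) > 0
        cols = {g: meta.index[meta["genotype_id"] == g]
                for g in ("HYB01", "F_HYB01", "M_HYB01")}
        mh = counts.loc[ahp, cols["HYB01"]].mean(axis=1)
        hi = np.maximum(counts.loc[ahp, cols["F_HYB01"]].mean(axis=1),
                        counts.loc[ahp, cols["M_HYB01"]].mean(axis=1))
        assert (mh > hi).all()


class TestPhenotypes:
    def test_null_entropy_correlation(self):
        cfg = SimulationConfig(n_hybrids=100, n_snps=1, n_genes=50,
                               entropy_heterosis_r=0.0, seed=11)
        data = simulate_phenotypes_and_annotations(cfg)
        t = data["phenotype_truth"]
        r = np.corrcoef(t["true_entropy_reduction"],
                        t["true_absolute_heterosis"])[0, 1]
        assert abs(r) < 3 / np.sqrt(100) * 1.5

    def test_no_deleterious_genes_no_pairs(self):
        cfg = SimulationConfig(n_hybrids=4, n_snps=1, n_genes=100,
                               frac_deleterious=0.0, seed=12)
        data = simulate_phenotypes_and_annotations(cfg)
        assert data["pair_truth"].empty
        assert data["deleterious_hap_counts"].empty

    def test_release_year_span_enforced(self):
        cfg = SimulationConfig(n_hybrids=4, n_snps=1, n_genes=50,
                               release_year_range=(2000, 2000), seed=13)
        with pytest.raises(ValueError):
            simulate_phenotypes_and_annotations(cfg)


class TestDeterminismAndTruth:
    def test_byte_identical_outputs_at_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(n_hybrids=3, n_snps=30, n_genes=50, seed=42)
        simulate_all(cfg, tmp_path / "a")
        simulate_all(cfg, tmp_path / "b")
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_truth_covers_all_generated_entities(self, small_dataset):
        _, data = small_dataset
        # every trio record has a truth record
        merged = data["trios"].merge(data["trio_truth"],
                                     on=["snp_id", "hybrid_id"], how="left")
        assert merged["true_case"].notna().all()
        # every SNP with counts has a planted ratio
        assert set(data["allele_counts"]["snp_id"]) <= \
            set(data["ase_truth"]["snp_id"])
        # every expressed gene has an expression truth row
        assert set(data["expr_counts"].index) == set(data["expr_truth"].index)
        # every complementary-pair haplotype record has pair truth
        hap_keys = set(map(tuple, data["deleterious_hap_counts"]
                           [["gene_id", "hybrid_id"]].drop_duplicates()
                           .itertuples(index=False)))
        truth_keys = set(map(tuple, data["pair_truth"]
                             [["gene_id", "hybrid_id"]].itertuples(index=False)))
        assert hap_keys == truth_keys

    def test_vcf_round_trip_matches_tsv(self, tmp_path):
        from hybridexpr.io import read_trio_vcf
        cfg = SimulationConfig(n_hybrids=2, n_snps=20, seed=14)
        data = simulate_all(cfg, tmp_path)
        back = read_trio_vcf(tmp_path / "genotypes.vcf", data["manifest"])
        merged = data["trios"].merge(
            back, on=["snp_id", "hybrid_id"], suffixes=("", "_vcf"))
        assert len(merged) == len(data["trios"])
        assert (merged["female_gt"] == merged["female_gt_vcf"]).all()
        assert (merged["male_gt"] == merged["male_gt_vcf"]).all()
        # hybrid genotypes match up to phasing notation and allele order
        def norm(gt):
            return "/".join(sorted(gt.replace("|", "/").split("/")))
        assert (merged["hybrid_gt"].map(norm)
                == merged["hybrid_gt_vcf"].map(norm)).all()
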