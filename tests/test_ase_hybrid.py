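"""Haplotype ASE: aggregation, imbalance tests, cis/trans, density response."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from hybridexpr.ase_hybrid import (aggregate_haplotype_counts,
                                   classify_allelic_response,
                                   classify_density_consistency,
                                   classify_regulatory_pattern)
from hybridexpr.ase_hybrid import test_allelic_imbalance as imbalance_test


def _counts(rows):
    return pd.DataFrame(rows, columns=["snp_id", "hybrid_id", "density",
                                       "replicate", "ref_count", "alt_count"])


def _phased(pairs):
    return pd.DataFrame(pairs, columns=["snp_id", "phased_gt"])


MAP = pd.DataFrame({"snp_id": ["v1", "v2", "v3"],
                    "gene_id": ["g1", "g1", "g2"]})


class TestAggregation:
    def test_sums_snps_within_gene(self):
        counts = _counts([("v1", "H1", "HPD", 1, 10, 5),
                          ("v2", "H1", "HPD", 1, 20, 15)])
        out = aggregate_haplotype_counts(
            counts, _phased([("v1", "0|1"), ("v2", "0|1")]), MAP)
        row = out.iloc[0]
        assert (row["maternal_count"], row["paternal_count"]) == (30, 20)

    def test_gene_without_phased_snps_absent(self):
        counts = _counts([("v3", "H1", "HPD", 1, 10, 5)])
        out = aggregate_haplotype_counts(counts, _phased([("v3", "none")]), MAP)
        assert out.empty

    def test_phase_orientation_flips_alleles(self):
        """Swap-phase oracle: flipping all phases swaps the allele columns."""
        counts = _counts([("v1", "H1", "HPD", 1, 10, 5),
                          ("v2", "H1", "HPD", 1, 20, 15)])
        fwd = aggregate_haplotype_counts(
            counts, _phased([("v1", "0|1"), ("v2", "0|1")]), MAP)
        rev = aggregate_haplotype_counts(
            counts, _phased([("v1", "1|0"), ("v2", "1|0")]), MAP)
        assert list(fwd["maternal_count"]) == list(rev["paternal_count"])
        assert list(fwd["paternal_count"]) == list(rev["maternal_count"])

    def test_snp_in_two_genes_assigned_to_none(self):
        bad_map = pd.DataFrame({"snp_id": ["v1", "v1"],
                                "gene_id": ["g1", "g9"]})
        counts = _counts([("v1", "H1", "HPD", 1, 10, 5)])
        out = aggregate_haplotype_counts(counts, _phased([("v1", "0|1")]),
                                         bad_map)
        assert out.empty


def _hap(rows):
    return pd.DataFrame(rows, columns=["gene_id", "hybrid_id", "density",
                                       "replicate", "maternal_count",
                                       "paternal_count"])


class TestImbalance:
    def test_balanced_gene_not_ase(self):
        out = imbalance_test(_hap([("g1", "H1", "HPD", 1, 50, 50)]))
        assert out.iloc[0]["p"] == pytest.approx(1.0)
        assert not out.iloc[0]["ase"]

    def test_strong_imbalance_detected(self):
        out = imbalance_test(_hap([("g1", "H1", "HPD", 1, 80, 20)]))
        row = out.iloc[0]
        assert row["ase_log2_ratio"] == pytest.approx(2.0)
        assert row["p"] < 1e-6
        assert row["ase"]
        # independent tail-sum oracle for the two-sided exact test
        pmf = binom.pmf(np.arange(101), 100, 0.5)
        oracle = pmf[pmf <= pmf[80] * (1 + 1e-9)].sum()
        assert row["p"] == pytest.approx(oracle, rel=1e-6)

    def test_total_monoallelic_closed_form(self):
        out = imbalance_test(_hap([("g1", "H1", "HPD", 1, 0, 40)]))
        assert out.iloc[0]["p"] == pytest.approx(2 * 0.5**40)
        assert out.iloc[0]["ase"]

    def test_min_total_excludes_shallow_genes(self):
        out = imbalance_test(_hap([("g1", "H1", "HPD", 1, 5, 4)]),
                                     min_total=20)
        assert out.empty

    def test_swap_symmetry(self):
        rows = [("g1", "H1", "HPD", 1, 80, 20), ("g2", "H1", "HPD", 1, 30, 70)]
        fwd = imbalance_test(_hap(rows))
        swapped = [(g, h, d, r, p, m) for g, h, d, r, m, p in rows]
        rev = imbalance_test(_hap(swapped))
        assert np.allclose(fwd["p"], rev["p"])
        assert np.allclose(fwd["ase_log2_ratio"], -rev["ase_log2_ratio"])


class TestRegulatoryPattern:
    DEPTH = 4000

    def _counts_for(self, log2_ratio):
        p = 2.0**log2_ratio / (1 + 2.0**log2_ratio)
        mat = int(round(self.DEPTH * p))
        return mat, self.DEPTH - mat

    def test_cis_only_matches_parental_fold_change(self):
        mat, pat = self._counts_for(2.0)
        out = classify_regulatory_pattern(mat, pat, parental_log2fc=2.0)
        assert out["pattern"] == "cis_only"

    def test_trans_only_equal_alleles_despite_parental_de(self):
        mat, pat = self._counts_for(0.0)
        out = classify_regulatory_pattern(mat, pat, parental_log2fc=2.0)
        assert out["pattern"] == "trans_only"

    def test_unexpected_when_allelic_bias_opposes_parents(self):
        mat, pat = self._counts_for(-1.0)
        out = classify_regulatory_pattern(mat, pat, parental_log2fc=2.0)
        assert out["pattern"] == "unexpected"

    def test_cis_plus_trans_same_direction(self):
        mat, pat = self._counts_for(1.0)
        out = classify_regulatory_pattern(mat, pat, parental_log2fc=2.5)
        assert out["pattern"] == "cis_plus_trans_same"

    def test_cis_plus_trans_opposite_direction(self):
        mat, pat = self._counts_for(2.5)
        out = classify_regulatory_pattern(mat, pat, parental_log2fc=1.0)
        assert out["pattern"] == "cis_plus_trans_opposite"

    def test_missing_parental_info_ambiguous(self):
        out = classify_regulatory_pattern(50, 50, parental_log2fc=np.nan)
        assert out["pattern"] == "ambiguous"
        out = classify_regulatory_pattern(50, 50, parental_log2fc=2.0,
                                          parental_de=False)
        assert out["pattern"] == "ambiguous"

    def test_planted_patterns_recovered_at_depth(self, rng):
        """>= 90% of planted cis/trans/cis+trans genes recovered at depth 500."""
        planted = []
        results = []
        for _ in range(100):
            kind = rng.choice(["cis_only", "trans_only", "cis_plus_trans_same"])
            fc = rng.uniform(1.5, 3.0)
            ratio = {"cis_only": fc, "trans_only": 0.0,
                     "cis_plus_trans_same": fc / 2}[kind]
            p = 2.0**ratio / (1 + 2.0**ratio)
            mat = rng.binomial(500, p)
            out = classify_regulatory_pattern(mat, 500 - mat,
                                              parental_log2fc=fc)
            planted.append(kind)
            results.append(out["pattern"])
        correct = np.mean([a == b for a, b in zip(planted, results)])
        assert correct >= 0.9


class TestDensityConsistency:
    def _imb(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "hybrid_id", "density",
                                           "ase", "ase_log2_ratio"])

    @pytest.mark.parametrize("hpd, lpd, label", [
        ((True, 1.0), (True, 0.5), "consistent"),
        ((True, 1.0), (True, -0.5), "direction_shift"),
        ((True, 1.0), (False, 0.1), "HPD_only"),
        ((False, 0.1), (True, -1.0), "LPD_only"),
        ((False, 0.1), (False, 0.0), "none"),
    ])
    def test_labels(self, hpd, lpd, label):
        imb = self._imb([("g1", "H1", "HPD", *hpd), ("g1", "H1", "LPD", *lpd)])
        out = classify_density_consistency(imb)
        assert out.iloc[0]["density_consistency"] == label
        assert not out.iloc[0]["one_density"]

    def test_single_density_flagged(self):
        imb = self._imb([("g1", "H1", "HPD", True, 1.0)])
        out = classify_density_consistency(imb)
        assert out.iloc[0]["density_consistency"] == "HPD_only"
        assert out.iloc[0]["one_density"]


class TestAllelicResponse:
    def _hap_response(self, rng, mat_fc, pat_fc, base=200, reps=3):
        rows = []
        for dens, mult_m, mult_p in (("LPD", 1.0, 1.0),
                                     ("HPD", 2.0**mat_fc, 2.0**pat_fc)):
            for r in range(1, reps + 1):
                rows.append(("g1", "H1", dens, r,
                             rng.poisson(base * mult_m),
                             rng.poisson(base * mult_p)))
        # anchor genes so normalisation and the BH family are well-behaved
        for i in range(2, 30):
            for dens in ("LPD", "HPD"):
                for r in range(1, reps + 1):
                    rows.append((f"g{i}", "H1", dens, r,
                                 rng.poisson(base), rng.poisson(base)))
        return _hap(rows)

    @pytest.mark.parametrize("mat_fc, pat_fc, label", [
        (2.0, 1.5, "same_direction"),
        (2.0, 0.0, "female_specific"),
        (0.0, -2.0, "male_specific"),
        (2.0, -2.0, "opposite_direction"),
        (0.0, 0.0, "none"),
    ])
    def test_categories(self, rng, mat_fc, pat_fc, label):
        hap = self._hap_response(rng, mat_fc, pat_fc)
        out = classify_allelic_response(hap, fdr_level=0.01, lfc=1.0)
        assert out.set_index("gene_id").loc["g1", "allelic_response"] == label

    def test_insufficient_replicates_flagged(self, rng):
        hap = self._hap_response(rng, 2.0, 2.0, reps=1)
        out = classify_allelic_response(hap)
        row = out.set_index("gene_id").loc["g1"]
        assert row["allelic_response"] == "none"
        assert row["insufficient_replicates"]
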