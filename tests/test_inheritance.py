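"""DE testing, SPE/CE, D/A ratio and inheritance-mode classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybridexpr.inheritance import (DABands, call_parental_de, call_spe_ce,
                                    classify_expression_classes,
                                    classify_inheritance, compute_da,
                                    fit_multifactor_de, size_factors)


class TestDA:
    @pytest.mark.parametrize("p1, p2, f1, expected", [
        (6.0, 14.0, 10.0, 0.0),
        (6.0, 14.0, 14.0, 1.0),
        (6.0, 14.0, 18.0, 2.0),
        (6.0, 14.0, 6.0, -1.0),
    ])
    def test_worked_examples(self, p1, p2, f1, expected):
        assert compute_da(p1, p2, f1) == pytest.approx(expected)

    def test_equal_parents_undefined(self):
        assert np.isnan(compute_da(5.0, 5.0, 7.0))

    @settings(max_examples=50, derandomize=True)
    @given(p1=st.floats(0.1, 100), p2=st.floats(0.1, 100),
           f1=st.floats(0.0, 200))
    def test_parent_relabelling_invariance(self, p1, p2, f1):
        a = compute_da(p1, p2, f1)
        b = compute_da(p2, p1, f1)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


class TestSpeCe:
    def test_spe_and_ce_thresholds(self):
        idx = ["g1", "g2", "g3"]
        p1 = pd.Series([0.05, 0.5, 0.05], index=idx)
        p2 = pd.Series([3.0, 3.0, 3.0], index=idx)
        f1 = pd.Series([2.0, 2.0, 0.8], index=idx)
        out = call_spe_ce(p1, p2, f1)
        assert out.loc["g1", "spe"] and out.loc["g1", "ce"]
        assert not out.loc["g2", "spe"]          # 0.1 <= P1: gap zone
        assert out.loc["g3", "spe"] and not out.loc["g3", "ce"]
        assert out.loc["g1", "silent_parent"] == "P1"

    def test_ce_count_never_exceeds_spe_count(self, rng):
        n = 300
        idx = [f"g{i}" for i in range(n)]
        p1 = pd.Series(rng.uniform(0, 3, n), index=idx)
        p2 = pd.Series(rng.uniform(0, 3, n), index=idx)
        f1 = pd.Series(rng.uniform(0, 3, n), index=idx)
        out = call_spe_ce(p1, p2, f1)
        assert out["ce"].sum() <= out["spe"].sum()
        assert not (out["ce"] & ~out["spe"]).any()

    def test_expression_classes(self):
        m = pd.DataFrame({"A": [5.0, 0.01, 5.0], "B": [2.0, 0.05, 0.01]},
                         index=["g1", "g2", "g3"])
        out = classify_expression_classes(m)
        assert list(out) == ["expressed", "silent", "genotype_dependent"]


def _two_group_counts(rng, n_genes, lfc_by_gene, base=300, reps=3):
    idx = [f"g{i}" for i in range(n_genes)]
    a = pd.DataFrame({f"a{r}": rng.poisson(base, n_genes) for r in range(reps)},
                     index=idx)
    mult = 2.0 ** np.asarray(lfc_by_gene)
    b = pd.DataFrame({f"b{r}": rng.poisson(base * mult)
                      for r in range(reps)}, index=idx)
    return a, b


class TestParentalDE:
    def test_tiers_from_planted_fold_changes(self, rng):
        lfc = np.zeros(60)
        lfc[0], lfc[1], lfc[2] = 1.4, 2.5, 3.3
        a, b = _two_group_counts(rng, 60, lfc, base=800)
        out = call_parental_de(a, b).set_index("gene_id")
        assert out.loc["g0", "de_tier"] == "DE_2"
        assert out.loc["g1", "de_tier"] == "DE_4"
        assert out.loc["g2", "de_tier"] == "DE_8"
        assert (out.iloc[10:]["de_tier"] == "none").mean() > 0.9

    def test_non_significant_gene_has_no_tier(self, rng):
        a, b = _two_group_counts(rng, 40, np.zeros(40))
        out = call_parental_de(a, b)
        assert (~out["de"]).mean() > 0.9
        assert (out.loc[~out["de"], "de_tier"] == "none").all()

    def test_single_replicate_rejected(self, rng):
        a, b = _two_group_counts(rng, 5, np.zeros(5), reps=1)
        with pytest.raises(ValueError):
            call_parental_de(a, b)


class TestMultifactorDE:
    @staticmethod
    def _design(n_stage=2, reps=2):
        rows = []
        for role in ("hybrid", "inbred"):
            for stage in [f"V{i}" for i in range(n_stage)]:
                for dens in ("HPD", "LPD"):
                    for r in range(reps):
                        rows.append((f"{role}.{stage}.{dens}.{r}", role,
                                     stage, dens, r))
        return pd.DataFrame(rows, columns=["sample_id", "role", "stage",
                                           "density", "replicate"]
                            ).set_index("sample_id")

    def test_planted_role_effect_recovered(self, rng):
        meta = self._design()
        n = 80
        counts = pd.DataFrame(
            {s: rng.poisson(400, n) for s in meta.index},
            index=[f"g{i}" for i in range(n)])
        hybrid_cols = meta.index[meta["role"] == "hybrid"]
        counts.loc["g0", hybrid_cols] = rng.poisson(1600, len(hybrid_cols))
        out = fit_multifactor_de(counts, meta)
        g0 = out.set_index(["gene_id", "contrast"])
        row = g0.loc[("g0", "hybrid_vs_inbred")]
        assert row["log2fc"] == pytest.approx(2.0, abs=0.4)
        assert row["de"]
        assert abs(g0.loc[("g0", "density_HPD"), "log2fc"]) < 0.5

    def test_constant_counts_nothing_de(self):
        meta = self._design()
        counts = pd.DataFrame(100, index=[f"g{i}" for i in range(5)],
                              columns=meta.index)
        out = fit_multifactor_de(counts, meta)
        assert np.allclose(out["log2fc"], 0.0, atol=1e-6)
        assert not out["de"].any()

    def test_effect_size_gate(self, rng):
        """A sub-two-fold change stays non-DE however small its FDR."""
        meta = self._design(reps=6)
        n = 40
        counts = pd.DataFrame(
            {s: rng.poisson(2000, n) for s in meta.index},
            index=[f"g{i}" for i in range(n)])
        hybrid_cols = meta.index[meta["role"] == "hybrid"]
        counts.loc["g0", hybrid_cols] = rng.poisson(2000 * 2**0.9,
                                                    len(hybrid_cols))
        out = fit_multifactor_de(counts, meta).set_index(["gene_id", "contrast"])
        row = out.loc[("g0", "hybrid_vs_inbred")]
        assert row["fdr"] < 0.01
        assert abs(row["log2fc"]) < 1.0
        assert not row["de"]

    def test_null_simulation_flags_at_most_two_percent(self, rng):
        """With no planted effects, <= 2% of 2000 genes are called DE."""
        meta = self._design(n_stage=3, reps=2)
        n = 2000
        base = rng.uniform(50, 500, n)
        k = 1 / 0.05
        counts = pd.DataFrame(
            {s: rng.poisson(rng.gamma(k, base / k)) for s in meta.index},
            index=[f"g{i}" for i in range(n)])
        out = fit_multifactor_de(counts, meta)
        per_gene_de = out.groupby("gene_id")["de"].any()
        assert per_gene_de.mean() <= 0.02

    def test_rank_deficient_design_names_confounded_factors(self):
        meta = self._design()
        meta["density"] = np.where(meta["role"] == "hybrid", "HPD", "LPD")
        counts = pd.DataFrame(10, index=["g0"], columns=meta.index)
        with pytest.raises(ValueError, match="confounded"):
            fit_multifactor_de(counts, meta)


class TestClassifyInheritance:
    def _counts(self, rng, mu1, mu2, muf, reps=3, disp=0.02):
        def draw(mu):
            k = 1 / disp
            return rng.poisson(rng.gamma(k, mu / k, reps))
        mk = lambda mu, pre: pd.DataFrame([draw(mu)], index=["g"],
                                          columns=[f"{pre}{r}" for r in range(reps)])
        return mk(mu1, "p1"), mk(mu2, "p2"), mk(muf, "f1")

    @pytest.mark.parametrize("muf_factor, expected", [
        ("mid", "MP"), ("high", "HP"), ("double_high", "AHP"), ("low", "LP"),
    ])
    def test_planted_single_gene_modes(self, rng, muf_factor, expected):
        mu1, mu2 = 100.0, 400.0
        muf = {"mid": 250.0, "high": 400.0, "double_high": 800.0,
               "low": 100.0}[muf_factor]
        p1, p2, f1 = self._counts(rng, mu1, mu2, muf)
        sf = pd.Series(1.0, index=list(p1) + list(p2) + list(f1))
        out = classify_inheritance(p1, p2, f1, sf=sf)
        assert out.loc["g", "mode"] == expected

    def test_equal_parents_da_undefined_mode_conservative(self, rng):
        p1, p2, f1 = self._counts(rng, 300.0, 300.0, 300.0)
        sf = pd.Series(1.0, index=list(p1) + list(p2) + list(f1))
        out = classify_inheritance(p1, p2, f1, sf=sf)
        assert out.loc["g", "mode"] == "MP"

    def test_custom_bands_respected(self, rng):
        p1, p2, f1 = self._counts(rng, 100.0, 400.0, 800.0)
        sf = pd.Series(1.0, index=list(p1) + list(p2) + list(f1))
        loose = classify_inheritance(p1, p2, f1, sf=sf,
                                     bands=DABands(0.25, 0.75, 10.0))
        assert loose.loc["g", "mode"] != "AHP"


def test_size_factors_recover_planted_libraries(rng):
    n = 400
    base = rng.uniform(50, 500, n)
    libs = np.array([0.8, 1.0, 1.25, 1.1])
    counts = pd.DataFrame(
        {f"s{j}": rng.poisson(base * libs[j]) for j in range(4)})
    sf = size_factors(counts)
    norm = sf / np.exp(np.log(sf).mean())
    expected = libs / np.exp(np.log(libs).mean())
    assert np.allclose(norm, expected, rtol=0.05)
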