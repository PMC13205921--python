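"""Per-hybrid haplotype allele-specific expression and regulatory patterns.

Phased SNP read counts are aggregated to gene-level maternal/paternal
haplotype counts (per-SNP summation; the synthetic generator emits counts
that are already de-duplicated at the read level, and this simplification
is recorded in output metadata).  Allelic imbalance per gene is tested with
an exact two-sided binomial test against 0.5, FDR-controlled within each
hybrid x density family.

Combining the hybrid's allelic ratio with the parents' differential
expression separates regulatory modes: a *trans*-only gene shows equal
allelic expression in the hybrid despite parental DE (diffusible factors
equalise the alleles); a *cis*-only gene preserves the parental fold change
between its alleles; *cis* + *trans* genes fall in between (same direction)
or beyond (opposite direction); and genes whose allelic bias opposes the
parental direction are "unexpected".  Candidate allelic-ratio models are
compared by BIC on the binomial likelihood.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from hybridexpr.fdr import bh_fdr
from hybridexpr.inheritance import pairwise_nb_test

__all__ = [
    "aggregate_haplotype_counts",
    "test_allelic_imbalance",
    "classify_regulatory_pattern",
    "classify_density_consistency",
    "classify_allelic_response",
]

logger = logging.getLogger(__name__)

_SAMPLE_KEYS = ["hybrid_id", "density", "replicate"]


def aggregate_haplotype_counts(counts: pd.DataFrame, phased: pd.DataFrame,
                               snp_to_gene: pd.DataFrame) -> pd.DataFrame:
    """Sum phased per-SNP allele counts to gene-level haplotype counts.

    Parameters
    ----------
    counts
        Long table ``snp_id, hybrid_id, density, replicate, ref_count,
        alt_count``.
    phased
        Phasing output with ``snp_id, phased_gt`` (only ``0|1`` / ``1|0``
        rows are used).  With phase ``0|1`` the maternal (female) allele is
        the reference allele; ``1|0`` flips the orientation.
    snp_to_gene
        Mapping with ``snp_id, gene_id``; SNPs mapped to more than one gene
        are assigned to none (warned).

    Returns
    -------
    Long table ``gene_id, hybrid_id, density, replicate, maternal_count,
    paternal_count``; genes without phased SNPs are absent.
    """
    phase_keys = ["snp_id"] + (["hybrid_id"] if "hybrid_id" in phased.columns
                               and "hybrid_id" in counts.columns else [])
    phase = phased.loc[phased["phased_gt"].isin(["0|1", "1|0"]),
                       phase_keys + ["phased_gt"]]
    n_genes = snp_to_gene.groupby("snp_id")["gene_id"].nunique()
    multi = n_genes.index[n_genes > 1]
    if len(multi):
        logger.warning("%d SNP(s) map to multiple genes; assigned to none",
                       len(multi))
    gene_map = (snp_to_gene.loc[~snp_to_gene["snp_id"].isin(multi)]
                .drop_duplicates("snp_id"))
    df = counts.merge(phase, on=phase_keys).merge(gene_map, on="snp_id")
    if df.empty:
        return pd.DataFrame(columns=["gene_id", *_SAMPLE_KEYS,
                                     "maternal_count", "paternal_count"])
    is01 = df["phased_gt"] == "0|1"
    df["maternal_count"] = np.where(is01, df["ref_count"], df["alt_count"])
    df["paternal_count"] = np.where(is01, df["alt_count"], df["ref_count"])
    out = (df.groupby(["gene_id", *_SAMPLE_KEYS], sort=True)
           [["maternal_count", "paternal_count"]].sum().reset_index())
    return out


def test_allelic_imbalance(hap: pd.DataFrame, min_total: int = 20,
                           fdr_level: float = 0.05) -> pd.DataFrame:
    """Exact binomial ASE test per gene, pooled per hybrid x density.

    Replicates are summed; genes with maternal+paternal below ``min_total``
    are skipped (zero-total genes always).  The two-sided binomial p-value
    against 0.5 is BH-adjusted within each hybrid x density family and the
    ASE flag requires FDR below ``fdr_level``.
    """
    pooled = (hap.groupby(["gene_id", "hybrid_id", "density"], sort=True)
              [["maternal_count", "paternal_count"]].sum().reset_index())
    pooled["total"] = pooled["maternal_count"] + pooled["paternal_count"]
    pooled = pooled.loc[pooled["total"] >= max(min_total, 1)].copy()
    with np.errstate(divide="ignore"):
        pooled["ase_log2_ratio"] = np.log2(
            pooled["maternal_count"] / pooled["paternal_count"])
    pooled["p"] = [
        sps.binomtest(int(m), int(t), 0.5).pvalue
        for m, t in zip(pooled["maternal_count"], pooled["total"])
    ]
    pooled["fdr"] = np.nan
    for _, idx in pooled.groupby(["hybrid_id", "density"]).groups.items():
        pooled.loc[idx, "fdr"] = bh_fdr(pooled.loc[idx, "p"])
    pooled["ase"] = pooled["fdr"] < fdr_level
    return pooled.reset_index(drop=True)


def _binomial_bic(mat: int, pat: int, p: float, k: int) -> float:
    n = mat + pat
    p = min(max(p, 1e-12), 1 - 1e-12)
    ll = mat * np.log(p) + pat * np.log(1 - p)
    return -2.0 * ll + k * np.log(n)


def classify_regulatory_pattern(maternal: int, paternal: int,
                                parental_log2fc: float,
                                parental_de: bool = True,
                                bic_margin: float = 2.0) -> dict:
    """Cis/trans classification of one gene in one hybrid.

    ``parental_log2fc`` is log2(female parent / male parent) on the same
    orientation as maternal/paternal counts.  Three allelic-ratio models
    are compared by BIC on the binomial likelihood of the pooled counts:
    equal alleles (trans-only), the parental fold change (cis-only), and a
    free ratio (cis + trans); the free ratio is split into same/opposite
    direction by its magnitude relative to the parental fold change, and an
    allelic bias whose sign opposes the parental DE direction is
    "unexpected".  A BIC gap below ``bic_margin`` between the two best
    models yields "ambiguous", as does missing parental DE information.
    """
    out = {"pattern": "ambiguous", "allelic_log2_ratio": np.nan,
           "bic_delta": np.nan}
    if not parental_de or parental_log2fc is None or np.isnan(parental_log2fc):
        return out
    total = maternal + paternal
    if total == 0:
        return out
    with np.errstate(divide="ignore"):
        allelic = float(np.log2(maternal / paternal)) if paternal and maternal \
            else float(np.log2((maternal + 0.5) / (paternal + 0.5)))
    out["allelic_log2_ratio"] = allelic
    p_cis = 2.0**parental_log2fc / (1.0 + 2.0**parental_log2fc)
    p_free = maternal / total
    bics = {
        "trans_only": _binomial_bic(maternal, paternal, 0.5, 0),
        "cis_only": _binomial_bic(maternal, paternal, p_cis, 0),
        "free": _binomial_bic(maternal, paternal, p_free, 1),
    }
    order = sorted(bics, key=bics.get)
    out["bic_delta"] = bics[order[1]] - bics[order[0]]
    if out["bic_delta"] < bic_margin:
        return out
    best = order[0]
    if best in ("trans_only", "cis_only"):
        out["pattern"] = best
        return out
    if np.sign(allelic) != np.sign(parental_log2fc):
        out["pattern"] = "unexpected"
    elif abs(allelic) < abs(parental_log2fc):
        out["pattern"] = "cis_plus_trans_same"
    else:
        out["pattern"] = "cis_plus_trans_opposite"
    return out


def classify_density_consistency(imbalance: pd.DataFrame,
                                 high_label: str = "HPD",
                                 low_label: str = "LPD") -> pd.DataFrame:
    """Consistency of per-gene ASE between the two density treatments.

    Input is :func:`test_allelic_imbalance` output for one hybrid.  A gene
    ASE in both densities with the same bias sign is ``consistent``; with
    opposite signs ``direction_shift``; ASE in exactly one density is
    ``HPD_only`` / ``LPD_only``; otherwise ``none``.  Genes tested in a
    single density are classified from that density alone and flagged.
    """
    wide = imbalance.pivot_table(index=["gene_id", "hybrid_id"],
                                 columns="density",
                                 values=["ase", "ase_log2_ratio"],
                                 aggfunc="first")
    recs = []
    for (gene, hyb), row in wide.iterrows():
        have_h = (high_label in wide["ase"].columns
                  and not pd.isna(row.get(("ase", high_label), np.nan)))
        have_l = (low_label in wide["ase"].columns
                  and not pd.isna(row.get(("ase", low_label), np.nan)))
        one_density = not (have_h and have_l)
        ase_h = bool(row.get(("ase", high_label), False)) if have_h else False
        ase_l = bool(row.get(("ase", low_label), False)) if have_l else False
        sign_h = np.sign(row.get(("ase_log2_ratio", high_label), np.nan))
        sign_l = np.sign(row.get(("ase_log2_ratio", low_label), np.nan))
        if ase_h and ase_l:
            label = "consistent" if sign_h == sign_l else "direction_shift"
        elif ase_h:
            label = f"{high_label}_only"
        elif ase_l:
            label = f"{low_label}_only"
        else:
            label = "none"
        recs.append((gene, hyb, label, one_density))
    return pd.DataFrame(recs, columns=["gene_id", "hybrid_id",
                                       "density_consistency", "one_density"])


def classify_allelic_response(hap: pd.DataFrame, fdr_level: float = 0.01,
                              lfc: float = 1.0, high_label: str = "HPD",
                              low_label: str = "LPD") -> pd.DataFrame:
    """Allele-specific response to density stress for one hybrid.

    Each parental allele's replicate counts are tested high vs low density
    with the pairwise NB GLM; an allele responds when |log2FC| > ``lfc``
    and FDR < ``fdr_level``.  Genes are then labelled ``same_direction``,
    ``opposite_direction``, ``female_specific``, ``male_specific`` or
    ``none``.  Genes with fewer than two replicates per condition are
    labelled ``none`` and flagged.
    """
    hybrids = hap["hybrid_id"].unique()
    if len(hybrids) != 1:
        raise ValueError("classify_allelic_response expects one hybrid")
    results = {}
    enough = None
    for allele, col in (("maternal", "maternal_count"),
                        ("paternal", "paternal_count")):
        mats = {}
        for dens in (high_label, low_label):
            sub = hap.loc[hap["density"] == dens]
            mats[dens] = sub.pivot_table(index="gene_id", columns="replicate",
                                         values=col, aggfunc="sum")
        genes = mats[high_label].index.intersection(mats[low_label].index)
        ok = ((mats[high_label].loc[genes].notna().sum(axis=1) >= 2)
              & (mats[low_label].loc[genes].notna().sum(axis=1) >= 2))
        enough = ok if enough is None else (enough & ok)
        a = mats[low_label].loc[genes].fillna(0.0)
        b = mats[high_label].loc[genes].fillna(0.0)
        res = pairwise_nb_test(a, b)  # log2FC of HPD relative to LPD
        res = res.set_index("gene_id")
        res["responsive"] = (res["fdr"] < fdr_level) & (res["log2fc"].abs() > lfc)
        results[allele] = res
    genes = results["maternal"].index.intersection(results["paternal"].index)
    mat = results["maternal"].loc[genes]
    pat = results["paternal"].loc[genes]
    insufficient = ~enough.reindex(genes).fillna(False)
    both = mat["responsive"] & pat["responsive"]
    same_sign = np.sign(mat["log2fc"]) == np.sign(pat["log2fc"])
    label = np.select(
        [insufficient,
         both & same_sign,
         both & ~same_sign,
         mat["responsive"] & ~pat["responsive"],
         pat["responsive"] & ~mat["responsive"]],
        ["none", "same_direction", "opposite_direction",
         "female_specific", "male_specific"],
        default="none")
    return pd.DataFrame({
        "gene_id": genes,
        "hybrid_id": hybrids[0],
        "maternal_log2fc": mat["log2fc"].to_numpy(),
        "paternal_log2fc": pat["log2fc"].to_numpy(),
        "maternal_responsive": mat["responsive"].to_numpy(),
        "paternal_responsive": pat["responsive"].to_numpy(),
        "allelic_response": label,
        "insufficient_replicates": insufficient.to_numpy(),
    })
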