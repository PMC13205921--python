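"""Deleterious-allele load, complementation and suppression in hybrids.

High-effect variants (frameshift, stop gained/lost, splice acceptor/donor,
gene fusion, exon loss, start lost, transcript ablation) mark an allele as
deleterious; a gene is counted once per parent however many such variants
it carries.  In a hybrid, a gene whose alleles are deleterious in exactly
one parent forms a complementary pair — the functional allele can mask the
deleterious one.  A pair is *suppressed* when the functional allele is
expressed at least two-fold above the deleterious allele with a significant
exact binomial test (FDR < 0.05).  GERP rejected-substitution scores above
2 define evolutionarily constrained (putatively deleterious) sites, split
into coding (CDS) versus cis-regulatory (2-kb upstream) regions for
breeding-trend correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from hybridexpr.fdr import bh_fdr
from hybridexpr.stats import correlate

__all__ = [
    "HIGH_EFFECT_CATEGORIES",
    "identify_deleterious",
    "find_complementary_pairs",
    "call_suppression",
    "gerp_region_trends",
]

logger = logging.getLogger(__name__)

HIGH_EFFECT_CATEGORIES = frozenset({
    "frameshift", "stop_gained", "splice_acceptor", "splice_donor",
    "gene_fusion", "exon_loss", "start_lost", "stop_lost",
    "transcript_ablation",
})

GERP_THRESHOLD = 2.0


def _deleterious_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    ann = annotations.copy()
    unknown = ann["impact"].isna()
    if unknown.any():
        logger.warning("%d unannotated variant(s) treated as modifier impact",
                       int(unknown.sum()))
        ann.loc[unknown, "impact"] = "modifier"
    return ann.loc[ann["effect_category"].isin(HIGH_EFFECT_CATEGORIES)]


def identify_deleterious(annotations: pd.DataFrame, carriers: pd.DataFrame,
                         trios: pd.DataFrame) -> pd.DataFrame:
    """Per-line deleterious gene counts and per-hybrid mid-parent counts.

    Parameters
    ----------
    annotations
        Variant table ``variant_id, gene_id, effect_category, impact,
        gerp_rs, region``.
    carriers
        Long table ``variant_id, genotype_id`` listing which line carries
        each variant.
    trios
        Manifest ``hybrid_id, female_id, male_id``.

    Returns
    -------
    Per-hybrid table with female, male and mid-parent deleterious gene
    counts (gene-level set semantics: multiple high-effect variants in one
    gene count once).
    """
    dele = _deleterious_annotations(annotations)
    hits = carriers.merge(dele[["variant_id", "gene_id"]], on="variant_id")
    genes_by_line = hits.groupby("genotype_id")["gene_id"].agg(set)
    recs = []
    for t in trios.itertuples(index=False):
        nf = len(genes_by_line.get(t.female_id, set()))
        nm = len(genes_by_line.get(t.male_id, set()))
        recs.append((t.hybrid_id, nf, nm, 0.5 * (nf + nm)))
    return pd.DataFrame(recs, columns=["hybrid_id", "n_deleterious_female",
                                       "n_deleterious_male", "mid_parent"])


def find_complementary_pairs(annotations: pd.DataFrame, carriers: pd.DataFrame,
                             trios: pd.DataFrame,
                             coding_only: bool = True) -> pd.DataFrame:
    """Genes deleterious on exactly one parental allele, per hybrid.

    Genes whose deleterious variants sit on both parental alleles are
    excluded (nothing to complement), as are genes deleterious in neither.
    With ``coding_only`` (default) only CDS-region variants define the
    deleterious allele, per the gene-centric pairing definition.
    """
    dele = _deleterious_annotations(annotations)
    if coding_only:
        dele = dele.loc[dele["region"] == "CDS"]
    hits = carriers.merge(dele[["variant_id", "gene_id"]], on="variant_id")
    genes_by_line = hits.groupby("genotype_id")["gene_id"].agg(set)
    recs = []
    for t in trios.itertuples(index=False):
        gf = genes_by_line.get(t.female_id, set())
        gm = genes_by_line.get(t.male_id, set())
        for gene in sorted(gf ^ gm):  # exactly one parent deleterious
            parent = "female" if gene in gf else "male"
            recs.append((gene, t.hybrid_id, parent))
    return pd.DataFrame(recs, columns=["gene_id", "hybrid_id",
                                       "deleterious_parent"])


def call_suppression(pairs: pd.DataFrame, hap: pd.DataFrame,
                     min_fold_log2: float = 1.0,
                     fdr_level: float = 0.05) -> pd.DataFrame:
    """Deleterious-allele suppression flags for complementary pairs.

    Haplotype counts (``gene_id, hybrid_id, maternal_count,
    paternal_count``; replicates/densities are summed) orient which allele
    is deleterious via ``deleterious_parent``.  A pair is suppressed when
    the functional allele count exceeds the deleterious one with
    |log2(functional/deleterious)| > ``min_fold_log2`` and exact binomial
    FDR < ``fdr_level`` (BH within each hybrid).  Zero-total pairs are
    dropped from the denominator (logged).
    """
    counts = (hap.groupby(["gene_id", "hybrid_id"])
              [["maternal_count", "paternal_count"]].sum())
    merged = pairs.merge(counts, on=["gene_id", "hybrid_id"], how="inner")
    is_female = merged["deleterious_parent"] == "female"
    merged["deleterious_count"] = np.where(is_female, merged["maternal_count"],
                                           merged["paternal_count"])
    merged["functional_count"] = np.where(is_female, merged["paternal_count"],
                                          merged["maternal_count"])
    total = merged["deleterious_count"] + merged["functional_count"]
    n_zero = int((total == 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-total complementary pair(s)", n_zero)
    merged = merged.loc[total > 0].copy()
    with np.errstate(divide="ignore"):
        merged["log2_functional_over_deleterious"] = np.log2(
            merged["functional_count"] / merged["deleterious_count"])
    merged["p"] = [
        sps.binomtest(int(f), int(f + d), 0.5).pvalue
        for f, d in zip(merged["functional_count"], merged["deleterious_count"])
    ]
    merged["fdr"] = np.nan
    for _, idx in merged.groupby("hybrid_id").groups.items():
        merged.loc[idx, "fdr"] = bh_fdr(merged.loc[idx, "p"])
    merged["suppressed"] = (
        (merged["functional_count"] > merged["deleterious_count"])
        & (merged["log2_functional_over_deleterious"] > min_fold_log2)
        & (merged["fdr"] < fdr_level))
    return merged.reset_index(drop=True)


def suppression_proportions(suppression: pd.DataFrame) -> pd.DataFrame:
    """Per-hybrid suppressed / complementary-pair proportions."""
    g = suppression.groupby("hybrid_id")["suppressed"]
    out = g.agg(n_pairs="size", n_suppressed="sum").reset_index()
    out["proportion_suppressed"] = out["n_suppressed"] / out["n_pairs"]
    return out


def gerp_region_trends(annotations: pd.DataFrame, carriers: pd.DataFrame,
                       trios: pd.DataFrame, phenotypes: pd.DataFrame,
                       gerp_threshold: float = GERP_THRESHOLD) -> pd.DataFrame:
    """Breeding trends of complemented constrained variants by region.

    Counts, per hybrid, complemented variant sites (carried by exactly one
    parent) with GERP RS above ``gerp_threshold``, separately for CDS and
    2-kb-upstream cis regions, and correlates each count with hybrid
    release year plus any trait values present in ``phenotypes`` (columns
    beyond ``hybrid_id, release_year``).  Requires at least three hybrids.
    """
    if len(trios) < 3:
        raise ValueError("correlations need >= 3 hybrids")
    constrained = annotations.loc[annotations["gerp_rs"] > gerp_threshold]
    hits = carriers.merge(constrained[["variant_id", "region"]], on="variant_id")
    var_by_line = hits.groupby("genotype_id").apply(
        lambda d: d.groupby("region")["variant_id"].agg(set), include_groups=False)
    recs = []
    for t in trios.itertuples(index=False):
        row = {"hybrid_id": t.hybrid_id}
        for region in ("CDS", "cis_upstream_2kb"):
            vf = (var_by_line.loc[t.female_id].get(region, set())
                  if t.female_id in var_by_line.index else set())
            vm = (var_by_line.loc[t.male_id].get(region, set())
                  if t.male_id in var_by_line.index else set())
            row[f"n_complemented_{region}"] = len(vf ^ vm)
        recs.append(row)
    counts = pd.DataFrame(recs)
    merged = counts.merge(phenotypes, on="hybrid_id")
    targets = [c for c in merged.columns
               if c not in ("hybrid_id",) and not c.startswith("n_complemented_")]
    rows = []
    for region in ("CDS", "cis_upstream_2kb"):
        x = merged[f"n_complemented_{region}"].to_numpy(float)
        for target in targets:
            y = merged[target].to_numpy(float)
            try:
                r, p, r2 = correlate(x, y)
            except ValueError as err:
                logger.warning("correlation %s vs %s undefined: %s",
                               region, target, err)
                r = p = r2 = np.nan
            rows.append((region, target, len(merged), r, p, r2))
    return pd.DataFrame(rows, columns=["region", "target", "n", "r", "p",
                                       "r_squared"])
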