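"""Transcriptomic Shannon entropy as a measure of expression plasticity.

For a genotype sampled across developmental stages and treatments, each
sample's expression profile is converted to a frequency vector (the FPKM
share of every gene within the sample), the frequencies are averaged over
the genotype's samples, and the Shannon entropy

    H(G) = - sum_i p_i log2 p_i

of the averaged vector summarises how evenly the transcriptome is spread
over genes.  A hybrid with lower entropy than its parents has a more
structured (less uniform) expression distribution; the entropy reduction

    dH = mean(H_female, H_male) - H_hybrid

is positive in that case and can be correlated with phenotypic heterosis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hybridexpr.stats import correlate

__all__ = [
    "expression_frequencies",
    "shannon_entropy",
    "entropy_profile",
    "entropy_reduction",
    "trio_entropy",
    "entropy_heterosis_association",
]

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-9


def expression_frequencies(fpkm: pd.DataFrame):
    """Per-sample expression frequencies and their average.

    Parameters
    ----------
    fpkm
        Genes x samples FPKM matrix for one genotype.

    Returns
    -------
    (freqs, p) where ``freqs`` is the genes x samples matrix of within-sample
    FPKM shares (each column sums to 1) and ``p`` is the across-sample mean
    frequency vector (sums to 1).  All-zero samples are excluded and logged.
    """
    if fpkm.shape[1] == 0:
        raise ValueError("need at least one sample")
    totals = fpkm.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        logger.warning("excluding %d all-zero sample(s) from frequencies", int(zero.sum()))
        fpkm = fpkm.loc[:, ~zero]
        totals = totals[~zero]
    if fpkm.shape[1] == 0:
        raise ValueError("all samples have zero total expression")
    freqs = fpkm.div(totals, axis=1)
    p = freqs.mean(axis=1)
    return freqs, p


def shannon_entropy(p) -> float:
    """Shannon entropy in bits of a frequency vector (0*log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > max(_NORM_TOL, 1e-6):
        raise ValueError(f"frequencies sum to {p.sum():.6g}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def filter_gene_universe(fpkm: pd.DataFrame, min_mean_fpkm: float = 1.0) -> pd.Index:
    """Genes whose mean FPKM over the given samples reaches ``min_mean_fpkm``."""
    return fpkm.index[fpkm.mean(axis=1) >= min_mean_fpkm]


def entropy_profile(fpkm: pd.DataFrame, genotype_id: str) -> dict:
    """EntropyProfile for one genotype: averaged frequencies plus H in bits."""
    freqs, p = expression_frequencies(fpkm)
    return {
        "genotype_id": genotype_id,
        "n_samples": freqs.shape[1],
        "n_genes": int(p.size),
        "entropy_bits": shannon_entropy(p.to_numpy()),
        "frequencies": p,
        "samples": list(freqs.columns),
    }


def entropy_reduction(hybrid_profile: dict, female_profile: dict,
                      male_profile: dict) -> dict:
    """Hybrid-parent entropy reduction dH = mean(H_f, H_m) - H_hybrid.

    All three profiles must be computed over the same gene universe.
    Positive dH means the hybrid transcriptome is more structured (lower
    entropy) than its parents.
    """
    gh = hybrid_profile["frequencies"].index
    gf = female_profile["frequencies"].index
    gm = male_profile["frequencies"].index
    if not (gh.equals(gf) and gh.equals(gm)):
        raise ValueError("gene universes differ between profiles; "
                         "intersect the FPKM matrices and recompute")
    hf, hm = female_profile["entropy_bits"], male_profile["entropy_bits"]
    hh = hybrid_profile["entropy_bits"]
    return {
        "entropy_female": hf,
        "entropy_male": hm,
        "entropy_hybrid": hh,
        "entropy_mid_parent": 0.5 * (hf + hm),
        "entropy_reduction": 0.5 * (hf + hm) - hh,
    }


def trio_entropy(fpkm: pd.DataFrame, metadata: pd.DataFrame, hybrid_id: str,
                 female_id: str, male_id: str,
                 min_mean_fpkm: float = 1.0) -> dict:
    """Entropy profiles and dH for one trio over a shared gene universe.

    Genes with mean FPKM below ``min_mean_fpkm`` across all samples of the
    three genotypes are removed before frequencies are computed, and the
    same retained-gene set is applied to all three genotypes.
    """
    ids = {"hybrid": hybrid_id, "female": female_id, "male": male_id}
    cols = {k: metadata.index[metadata["genotype_id"] == v] for k, v in ids.items()}
    for k, c in cols.items():
        if len(c) == 0:
            raise ValueError(f"no samples for {k} genotype {ids[k]!r}")
    all_cols = cols["hybrid"].append([cols["female"], cols["male"]])
    universe = filter_gene_universe(fpkm[all_cols], min_mean_fpkm)
    profiles = {k: entropy_profile(fpkm.loc[universe, c], ids[k])
                for k, c in cols.items()}
    out = entropy_reduction(profiles["hybrid"], profiles["female"], profiles["male"])
    out["hybrid_id"] = hybrid_id
    out["n_genes"] = len(universe)
    out["profiles"] = profiles
    return out


def entropy_heterosis_association(entropy_reduction_by_hybrid: pd.Series,
                                  heterosis: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-hybrid dH with heterosis, per trait.

    ``heterosis`` must carry columns ``hybrid_id, trait`` and a value column
    (``absolute_heterosis`` preferred, else ``value``).  Requires at least
    three hybrids with both quantities.
    """
    value_col = ("absolute_heterosis" if "absolute_heterosis" in heterosis.columns
                 else "value")
    rows = []
    for trait, sub in heterosis.groupby("trait"):
        merged = (sub.groupby("hybrid_id")[value_col].mean()
                  .to_frame("het")
                  .join(entropy_reduction_by_hybrid.rename("dh"), how="inner")
                  .dropna())
        if len(merged) < 3:
            raise ValueError(f"trait {trait!r}: fewer than 3 hybrids with "
                             "both entropy reduction and heterosis")
        r, p, r2 = correlate(merged["dh"], merged["het"])
        rows.append((trait, len(merged), r, p, r2))
    return pd.DataFrame(rows, columns=["trait", "n", "r", "p", "r_squared"])
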