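"""Parent-guided phasing of hybrid heterozygous SNPs.

In an F1 hybrid, any site where the two parents are opposite homozygotes is
trivially phaseable: the hybrid must carry one allele from each parent.  A
site is phased ``0|1`` when the female parent is ``0/0`` and the male parent
``1/1`` (maternal allele written first), and ``1|0`` for the opposite
configuration.  Sites heterozygous in either parent carry no reliable phase
information and are removed, as are sites whose hybrid genotype contradicts
Mendelian expectation (e.g. both parents ``0/0`` but the hybrid ``0/1``).
"""

from __future__ import annotations

import logging

import pandas as pd

__all__ = ["phase_trio", "GT_CODES"]

logger = logging.getLogger(__name__)

#: canonical diploid genotype codes over a biallelic site
GT_CODES = {"0/0", "0/1", "1/0", "1/1", "0|1", "1|0", "0|0", "1|1", "./.", "."}

_HET = {"0/1", "1/0", "0|1", "1|0"}
_HOM_REF = {"0/0", "0|0"}
_HOM_ALT = {"1/1", "1|1"}
_MISSING = {"./.", "."}


def _alleles(gt: str):
    return gt.replace("|", "/").split("/")


def _classify(female: str, male: str, hybrid: str):
    """(phased_gt, filter_reason) for one trio genotype combination."""
    gts = (female, male, hybrid)
    if any(g in _MISSING for g in gts):
        return "none", "missing"
    # multi-allelic alleles (>=2) cannot be phased against a biallelic model
    for g in gts:
        if any(a not in ("0", "1") for a in _alleles(g)):
            return "none", "uninformative"
    if female in _HET or male in _HET:
        return "none", "parent_het"
    same_parents = (female in _HOM_REF) == (male in _HOM_REF)
    if same_parents:
        # parents identical homozygotes: a het hybrid is a Mendelian conflict,
        # a homozygous hybrid carries no allele-specific information
        return ("none", "conflict") if hybrid in _HET else ("none", "uninformative")
    # informative: opposite parental homozygotes
    if hybrid not in _HET:
        # hybrid should be heterozygous here; treat as genotyping error
        return "none", "conflict"
    phased = "0|1" if female in _HOM_REF else "1|0"
    return phased, "kept"


def phase_trio(records: pd.DataFrame, female_col: str = "female_gt",
               male_col: str = "male_gt", hybrid_col: str = "hybrid_gt"
               ) -> pd.DataFrame:
    """Assign phase and filter labels to trio genotype records.

    Parameters
    ----------
    records
        One row per SNP with female, male and hybrid genotype codes
        (``0/0``-style; already-phased ``0|1`` codes are accepted, making the
        operation idempotent).

    Returns
    -------
    Copy of the input with ``phased_gt`` (``0|1`` / ``1|0`` / ``none``) and
    ``filter_reason`` (``kept, parent_het, conflict, uninformative,
    missing``) columns.  Rows with malformed genotype codes are rejected
    (dropped) with a logged count rather than aborting the run.
    """
    out = records.copy()
    valid_code = out[[female_col, male_col, hybrid_col]].isin(GT_CODES).all(axis=1)
    # codes like "2/2" are syntactically genotype-shaped but multi-allelic:
    # accept any a/b with integer alleles, reject true garbage
    shaped = out[[female_col, male_col, hybrid_col]].apply(
        lambda col: col.astype(str).str.fullmatch(r"\d+[/|]\d+|\.[/|]\.|\.").fillna(False)
    ).all(axis=1)
    ok = valid_code | shaped
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("rejected %d record(s) with malformed genotype codes", n_bad)
        out = out.loc[ok].copy()

    keys = list(zip(out[female_col], out[male_col], out[hybrid_col]))
    cache: dict[tuple, tuple] = {}
    phased, reason = [], []
    for k in keys:
        if k not in cache:
            cache[k] = _classify(*k)
        ph, re_ = cache[k]
        phased.append(ph)
        reason.append(re_)
    out["phased_gt"] = phased
    out["filter_reason"] = reason
    return out


def phase_summary(phased: pd.DataFrame) -> pd.DataFrame:
    """Counts of each filter_reason (partition of the phased input)."""
    counts = phased["filter_reason"].value_counts()
    return (counts.rename_axis("filter_reason").reset_index(name="n_snps")
            .sort_values("filter_reason", ignore_index=True))
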