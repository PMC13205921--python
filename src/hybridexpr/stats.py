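"""Phenotype heterosis, genetic gain and correlation utilities.

Mid-parent heterosis for a trait is the difference between the hybrid's
phenotypic value and the average of its two parents; percent heterosis
expresses that difference relative to the mid-parent value.  Genetic gain
over a breeding period is the slope of an ordinary least-squares regression
of trait performance (or heterosis) on hybrid release year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "compute_heterosis",
    "genetic_gain",
    "fisher_z_compare",
    "correlate",
]


def compute_heterosis(phenotypes: pd.DataFrame, trios: pd.DataFrame) -> pd.DataFrame:
    """Mid-parent, absolute and percent heterosis per hybrid x trait x density.

    Parameters
    ----------
    phenotypes
        Long table with columns ``genotype_id, trait, density, value`` (a
        ``role`` column is permitted and ignored; values are trait units).
    trios
        Trio manifest with columns ``hybrid_id, female_id, male_id``.

    Returns
    -------
    DataFrame with columns ``hybrid_id, trait, density, hybrid_value,
    mid_parent, absolute_heterosis, percent_heterosis, status``.  Cells where
    a parent is unmeasured are skipped with ``status='missing_parent'``;
    a zero mid-parent value yields ``percent_heterosis = NaN`` and
    ``status='zero_mid_parent'``.
    """
    value = phenotypes.set_index(["genotype_id", "trait", "density"])["value"]
    rows = []
    for t in trios.itertuples(index=False):
        hyb_cells = phenotypes.loc[
            phenotypes["genotype_id"] == t.hybrid_id, ["trait", "density"]
        ].drop_duplicates()
        for trait, density in hyb_cells.itertuples(index=False):
            f1 = value.get((t.hybrid_id, trait, density), np.nan)
            p1 = value.get((t.female_id, trait, density), np.nan)
            p2 = value.get((t.male_id, trait, density), np.nan)
            if np.isnan(p1) or np.isnan(p2):
                rows.append((t.hybrid_id, trait, density, f1, np.nan, np.nan,
                             np.nan, "missing_parent"))
                continue
            mp = 0.5 * (p1 + p2)
            absolute = f1 - mp
            if mp == 0:
                rows.append((t.hybrid_id, trait, density, f1, mp, absolute,
                             np.nan, "zero_mid_parent"))
            else:
                rows.append((t.hybrid_id, trait, density, f1, mp, absolute,
                             100.0 * absolute / mp, "ok"))
    return pd.DataFrame(
        rows,
        columns=["hybrid_id", "trait", "density", "hybrid_value", "mid_parent",
                 "absolute_heterosis", "percent_heterosis", "status"],
    )


def genetic_gain(values, years):
    """OLS regression of a trait (or heterosis) value on hybrid release year.

    Returns ``(slope, intercept, r_squared)`` with the slope in trait units
    per year.  Requires at least three hybrids and two distinct years.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    if values.size < 3:
        raise ValueError("genetic gain needs >= 3 hybrids")
    if np.unique(years).size < 2:
        raise ValueError("genetic gain needs >= 2 distinct release years")
    res = sps.linregress(years, values)
    return res.slope, res.intercept, res.rvalue**2


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int):
    """Compare two independent Pearson correlations with Fisher's z test.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the two-sided
    p-value is from the standard normal.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return z, p


def correlate(x, y):
    """Pearson correlation with t-distribution p-value and R^2.

    Returns ``(r, p, r_squared)``; raises on n < 3 or zero variance in
    either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return r, p, r**2
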