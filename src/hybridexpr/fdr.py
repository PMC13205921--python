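"""Benjamini-Hochberg false-discovery-rate control."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr"]


def bh_fdr(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (q-values) in the input order.

    NaN p-values are rejected: the caller decides which tests form the
    family, so silent dropping would change the correction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed in the BH family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
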