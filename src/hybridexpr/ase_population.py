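"""Population-level allele-specific expression via a Bayesian binomial GLMM.

For each genic SNP heterozygous in a panel of hybrids, the alternative-allele
read count in hybrid (genotype) g under treatment t is modelled as

    alt_gt ~ Binomial(total_gt, p_gt),   logit(p_gt) = b0 + a_g + c_t

with random effects a_g ~ N(0, sigma_a^2) over hybrids and c_t ~ N(0,
sigma_c^2) over treatments (planting densities).  The allelic bias of the
SNP is the posterior of invlogit(b0).  Because reference-bias and other
global asymmetries shift the whole dataset, the null ratio is not 0.5 but
the median observed ratio m of the filtered dataset; a SNP is tested with a
two-sided posterior tail probability about m and the Benjamini-Hochberg
procedure controls the FDR across SNPs.

Priors are weakly informative (b0 ~ N(0, 2.5^2); sigma ~ HalfNormal(1)) and
configurable.  Inference is by an adaptive Metropolis-within-Gibbs sampler
vectorised across SNPs and chains, so thousands of SNPs are fitted jointly
in a few numpy passes per sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hybridexpr.fdr import bh_fdr

__all__ = [
    "ASEModelSpec",
    "filter_ase_snps",
    "compute_null_ratio",
    "fit_ase_population",
    "fit_ase_glmm",
    "summarize_ase",
]

logger = logging.getLogger(__name__)


@dataclass
class ASEModelSpec:
    """Priors and sampler settings for the binomial mixed model.

    ``prior_intercept_sd`` is the SD of the Normal prior on the logit-scale
    intercept; ``prior_sigma_sd`` the scale of the HalfNormal priors on the
    genotype and treatment random-effect SDs.  The sampler runs ``chains``
    independent chains of ``warmup`` adaptation sweeps followed by ``draws``
    retained sweeps; convergence is monitored with split-R-hat on b0.
    """

    prior_intercept_sd: float = 2.5
    prior_sigma_sd: float = 1.0
    chains: int = 4
    draws: int = 1000
    warmup: int = 500
    seed: int = 0
    rhat_threshold: float = 1.05
    ci_level: float = 0.975  # 97.5% credible interval
    fdr_level: float = 0.05

    def __post_init__(self):
        if self.prior_intercept_sd <= 0 or self.prior_sigma_sd <= 0:
            raise ValueError("prior SDs must be positive")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for split-R-hat")


def filter_ase_snps(obs: pd.DataFrame, min_hybrids: int = 10,
                    min_total: int = 10) -> pd.DataFrame:
    """Keep observations with enough reads at SNPs heterozygous in enough hybrids.

    Observations with ``total_count < min_total`` are removed first; SNPs
    then heterozygous (observed) in fewer than ``min_hybrids`` distinct
    hybrids are dropped entirely.  Both bounds are inclusive.
    """
    if obs.empty:
        logger.warning("filter_ase_snps: empty observation table")
        return obs.copy()
    kept = obs.loc[obs["total_count"] >= min_total]
    n_hyb = kept.groupby("snp_id")["hybrid_id"].nunique()
    good = n_hyb.index[n_hyb >= min_hybrids]
    out = kept.loc[kept["snp_id"].isin(good)].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_ase_snps: no SNP passed the filters")
    return out


def compute_null_ratio(obs: pd.DataFrame) -> float:
    """Median alt/total ratio over all filtered observations (the null m)."""
    if obs.empty:
        raise ValueError("cannot compute a null ratio from an empty table")
    return float((obs["alt_count"] / obs["total_count"]).median())


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _ll_terms(alt, tot, b0, alpha, gamma):
    """Binomial log-likelihood terms, shape (chains, S, G, T).

    alt*eta - tot*log(1 + e^eta); cells with tot == 0 contribute zero.
    """
    eta = b0[..., None, None] + alpha[..., :, None] + gamma[..., None, :]
    return alt * eta - tot * np.logaddexp(0.0, eta)


class _Adapter:
    """Per-parameter proposal scales adapted toward 0.44 acceptance."""

    def __init__(self, shape, target=0.44):
        self.log_s = np.full(shape, -0.5)
        self.acc = np.zeros(shape)
        self.n = 0
        self.batch = 0
        self.target = target

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accepted):
        self.acc += accepted
        self.n += 1
        if self.n == 50:
            self.batch += 1
            delta = min(0.25, self.batch**-0.5)
            self.log_s += delta * np.sign(self.acc / self.n - self.target)
            self.acc[...] = 0.0
            self.n = 0


def _split_rhat(draws):
    """Split-R-hat over axis (chains, draws, S) -> (S,)."""
    c, n, s = draws.shape
    half = n // 2
    seq = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    m, n2 = seq.shape[0], seq.shape[1]
    means = seq.mean(axis=1)
    variances = seq.var(axis=1, ddof=1)
    w = variances.mean(axis=0)
    b = n2 * means.var(axis=0, ddof=1)
    var_hat = (n2 - 1) / n2 * w + b / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / w)


def _run_sampler(alt, tot, spec: ASEModelSpec):
    """Adaptive MH-within-Gibbs over all SNPs at once.

    Returns posterior draws of b0 with shape (chains, draws, S) plus mean
    random-effect SDs for metadata.
    """
    s_snps, n_g, n_t = alt.shape
    c = spec.chains
    rng = np.random.default_rng(spec.seed)

    # start the intercept at the empirical pooled logit (overdispersed by chain)
    pooled_ratio = (alt.sum(axis=(1, 2)) + 0.5) / (tot.sum(axis=(1, 2)) + 1.0)
    b0_init = np.log(pooled_ratio / (1.0 - pooled_ratio))
    b0 = b0_init[None, :] + rng.normal(0.0, 0.2, size=(c, s_snps))
    alpha = rng.normal(0.0, 0.1, size=(c, s_snps, n_g))
    gamma = rng.normal(0.0, 0.1, size=(c, s_snps, n_t))
    log_sa = np.full((c, s_snps), np.log(0.3)) + rng.normal(0, 0.05, (c, s_snps))
    log_sc = np.full((c, s_snps), np.log(0.3)) + rng.normal(0, 0.05, (c, s_snps))

    ad_b0 = _Adapter((c, s_snps))
    ad_a = _Adapter((c, s_snps, n_g))
    ad_g = _Adapter((c, s_snps, n_t))
    ad_sa = _Adapter((c, s_snps))
    ad_sc = _Adapter((c, s_snps))
    ad_ta = _Adapter((c, s_snps))
    ad_tc = _Adapter((c, s_snps))

    terms = _ll_terms(alt, tot, b0, alpha, gamma)
    draws_b0 = np.empty((c, spec.draws, s_snps))
    sa_sum = np.zeros((c, s_snps))
    sc_sum = np.zeros((c, s_snps))

    isd2 = 1.0 / spec.prior_intercept_sd**2
    sig2 = spec.prior_sigma_sd**2

    total_iter = spec.warmup + spec.draws
    for it in range(total_iter):
        adapting = it < spec.warmup

        # --- intercept ---
        prop = b0 + ad_b0.scale * rng.standard_normal(b0.shape)
        terms_p = _ll_terms(alt, tot, prop, alpha, gamma)
        d = (terms_p.sum(axis=(-1, -2)) - terms.sum(axis=(-1, -2))
             - 0.5 * isd2 * (prop**2 - b0**2))
        acc = np.log(rng.random(b0.shape)) < d
        b0 = np.where(acc, prop, b0)
        terms = np.where(acc[..., None, None], terms_p, terms)
        if adapting:
            ad_b0.update(acc)

        # --- genotype random effects (independent across g given the rest) ---
        sa2 = np.exp(2 * log_sa)[..., None]
        prop = alpha + ad_a.scale * rng.standard_normal(alpha.shape)
        terms_p = _ll_terms(alt, tot, b0, prop, gamma)
        d = (terms_p.sum(axis=-1) - terms.sum(axis=-1)
             - 0.5 * (prop**2 - alpha**2) / sa2)
        acc = np.log(rng.random(alpha.shape)) < d
        alpha = np.where(acc, prop, alpha)
        terms = np.where(acc[..., None], terms_p, terms)
        if adapting:
            ad_a.update(acc)

        # --- treatment random effects ---
        sc2 = np.exp(2 * log_sc)[..., None]
        prop = gamma + ad_g.scale * rng.standard_normal(gamma.shape)
        terms_p = _ll_terms(alt, tot, b0, alpha, prop)
        d = (terms_p.sum(axis=-2) - terms.sum(axis=-2)
             - 0.5 * (prop**2 - gamma**2) / sc2)
        acc = np.log(rng.random(gamma.shape)) < d
        gamma = np.where(acc, prop, gamma)
        terms = np.where(acc[..., None, :], terms_p, terms)
        if adapting:
            ad_g.update(acc)

        # --- translation moves along the b0 / random-effect ridge ---
        # the likelihood only identifies b0 + mean(effects); shifting b0 by
        # delta and every effect by -delta leaves eta (hence the likelihood)
        # unchanged, so acceptance depends on the priors alone.  Without this
        # move the intercept mixes very slowly.
        for eff, log_s_eff, ad, k in ((alpha, log_sa, ad_ta, n_g),
                                      (gamma, log_sc, ad_tc, n_t)):
            delta = ad.scale * rng.standard_normal(b0.shape)
            s2 = np.exp(2 * log_s_eff)
            b0_p = b0 + delta
            d = (-0.5 * isd2 * (b0_p**2 - b0**2)
                 - 0.5 * ((eff - delta[..., None])**2 - eff**2).sum(axis=-1) / s2)
            acc = np.log(rng.random(b0.shape)) < d
            b0 = np.where(acc, b0_p, b0)
            eff -= np.where(acc, delta, 0.0)[..., None]
            if adapting:
                ad.update(acc)

        # --- random-effect SDs (sampled on the log scale; the Jacobian adds
        #     +log sigma to the target) ---
        a2 = (alpha**2).sum(axis=-1)
        for log_s, ad, ssq, k in ((log_sa, ad_sa, a2, n_g),
                                  (log_sc, ad_sc, (gamma**2).sum(axis=-1), n_t)):
            prop = log_s + ad.scale * rng.standard_normal(log_s.shape)
            def _logpost(ls, ssq=ssq, k=k):
                s2 = np.exp(2 * ls)
                return (-k * ls - 0.5 * ssq / s2       # N(0, s^2) on effects
                        - 0.5 * s2 / sig2              # HalfNormal prior
                        + ls)                          # Jacobian
            d = _logpost(prop) - _logpost(log_s)
            acc = np.log(rng.random(log_s.shape)) < d
            np.copyto(log_s, np.where(acc, prop, log_s))
            if adapting:
                ad.update(acc)

        if not adapting:
            j = it - spec.warmup
            draws_b0[:, j] = b0
            sa_sum += np.exp(log_sa)
            sc_sum += np.exp(log_sc)

    return draws_b0, sa_sum / spec.draws, sc_sum / spec.draws


def _prepare_arrays(obs: pd.DataFrame):
    """Pool replicates within (snp, hybrid, density) and build dense arrays."""
    pooled = (obs.groupby(["snp_id", "hybrid_id", "density"], sort=True)
              [["alt_count", "total_count"]].sum().reset_index())
    snps = np.sort(pooled["snp_id"].unique())
    hybrids = np.sort(pooled["hybrid_id"].unique())
    densities = np.sort(pooled["density"].unique())
    si = pd.Index(snps).get_indexer(pooled["snp_id"])
    gi = pd.Index(hybrids).get_indexer(pooled["hybrid_id"])
    ti = pd.Index(densities).get_indexer(pooled["density"])
    alt = np.zeros((len(snps), len(hybrids), len(densities)))
    tot = np.zeros_like(alt)
    alt[si, gi, ti] = pooled["alt_count"].to_numpy(float)
    tot[si, gi, ti] = pooled["total_count"].to_numpy(float)
    return snps, hybrids, densities, alt, tot, pooled


def fit_ase_population(obs: pd.DataFrame, spec: ASEModelSpec | None = None,
                       null_ratio: float | None = None) -> pd.DataFrame:
    """Fit the binomial GLMM to every SNP and test against the median null.

    Parameters
    ----------
    obs
        Filtered observation table (``snp_id, hybrid_id, density, alt_count,
        total_count``); replicates within a (hybrid, density) cell are summed
        before modelling.
    spec
        Priors and sampler settings (defaults: see :class:`ASEModelSpec`).
    null_ratio
        The null hypothesis m; by default the median ratio of ``obs``.

    Returns
    -------
    One row per SNP with the posterior mean ASE ratio (invlogit of b0),
    97.5% credible interval, two-sided posterior p-value about m, BH FDR
    over the converged SNPs, and a ``significant`` flag at the spec's FDR
    level.  SNPs whose split-R-hat on b0 exceeds the threshold are flagged
    unconverged and excluded from the BH family.
    """
    if obs.empty:
        raise ValueError("no observations to fit")
    spec = spec or ASEModelSpec()
    m = compute_null_ratio(obs) if null_ratio is None else float(null_ratio)

    snps, hybrids, densities, alt, tot, pooled = _prepare_arrays(obs)
    logger.info("fitting %d SNPs x %d hybrids x %d densities (null m=%.4f)",
                len(snps), len(hybrids), len(densities), m)
    draws_b0, sa_mean, sc_mean = _run_sampler(alt, tot, spec)

    ratios = 1.0 / (1.0 + np.exp(-draws_b0))           # (chains, draws, S)
    flat = ratios.reshape(-1, len(snps))
    post_mean = flat.mean(axis=0)
    lo_q = (1.0 - spec.ci_level) / 2.0
    ci_low = np.quantile(flat, lo_q, axis=0)
    ci_high = np.quantile(flat, 1.0 - lo_q, axis=0)
    p_below = (flat < m).mean(axis=0)
    post_p = np.minimum(1.0, 2.0 * np.minimum(p_below, 1.0 - p_below))
    rhat = _split_rhat(draws_b0)
    converged = rhat <= spec.rhat_threshold

    n_hyb = pooled.groupby("snp_id")["hybrid_id"].nunique().reindex(snps).to_numpy()
    fits = pd.DataFrame({
        "snp_id": snps,
        "n_hybrids": n_hyb,
        "ase_ratio": post_mean,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "post_p": post_p,
        "rhat": rhat,
        "converged": converged,
        "sigma_genotype": sa_mean.mean(axis=0),
        "sigma_treatment": sc_mean.mean(axis=0),
        "null_ratio": m,
    })
    fits["fdr"] = np.nan
    if converged.any():
        fits.loc[converged, "fdr"] = bh_fdr(fits.loc[converged, "post_p"])
    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("%d SNP(s) failed convergence (split-R-hat > %.2f) and "
                       "were excluded from FDR control", n_bad, spec.rhat_threshold)
    fits["significant"] = fits["fdr"] < spec.fdr_level
    return fits


def fit_ase_glmm(obs_one_snp: pd.DataFrame, spec: ASEModelSpec | None = None,
                 null_ratio: float = 0.5) -> pd.Series:
    """Fit a single SNP (convenience wrapper around the joint fitter)."""
    fits = fit_ase_population(obs_one_snp, spec=spec, null_ratio=null_ratio)
    if len(fits) != 1:
        raise ValueError("expected observations for exactly one SNP")
    return fits.iloc[0]


def summarize_ase(fits: pd.DataFrame, snp_to_gene: pd.Series | None = None,
                  alt_freq: pd.Series | None = None,
                  maf_cut: float = 0.1) -> dict:
    """Dataset-level ASE summary (counts, proportions, frequency trends).

    Reports the number and percentage of significant SNPs, the genes covered
    and the genes with at least one significant SNP, and — when alternative-
    allele frequencies are supplied — the MAF-stratified significant
    proportions with their fold ratio and the correlation of the ASE ratio
    with allele frequency separately for significant and non-significant
    SNPs.
    """
    from hybridexpr.stats import correlate

    out: dict = {"n_snps": int(len(fits))}
    sig = fits["significant"].fillna(False).astype(bool)
    out["n_significant"] = int(sig.sum())
    out["pct_significant"] = (100.0 * out["n_significant"] / out["n_snps"]
                              if out["n_snps"] else 0.0)
    if snp_to_gene is not None:
        genes = snp_to_gene.reindex(fits["snp_id"])
        covered = genes.dropna().unique()
        sig_genes = genes[sig.to_numpy()].dropna().unique()
        out["n_genes_covered"] = int(len(covered))
        out["n_genes_significant"] = int(len(sig_genes))
        out["pct_genes_significant"] = (100.0 * len(sig_genes) / len(covered)
                                        if len(covered) else 0.0)
    if alt_freq is not None:
        freq = alt_freq.reindex(fits["snp_id"]).to_numpy(float)
        maf = np.minimum(freq, 1.0 - freq)
        low = maf < maf_cut
        with np.errstate(invalid="ignore"):
            p_low = float(sig[low].mean()) if low.any() else np.nan
            p_common = float(sig[~low].mean()) if (~low).any() else np.nan
        out["pct_significant_low_maf"] = 100.0 * p_low
        out["pct_significant_common"] = 100.0 * p_common
        out["maf_fold_ratio"] = (p_low / p_common if p_common else np.nan)
        for label, mask in (("significant", sig.to_numpy()),
                            ("nonsignificant", ~sig.to_numpy())):
            if mask.sum() >= 3:
                try:
                    r, p, _ = correlate(fits["ase_ratio"].to_numpy()[mask],
                                        freq[mask])
                except ValueError:
                    continue  # degenerate ratios/frequencies: skip
                out[f"r_ratio_vs_freq_{label}"] = r
                out[f"p_ratio_vs_freq_{label}"] = p
    return out
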