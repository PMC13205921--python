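"""Synthetic trio / expression / phenotype data with known ground truth.

The generator emulates a panel of single-cross hybrids and their parental
inbred lines grown under two planting densities and sampled at three
developmental stages with replicated RNA-seq, producing every input the
analysis modules consume:

* trio genotype tables with informative, uninformative, parent-
  heterozygous, conflicting and missing sites at configurable rates;
* per-SNP allele-specific read counts drawn from the binomial logit model
  with genotype and treatment random effects;
* gene expression count/FPKM matrices with planted inheritance modes
  (mid-parent additive, dominant, overdominant), single-parent-expressed
  genes and their hybrid complementation, and density/role effects;
* variant-effect annotations (high-effect categories, GERP RS scores,
  CDS vs 2-kb-upstream regions) with planted complementation and
  suppression structure;
* phenotypes with release years and a planted correlation between
  transcriptomic entropy reduction and heterosis through a shared latent
  factor.

Every planted quantity is recorded in truth tables so parameter-recovery
tests can check the estimators.  A fixed seed regenerates byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "simulate_trios",
    "simulate_allele_counts",
    "simulate_expression",
    "simulate_phenotypes_and_annotations",
    "simulate_all",
]

HIGH_EFFECTS = ("frameshift", "stop_gained", "splice_acceptor", "splice_donor",
                "gene_fusion", "exon_loss", "start_lost", "stop_lost",
                "transcript_ablation")


@dataclass
class SimulationConfig:
    """All generator knobs; defaults mirror the emulated study design.

    Twenty hybrids, three replicates, stages V4/V10/VT and high/low
    planting density reproduce the field design; random-effect SDs are on
    the logit scale; ``mean_depth`` is the mean total read count per SNP
    per sample with NB dispersion ``nb_dispersion``; ``inheritance_mix``
    gives the planted proportions of additive / dominant / overdominant
    genes among parental-DE genes.
    """

    n_hybrids: int = 20
    n_snps: int = 300
    n_genes: int = 400
    stages: tuple = ("V4", "V10", "VT")
    densities: tuple = ("HPD", "LPD")
    n_replicates: int = 3
    seed: int = 0

    # --- trio genotype case rates ---
    frac_informative: float = 0.70
    frac_uninformative: float = 0.15
    frac_parent_het: float = 0.08
    frac_conflict: float = 0.04
    frac_missing: float = 0.03

    # --- allele counts (binomial logit model) ---
    ase_effect_sd: float = 0.25      # sigma of genotype random effect
    density_effect_sd: float = 0.10  # sigma of treatment random effect
    beta0_mean: float = 0.0          # logit-scale intercept distribution
    beta0_sd: float = 0.8
    mean_depth: int = 100
    nb_dispersion: float = 0.3       # depth NB dispersion (var = m + d m^2)

    # --- expression matrix ---
    mean_expression: float = 100.0   # scale of per-gene NB count means
    expr_log2_sd: float = 1.5        # spread of gene base means (log2)
    expr_dispersion: float = 0.05
    frac_parental_de: float = 0.40
    parental_lfc_range: tuple = (1.2, 3.0)
    frac_spe: float = 0.03
    frac_ce_given_spe: float = 0.57
    frac_density_de: float = 0.10
    frac_role_de: float = 0.10
    stage_effect_sd: float = 0.05    # mild per-stage log2 wobble
    library_size_jitter: float = 0.2
    # hybrid profile sharpening must outweigh the entropy-raising effect of
    # mid-parent averaging on DE genes for the planted reduction to be real
    entropy_sharpening_range: tuple = (1.3, 1.7)
    inheritance_mix: dict = field(default_factory=lambda: {
        "additive": 0.55, "dominantHP": 0.19, "dominantLP": 0.23,
        "overdominantAHP": 0.014, "overdominantBLP": 0.016})

    # --- deleterious load / annotations ---
    frac_deleterious: float = 0.08
    frac_suppressed: float = 0.53
    suppressed_fraction_functional: float = 0.85
    gerp_cis_year_r: float = 0.6
    gerp_cds_year_r: float = 0.0
    gerp_mean_count: float = 30.0
    gerp_count_sd: float = 8.0

    # --- phenotypes ---
    release_year_range: tuple = (1960, 2010)
    entropy_heterosis_r: float = 0.5
    trait: str = "GYPP"
    percent_heterosis_mean: float = 0.60
    trait_gain_per_year: float = 0.5

    def __post_init__(self):
        fracs = {
            "frac_informative": self.frac_informative,
            "frac_uninformative": self.frac_uninformative,
            "frac_parent_het": self.frac_parent_het,
            "frac_conflict": self.frac_conflict,
            "frac_missing": self.frac_missing,
            "frac_parental_de": self.frac_parental_de,
            "frac_spe": self.frac_spe,
            "frac_ce_given_spe": self.frac_ce_given_spe,
            "frac_density_de": self.frac_density_de,
            "frac_role_de": self.frac_role_de,
            "frac_deleterious": self.frac_deleterious,
            "frac_suppressed": self.frac_suppressed,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        case_sum = (self.frac_informative + self.frac_uninformative
                    + self.frac_parent_het + self.frac_conflict
                    + self.frac_missing)
        if abs(case_sum - 1.0) > 1e-9:
            raise ValueError(f"trio case fractions sum to {case_sum}, not 1")
        mix_sum = sum(self.inheritance_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ValueError(f"inheritance_mix sums to {mix_sum}, not 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if abs(self.entropy_heterosis_r) > 1:
            raise ValueError("entropy_heterosis_r must lie in [-1, 1]")

    def hybrid_ids(self):
        return [f"HYB{i + 1:02d}" for i in range(self.n_hybrids)]

    def parent_ids(self, hybrid_id):
        return f"F_{hybrid_id}", f"M_{hybrid_id}"

    def rng_for(self, component: str) -> np.random.Generator:
        """Independent deterministic stream per generator component."""
        offsets = {"trios": 1, "counts": 2, "expression": 3, "phenotypes": 4}
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, offsets[component]]))


def _nb_draw(rng, mean, dispersion, size):
    """NB counts with var = mean + dispersion * mean^2 (Poisson at d=0)."""
    mean = np.broadcast_to(np.asarray(mean, float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    k = 1.0 / dispersion
    return rng.poisson(rng.gamma(k, mean / k))


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def simulate_trios(config: SimulationConfig):
    """Trio genotype table over all hybrids plus per-site truth.

    Each (SNP, hybrid) pair is drawn one of five cases at the configured
    rates: informative (opposite parental homozygotes, hybrid het, known
    phase), uninformative (same homozygotes), parent-heterozygous,
    conflicting (same homozygotes but het hybrid) or missing.
    """
    if config.n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = config.rng_for("trios")
    cases = np.array(["informative", "uninformative", "parent_het",
                      "conflict", "missing"])
    probs = np.array([config.frac_informative, config.frac_uninformative,
                      config.frac_parent_het, config.frac_conflict,
                      config.frac_missing])
    snp_ids = [f"snp{i + 1:05d}" for i in range(config.n_snps)]
    positions = np.sort(rng.choice(np.arange(1, 50_000_001),
                                   size=config.n_snps, replace=False))
    recs, truth = [], []
    for hyb in config.hybrid_ids():
        case_idx = rng.choice(len(cases), size=config.n_snps, p=probs)
        flips = rng.random(config.n_snps) < 0.5
        aux = rng.random(config.n_snps)
        for i, snp in enumerate(snp_ids):
            case = cases[case_idx[i]]
            flip = flips[i]
            if case == "informative":
                f, m, h = ("0/0", "1/1", "0/1") if not flip else \
                          ("1/1", "0/0", "0/1")
                phase = "0|1" if not flip else "1|0"
            elif case == "uninformative":
                gt = "0/0" if not flip else "1/1"
                f, m, h, phase = gt, gt, gt, "none"
            elif case == "parent_het":
                hom = "0/0" if not flip else "1/1"
                f, m = ("0/1", hom) if aux[i] < 0.5 else (hom, "0/1")
                h, phase = "0/1", "none"
            elif case == "conflict":
                gt = "0/0" if not flip else "1/1"
                f, m, h, phase = gt, gt, "0/1", "none"
            else:  # missing
                f, m, h = ("0/0", "1/1", "0/1")
                member = int(aux[i] * 3)
                f, m, h = [("./." if j == member else g)
                           for j, g in enumerate((f, m, h))]
                phase = "none"
            recs.append((snp, "chr1", int(positions[i]), hyb, f, m, h))
            truth.append((snp, hyb, case, phase))
    trios = pd.DataFrame(recs, columns=["snp_id", "chrom", "pos", "hybrid_id",
                                        "female_gt", "male_gt", "hybrid_gt"])
    truth = pd.DataFrame(truth, columns=["snp_id", "hybrid_id", "true_case",
                                         "true_phase"])
    return trios, truth


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def simulate_allele_counts(trio_truth: pd.DataFrame, config: SimulationConfig,
                           true_ratios=None):
    """Allele-specific read counts at phased sites plus effect truth.

    Counts are drawn per (SNP, hybrid, density, replicate) for sites the
    hybrid is informative at: total ~ NB(mean_depth, nb_dispersion), alt ~
    Binomial(total, p) with logit(p) = b0_snp + a_hybrid + c_density.
    ``true_ratios`` optionally fixes invlogit(b0) per SNP (array over the
    SNPs present in ``trio_truth``).
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = config.rng_for("counts")
    snp_ids = np.sort(trio_truth["snp_id"].unique())
    n_snps = len(snp_ids)
    if true_ratios is not None:
        true_ratios = np.asarray(true_ratios, float)
        if len(true_ratios) != n_snps:
            raise ValueError("true_ratios length must match SNP count")
        beta0 = np.log(true_ratios / (1.0 - true_ratios))
    else:
        beta0 = rng.normal(config.beta0_mean, config.beta0_sd, n_snps)
    hybrids = config.hybrid_ids()
    alphas = rng.normal(0.0, config.ase_effect_sd, (n_snps, len(hybrids)))
    gammas = rng.normal(0.0, config.density_effect_sd,
                        (n_snps, len(config.densities)))
    snp_idx = pd.Index(snp_ids)
    hyb_idx = pd.Index(hybrids)

    phased = trio_truth.loc[trio_truth["true_phase"].isin(["0|1", "1|0"])]
    recs, effect_truth = [], []
    for row in phased.itertuples(index=False):
        s = snp_idx.get_loc(row.snp_id)
        g = hyb_idx.get_loc(row.hybrid_id)
        for t, dens in enumerate(config.densities):
            eta = beta0[s] + alphas[s, g] + gammas[s, t]
            p = 1.0 / (1.0 + np.exp(-eta))
            totals = _nb_draw(rng, config.mean_depth, config.nb_dispersion,
                              (config.n_replicates,))
            alts = rng.binomial(totals, p)
            for rep in range(config.n_replicates):
                recs.append((row.snp_id, row.hybrid_id, dens, rep + 1,
                             int(totals[rep] - alts[rep]), int(alts[rep]),
                             int(totals[rep])))
        effect_truth.append((row.snp_id, row.hybrid_id, alphas[s, g]))
    counts = pd.DataFrame(recs, columns=["snp_id", "hybrid_id", "density",
                                         "replicate", "ref_count", "alt_count",
                                         "total_count"])
    truth = pd.DataFrame({
        "snp_id": snp_ids,
        "true_beta0": beta0,
        "true_ase_ratio": 1.0 / (1.0 + np.exp(-beta0)),
    })
    effects = pd.DataFrame(effect_truth,
                           columns=["snp_id", "hybrid_id", "true_alpha"])
    gamma_truth = pd.DataFrame({
        "snp_id": np.repeat(snp_ids, len(config.densities)),
        "density": list(config.densities) * n_snps,
        "true_gamma": gammas.ravel(),
    })
    return counts, truth, effects, gamma_truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _plant_modes(rng, config, n_de):
    modes = list(config.inheritance_mix)
    probs = np.array([config.inheritance_mix[m] for m in modes])
    return rng.choice(modes, size=n_de, p=probs / probs.sum())


def simulate_expression(config: SimulationConfig):
    """Counts + FPKM matrices, sample metadata, gene info and truth.

    Per gene, parental means follow a lognormal base level; parental-DE
    genes split the fold change symmetrically between the parents and the
    hybrid mean follows the planted mode (mid-parent, either parent, or
    1.6x the high / 0.5x the low parent for overdominance).  SPE genes set
    the silent parent's mean effectively to zero; a planted fraction of
    them stays expressed in the hybrid (CE).  Density and hybrid/inbred
    effects are planted on disjoint gene subsets; hybrid profiles are mildly
    sharpened (power > 1, renormalised) so hybrids have lower transcriptomic
    entropy.  FPKM is computed from counts with fixed gene lengths and
    jittered library sizes.
    """
    rng = config.rng_for("expression")
    n_genes = config.n_genes
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    lengths = rng.integers(500, 5001, n_genes)
    base = config.mean_expression * 2.0 ** rng.normal(
        0.0, config.expr_log2_sd, n_genes)

    # disjoint planting classes
    classes = rng.choice(
        ["spe", "parental_de", "flat"], size=n_genes,
        p=[config.frac_spe, config.frac_parental_de,
           1.0 - config.frac_spe - config.frac_parental_de])
    is_spe = classes == "spe"
    is_de = classes == "parental_de"
    lfc = np.zeros(n_genes)
    lo, hi = config.parental_lfc_range
    lfc[is_de] = (rng.uniform(lo, hi, is_de.sum())
                  * rng.choice([-1.0, 1.0], is_de.sum()))
    modes = np.array(["none"] * n_genes, dtype=object)
    modes[is_de] = _plant_modes(rng, config, int(is_de.sum()))
    # below-low-parent overdominance (D/A = -2.5) needs the low parent well
    # above zero, so its parental fold change is capped
    blp = modes == "overdominantBLP"
    lfc[blp] = np.clip(lfc[blp], -1.1, 1.1)
    spe_silent_female = rng.random(n_genes) < 0.5
    spe_ce = is_spe & (rng.random(n_genes) < config.frac_ce_given_spe)

    dens_de = rng.random(n_genes) < config.frac_density_de
    dens_lfc = np.where(dens_de, rng.uniform(1.0, 2.0, n_genes)
                        * rng.choice([-1.0, 1.0], n_genes), 0.0)
    role_de = (classes == "flat") & (rng.random(n_genes) < config.frac_role_de)
    role_lfc = np.where(role_de, rng.uniform(1.0, 2.0, n_genes)
                        * rng.choice([-1.0, 1.0], n_genes), 0.0)
    stage_eff = rng.normal(0.0, config.stage_effect_sd,
                           (n_genes, len(config.stages)))

    # per-genotype baseline means
    half = 2.0 ** (lfc / 2.0)
    mu_f = base / half          # female parent
    mu_m = base * half          # male parent
    mu_f[is_spe & spe_silent_female] = 0.0
    mu_m[is_spe & spe_silent_female] = base[is_spe & spe_silent_female]
    mu_m[is_spe & ~spe_silent_female] = 0.0
    mu_f[is_spe & ~spe_silent_female] = base[is_spe & ~spe_silent_female]

    mid = 0.5 * (mu_f + mu_m)
    hi_p = np.maximum(mu_f, mu_m)
    lo_p = np.minimum(mu_f, mu_m)
    mu_h = mid.copy()
    mu_h[modes == "dominantHP"] = hi_p[modes == "dominantHP"]
    mu_h[modes == "dominantLP"] = lo_p[modes == "dominantLP"]
    # overdominants are planted directly in D/A space (F1 = mid +/- 2.5 x
    # the additive half-range) so the planted category is unambiguous
    ahp = modes == "overdominantAHP"
    mu_h[ahp] = mid[ahp] + 2.5 * (hi_p[ahp] - mid[ahp])
    mu_h[blp] = np.maximum(mid[blp] - 2.5 * (mid[blp] - lo_p[blp]),
                           0.02 * lo_p[blp])
    mu_h[is_spe] = np.where(spe_ce[is_spe], 0.5 * hi_p[is_spe], 0.0)

    sharpen = rng.uniform(*config.entropy_sharpening_range, config.n_hybrids)

    samples, meta_rows = [], []
    count_cols = {}
    s_lo, s_hi = 1.0 - config.library_size_jitter, 1.0 + config.library_size_jitter
    for h_i, hyb in enumerate(config.hybrid_ids()):
        fem, mal = config.parent_ids(hyb)
        mu_h_g = mu_h.copy()
        # sharpen the hybrid profile on the unplanted gene class only
        # (power > 1 then renormalise the class total), so planted
        # inheritance modes and SPE levels stay exact
        pos = (classes == "flat") & (mu_h_g > 0.01)
        sharpened = mu_h_g[pos] ** sharpen[h_i]
        sharpened *= mu_h_g[pos].sum() / sharpened.sum()
        mu_h_g[pos] = sharpened
        for geno, role, mu_g in ((hyb, "hybrid", mu_h_g),
                                 (fem, "female", mu_f),
                                 (mal, "male", mu_m)):
            role_mult = 2.0 ** role_lfc if role == "hybrid" else 1.0
            for s_i, stage in enumerate(config.stages):
                stage_mult = 2.0 ** stage_eff[:, s_i]
                for dens in config.densities:
                    dens_mult = 2.0 ** dens_lfc if dens == config.densities[0] else 1.0
                    for rep in range(1, config.n_replicates + 1):
                        lib = rng.uniform(s_lo, s_hi)
                        mu = mu_g * stage_mult * dens_mult * role_mult * lib
                        y = _nb_draw(rng, mu, config.expr_dispersion, (n_genes,))
                        name = f"{geno}.{stage}.{dens}.r{rep}"
                        count_cols[name] = y
                        meta_rows.append((name, geno, role, stage, dens, rep))
    counts = pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "genotype_id", "role",
                                            "stage", "density", "replicate"]
                        ).set_index("sample_id")
    totals = counts.sum(axis=0).astype(float)
    fpkm = counts.div(lengths / 1000.0, axis=0).div(totals / 1e6, axis=1)

    gene_info = pd.DataFrame({"gene_id": gene_ids, "length": lengths}
                             ).set_index("gene_id")
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "true_class": classes,
        "true_mode": modes,
        "true_parental_log2fc": lfc,
        "true_spe": is_spe,
        "true_spe_silent_parent": np.where(
            is_spe, np.where(spe_silent_female, "female", "male"), "none"),
        "true_ce": spe_ce,
        "true_density_log2fc": dens_lfc,
        "true_role_log2fc": role_lfc,
    }).set_index("gene_id")
    sharpen_truth = pd.DataFrame({"hybrid_id": config.hybrid_ids(),
                                  "true_sharpening": sharpen})
    return counts, fpkm, meta, gene_info, truth, sharpen_truth


# ---------------------------------------------------------------------------
# phenotypes + annotations
# ---------------------------------------------------------------------------

def simulate_phenotypes_and_annotations(config: SimulationConfig):
    """Phenotypes, release years, variant annotations and planted structure.

    Heterosis for the default trait is tied to a per-hybrid latent factor
    shared with the planted entropy reduction so their correlation equals
    ``entropy_heterosis_r`` in expectation.  Complemented GERP-constrained
    variant counts in cis-regulatory regions are planted to correlate with
    release year at ``gerp_cis_year_r`` (CDS counts at ``gerp_cds_year_r``).
    Deleterious genes carry a high-effect CDS variant in exactly one parent;
    a planted fraction of the resulting complementary pairs is suppressed
    in the gene-level haplotype counts.
    """
    rng = config.rng_for("phenotypes")
    hybrids = config.hybrid_ids()
    n = config.n_hybrids
    y_lo, y_hi = config.release_year_range
    if y_hi - y_lo < 1:
        raise ValueError("release year span must cover >= 2 years")
    years = np.sort(rng.integers(y_lo, y_hi + 1, n))

    # shared latent factor -> entropy reduction and heterosis
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    r = config.entropy_heterosis_r
    dh = 0.30 + 0.15 * z
    het_score = r * z + np.sqrt(max(0.0, 1.0 - r**2)) * eps

    year_z = (years - years.mean()) / max(years.std(), 1e-9)
    mid_parent = 100.0 + config.trait_gain_per_year * (years - years.mean()) \
        + rng.normal(0.0, 5.0, n)
    absolute_het = config.percent_heterosis_mean * mid_parent \
        * (1.0 + 0.25 * het_score)
    f1 = mid_parent + absolute_het
    parent_split = rng.normal(0.0, 6.0, n)

    pheno_rows, truth_rows = [], []
    for i, hyb in enumerate(hybrids):
        fem, mal = config.parent_ids(hyb)
        for dens in config.densities:
            noise = rng.normal(0.0, 1.0, 3)
            pheno_rows += [
                (hyb, "hybrid", config.trait, dens, f1[i] + noise[0], years[i]),
                (fem, "female", config.trait, dens,
                 mid_parent[i] + parent_split[i] + noise[1], np.nan),
                (mal, "male", config.trait, dens,
                 mid_parent[i] - parent_split[i] + noise[2], np.nan),
            ]
        truth_rows.append((hyb, years[i], dh[i], absolute_het[i], z[i]))
    phenotypes = pd.DataFrame(pheno_rows, columns=[
        "genotype_id", "role", "trait", "density", "value", "release_year"])
    pheno_truth = pd.DataFrame(truth_rows, columns=[
        "hybrid_id", "release_year", "true_entropy_reduction",
        "true_absolute_heterosis", "latent_factor"])

    # --- deleterious genes and complementary pairs ---
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    n_dele = int(round(config.frac_deleterious * config.n_genes))
    dele_genes = list(rng.choice(gene_ids, size=n_dele, replace=False))
    ann_rows, carrier_rows, hap_rows, pair_truth = [], [], [], []
    vid = 0
    for gene in dele_genes:
        vid += 1
        variant = f"var{vid:06d}"
        effect = HIGH_EFFECTS[rng.integers(len(HIGH_EFFECTS))]
        ann_rows.append((variant, gene, effect, "high",
                         float(rng.uniform(2.5, 6.0)), "CDS"))
        # carried by one parent of every hybrid (same side per gene);
        # suppression is drawn per complementary pair (gene x hybrid)
        female_side = rng.random() < 0.5
        for hyb in hybrids:
            fem, mal = config.parent_ids(hyb)
            carrier_rows.append((variant, fem if female_side else mal))
            suppressed = rng.random() < config.frac_suppressed
            p_func = config.suppressed_fraction_functional if suppressed else 0.5
            for dens in config.densities:
                for rep in range(1, config.n_replicates + 1):
                    total = int(_nb_draw(rng, 150.0, 0.1, (1,))[0])
                    func = rng.binomial(total, p_func)
                    dele_c = total - func
                    mat, pat = (dele_c, func) if female_side else (func, dele_c)
                    hap_rows.append((gene, hyb, dens, rep, mat, pat))
            pair_truth.append((gene, hyb,
                               "female" if female_side else "male", suppressed))

    # --- GERP-constrained variants with planted year trends ---
    # the target correlation is planted exactly in-sample (noise is
    # orthogonalised against the year vector before mixing), so recovery
    # deviates from the target only through integer rounding
    def planted_counts(r_target):
        noise = rng.standard_normal(n)
        noise = noise - noise.mean()
        noise -= year_z * (noise @ year_z) / (year_z @ year_z)
        noise /= max(noise.std(), 1e-12)
        yz = year_z / max(year_z.std(), 1e-12)
        score = r_target * yz + np.sqrt(max(0.0, 1.0 - r_target**2)) * noise
        return np.maximum(
            0, np.round(config.gerp_mean_count + config.gerp_count_sd * score)
        ).astype(int)

    cis_counts = planted_counts(config.gerp_cis_year_r)
    cds_counts = planted_counts(config.gerp_cds_year_r)
    for i, hyb in enumerate(hybrids):
        fem, mal = config.parent_ids(hyb)
        for region, count in (("cis_upstream_2kb", cis_counts[i]),
                              ("CDS", cds_counts[i])):
            for _ in range(count):
                vid += 1
                variant = f"var{vid:06d}"
                gene = gene_ids[rng.integers(config.n_genes)]
                ann_rows.append((variant, gene, "other", "modifier",
                                 float(rng.uniform(2.1, 6.0)), region))
                carrier_rows.append((variant, fem if rng.random() < 0.5 else mal))

    annotations = pd.DataFrame(ann_rows, columns=[
        "variant_id", "gene_id", "effect_category", "impact", "gerp_rs",
        "region"])
    carriers = pd.DataFrame(carrier_rows, columns=["variant_id", "genotype_id"])
    hap_counts = pd.DataFrame(hap_rows, columns=[
        "gene_id", "hybrid_id", "density", "replicate", "maternal_count",
        "paternal_count"])
    pair_truth = pd.DataFrame(pair_truth, columns=[
        "gene_id", "hybrid_id", "true_deleterious_parent", "true_suppressed"])
    gerp_truth = pd.DataFrame({
        "hybrid_id": hybrids, "release_year": years,
        "true_cis_count": cis_counts, "true_cds_count": cds_counts})
    return {
        "phenotypes": phenotypes,
        "phenotype_truth": pheno_truth,
        "annotations": annotations,
        "carriers": carriers,
        "deleterious_hap_counts": hap_counts,
        "pair_truth": pair_truth,
        "gerp_truth": gerp_truth,
    }


# ---------------------------------------------------------------------------
# orchestration and file output
# ---------------------------------------------------------------------------

def _write_vcf(trios: pd.DataFrame, truth: pd.DataFrame, config,
               path: Path) -> None:
    """Minimal VCF with one sample column per line; hybrid GTs phased."""
    phased = truth.set_index(["snp_id", "hybrid_id"])["true_phase"]
    samples = []
    for hyb in config.hybrid_ids():
        fem, mal = config.parent_ids(hyb)
        samples += [fem, mal, hyb]
    gts = {}
    sites = trios.drop_duplicates("snp_id")[["snp_id", "chrom", "pos"]]
    wide = trios.set_index(["snp_id", "hybrid_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for site in sites.itertuples(index=False):
            fields = [site.chrom, str(site.pos), site.snp_id, "A", "G", ".",
                      "PASS", ".", "GT"]
            for hyb in config.hybrid_ids():
                row = wide.loc[(site.snp_id, hyb)]
                ph = phased.get((site.snp_id, hyb), "none")
                hyb_gt = ph if ph in ("0|1", "1|0") else row["hybrid_gt"]
                fields += [row["female_gt"], row["male_gt"], hyb_gt]
            fh.write("\t".join(fields) + "\n")


def simulate_all(config: SimulationConfig, outdir: str | Path | None = None
                 ) -> dict:
    """Run every generator component; optionally write all files.

    Returns a dict of DataFrames (inputs and truth tables).  When
    ``outdir`` is given, inputs are written as TSV (plus a minimal VCF for
    the genotypes and the config as YAML) and truth tables under
    ``truth_*`` names; a fixed seed gives byte-identical files.
    """
    trios, trio_truth = simulate_trios(config)
    counts, ase_truth, alpha_truth, gamma_truth = simulate_allele_counts(
        trio_truth, config)
    (expr_counts, fpkm, meta, gene_info, expr_truth,
     sharpen_truth) = simulate_expression(config)
    pheno = simulate_phenotypes_and_annotations(config)

    manifest = pd.DataFrame(
        [(h, *config.parent_ids(h)) for h in config.hybrid_ids()],
        columns=["hybrid_id", "female_id", "male_id"])
    snp_to_gene = pd.DataFrame({
        "snp_id": sorted(trios["snp_id"].unique()),
        "gene_id": [f"gene{(i % config.n_genes) + 1:05d}"
                    for i in range(trios["snp_id"].nunique())],
    })

    out = {
        "trios": trios, "trio_truth": trio_truth, "manifest": manifest,
        "allele_counts": counts, "ase_truth": ase_truth,
        "alpha_truth": alpha_truth, "gamma_truth": gamma_truth,
        "expr_counts": expr_counts, "fpkm": fpkm, "meta": meta,
        "gene_info": gene_info, "expr_truth": expr_truth,
        "sharpen_truth": sharpen_truth, "snp_to_gene": snp_to_gene,
        **pheno,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "trio_genotypes.tsv": trios,
            "trio_manifest.tsv": manifest,
            "allele_counts.tsv": counts,
            "expression_counts.tsv": expr_counts.reset_index(),
            "expression_fpkm.tsv": fpkm.reset_index(),
            "sample_metadata.tsv": meta.reset_index(),
            "gene_info.tsv": gene_info.reset_index(),
            "snp_to_gene.tsv": snp_to_gene,
            "phenotypes.tsv": pheno["phenotypes"],
            "annotations.tsv": pheno["annotations"],
            "carriers.tsv": pheno["carriers"],
            "deleterious_hap_counts.tsv": pheno["deleterious_hap_counts"],
            "truth_trios.tsv": trio_truth,
            "truth_ase.tsv": ase_truth,
            "truth_ase_alpha.tsv": alpha_truth,
            "truth_ase_gamma.tsv": gamma_truth,
            "truth_expression.tsv": expr_truth.reset_index(),
            "truth_sharpening.tsv": sharpen_truth,
            "truth_phenotypes.tsv": pheno["phenotype_truth"],
            "truth_pairs.tsv": pheno["pair_truth"],
            "truth_gerp.tsv": pheno["gerp_truth"],
        }
        for name, df in tables.items():
            df.to_csv(outdir / name, sep="\t", index=False,
                      float_format="%.10g")
        _write_vcf(trios, trio_truth, config, outdir / "genotypes.vcf")
        cfg = asdict(config)
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in cfg.items()}
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
    return out
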