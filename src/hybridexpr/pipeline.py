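"""End-to-end orchestration: simulate -> phase -> ASE -> inheritance ->
deleterious -> entropy -> heterosis, with a machine-readable manifest.

Every threshold is surfaced on :class:`PipelineConfig`; the defaults
reproduce the analysis thresholds of the emulated study (population DE at
FDR 0.01 with |log2FC| > 1, ASE at FDR 0.05, suppression at FDR 0.05 with
two-fold imbalance, allelic density response at FDR 0.01, SPE cutoffs
0.1 / 1 FPKM, GERP RS > 2, SNPs heterozygous in >= 10 hybrids with >= 10
reads).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from hybridexpr import __version__
from hybridexpr.simulate import SimulationConfig, simulate_all
from hybridexpr.phasing import phase_trio, phase_summary
from hybridexpr.ase_population import (
    ASEModelSpec, compute_null_ratio, filter_ase_snps, fit_ase_population,
    summarize_ase)
from hybridexpr.ase_hybrid import (
    aggregate_haplotype_counts, classify_allelic_response,
    classify_density_consistency, classify_regulatory_pattern,
    test_allelic_imbalance)
from hybridexpr.inheritance import (
    DABands, call_parental_de, call_spe_ce, classify_inheritance,
    fit_multifactor_de)
from hybridexpr.deleterious import (
    call_suppression, find_complementary_pairs, gerp_region_trends,
    identify_deleterious, suppression_proportions)
from hybridexpr.entropy import entropy_heterosis_association, trio_entropy
from hybridexpr.stats import compute_heterosis, genetic_gain

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles, thresholds and paths for an end-to-end run."""

    outdir: str = "hybridexpr_run"
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig | None = None

    # stage toggles
    run_phasing: bool = True
    run_ase_population: bool = True
    run_ase_hybrid: bool = True
    run_inheritance: bool = True
    run_deleterious: bool = True
    run_entropy: bool = True
    run_heterosis: bool = True

    # thresholds (defaults = the study's stated analysis thresholds)
    de_fdr: float = 0.01
    de_lfc: float = 1.0
    ase_fdr: float = 0.05
    ase_min_hybrids: int = 10
    ase_min_total: int = 10
    imbalance_min_total: int = 20
    response_fdr: float = 0.01
    suppression_fdr: float = 0.05
    suppression_min_fold_log2: float = 1.0
    spe_silent_below: float = 0.1
    spe_expressed_above: float = 1.0
    gerp_threshold: float = 2.0
    entropy_min_mean_fpkm: float = 1.0
    da_bands: tuple = (0.25, 0.75, 1.25)

    # sampler settings for the population ASE model
    mcmc_chains: int = 4
    mcmc_draws: int = 1000
    mcmc_warmup: int = 500


def _write(df: pd.DataFrame, outdir: Path, name: str, index=False):
    df.to_csv(outdir / name, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the result tables and report.

    Stage outputs are written under ``config.outdir`` together with a
    ``manifest.yaml`` recording version, seed and thresholds.  A stage
    failure aborts with the stage name; earlier outputs are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    results: dict = {}
    stage = "setup"
    t_start = time.time()
    try:
        stage = "simulate"
        if config.simulate:
            sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
            data = simulate_all(sim_cfg, outdir / "inputs")
        else:
            raise ValueError("file-based input loading requires "
                             "simulate=True or a prepared dataset dict; "
                             "use the per-stage CLI for external files")
        results["data"] = data
        manifest = data["manifest"]

        if config.run_phasing:
            stage = "phasing"
            t0 = time.time()
            phased = phase_trio(data["trios"])
            results["phased"] = phased
            _write(phased, outdir, "phased_genotypes.tsv")
            _write(phase_summary(phased), outdir, "phasing_summary.tsv")
            logger.info("phasing done in %.1fs", time.time() - t0)
            report["phasing"] = phase_summary(phased).to_dict("records")

        if config.run_ase_population:
            stage = "ase_population"
            t0 = time.time()
            obs = filter_ase_snps(data["allele_counts"],
                                  min_hybrids=config.ase_min_hybrids,
                                  min_total=config.ase_min_total)
            if obs.empty:
                report["ase_population"] = {"n_snps": 0}
            else:
                m = compute_null_ratio(obs)
                spec = ASEModelSpec(chains=config.mcmc_chains,
                                    draws=config.mcmc_draws,
                                    warmup=config.mcmc_warmup,
                                    seed=config.seed,
                                    fdr_level=config.ase_fdr)
                fits = fit_ase_population(obs, spec, null_ratio=m)
                results["ase_fits"] = fits
                _write(fits, outdir, "ase_population_fits.tsv")
                summary = summarize_ase(
                    fits, snp_to_gene=data["snp_to_gene"]
                    .set_index("snp_id")["gene_id"])
                summary["null_ratio"] = m
                summary["model"] = ("binomial GLMM, logit(p) = b0 + "
                                    "a_genotype + c_density; posterior "
                                    "two-sided tail probability about the "
                                    "dataset median null")
                report["ase_population"] = summary
            logger.info("ase_population done in %.1fs", time.time() - t0)

        if config.run_ase_hybrid:
            stage = "ase_hybrid"
            t0 = time.time()
            phased = results.get("phased", phase_trio(data["trios"]))
            hap = aggregate_haplotype_counts(
                data["allele_counts"],
                phased.rename(columns={"hybrid_gt": "hybrid_gt"}),
                data["snp_to_gene"])
            results["haplotype_counts"] = hap
            imb = test_allelic_imbalance(hap,
                                         min_total=config.imbalance_min_total,
                                         fdr_level=config.ase_fdr)
            results["imbalance"] = imb
            _write(imb, outdir, "allelic_imbalance.tsv")
            cons = pd.concat([
                classify_density_consistency(imb[imb["hybrid_id"] == h])
                for h in imb["hybrid_id"].unique()
            ], ignore_index=True) if len(imb) else pd.DataFrame()
            results["density_consistency"] = cons
            if len(cons):
                _write(cons, outdir, "density_consistency.tsv")
                report["ase_hybrid"] = (cons["density_consistency"]
                                        .value_counts(normalize=True)
                                        .round(4).to_dict())
            logger.info("ase_hybrid done in %.1fs", time.time() - t0)

        if config.run_inheritance:
            stage = "inheritance"
            t0 = time.time()
            counts, fpkm, meta = (data["expr_counts"], data["fpkm"],
                                  data["meta"])
            de = fit_multifactor_de(counts, meta, fdr=config.de_fdr,
                                    lfc=config.de_lfc)
            results["multifactor_de"] = de
            _write(de, outdir, "multifactor_de.tsv")
            report["multifactor_de"] = (
                de.groupby("contrast")["de"].sum().astype(int).to_dict())

            # per-trio: parental DE, SPE/CE, inheritance in one condition,
            # cis/trans patterns and allele-specific density response
            stage0, dens0 = meta["stage"].iloc[0], meta["density"].iloc[0]
            mode_rows, spe_summary, pattern_rows, response_rows = [], [], [], []
            hap_all = results.get("haplotype_counts")
            bands = DABands(*config.da_bands)
            for t in manifest.itertuples(index=False):
                cell = meta[(meta["stage"] == stage0)
                            & (meta["density"] == dens0)]
                cols = {r: cell.index[cell["genotype_id"] == g]
                        for r, g in (("P1", t.female_id), ("P2", t.male_id),
                                     ("F1", t.hybrid_id))}
                fpkm_means = pd.DataFrame(
                    {r: fpkm[c].mean(axis=1) for r, c in cols.items()})
                spe = call_spe_ce(fpkm_means["P1"], fpkm_means["P2"],
                                  fpkm_means["F1"],
                                  silent_below=config.spe_silent_below,
                                  expressed_above=config.spe_expressed_above)
                spe_summary.append((t.hybrid_id, int(spe["spe"].sum()),
                                    int(spe["ce"].sum())))
                pde = call_parental_de(counts[cols["P1"]], counts[cols["P2"]],
                                       fdr=config.de_fdr).set_index("gene_id")
                de_genes = pde.index[pde["de"]]
                if len(de_genes):
                    inh = classify_inheritance(
                        counts.loc[de_genes, cols["P1"]],
                        counts.loc[de_genes, cols["P2"]],
                        counts.loc[de_genes, cols["F1"]],
                        fpkm_means=fpkm_means.loc[de_genes], bands=bands)
                    inh["hybrid_id"] = t.hybrid_id
                    mode_rows.append(inh.reset_index())
                if hap_all is not None and len(hap_all):
                    hap_h = hap_all[hap_all["hybrid_id"] == t.hybrid_id]
                    pooled = (hap_h.groupby("gene_id")
                              [["maternal_count", "paternal_count"]].sum())
                    for gene in pooled.index.intersection(de_genes):
                        # parental log2FC oriented female/male to match
                        # the maternal/paternal count orientation
                        call = classify_regulatory_pattern(
                            int(pooled.loc[gene, "maternal_count"]),
                            int(pooled.loc[gene, "paternal_count"]),
                            parental_log2fc=-pde.loc[gene, "log2fc"])
                        pattern_rows.append((gene, t.hybrid_id,
                                             call["pattern"],
                                             call["allelic_log2_ratio"]))
                    if len(hap_h):
                        resp = classify_allelic_response(
                            hap_h, fdr_level=config.response_fdr)
                        response_rows.append(resp)
            spe_df = pd.DataFrame(spe_summary,
                                  columns=["hybrid_id", "n_spe", "n_ce"])
            results["spe_summary"] = spe_df
            _write(spe_df, outdir, "spe_ce_summary.tsv")
            if mode_rows:
                inh_all = pd.concat(mode_rows, ignore_index=True)
                results["inheritance"] = inh_all
                _write(inh_all, outdir, "inheritance_calls.tsv")
                report["inheritance_mode_proportions"] = (
                    inh_all["mode"].value_counts(normalize=True)
                    .round(4).to_dict())
            if pattern_rows:
                patterns = pd.DataFrame(pattern_rows, columns=[
                    "gene_id", "hybrid_id", "pattern", "allelic_log2_ratio"])
                results["regulatory_patterns"] = patterns
                _write(patterns, outdir, "regulatory_patterns.tsv")
                report["regulatory_pattern_proportions"] = (
                    patterns["pattern"].value_counts(normalize=True)
                    .round(4).to_dict())
            if response_rows:
                responses = pd.concat(response_rows, ignore_index=True)
                results["allelic_response"] = responses
                _write(responses, outdir, "allelic_response.tsv")
                report["allelic_response_proportions"] = (
                    responses["allelic_response"].value_counts(normalize=True)
                    .round(4).to_dict())
            logger.info("inheritance done in %.1fs", time.time() - t0)

        if config.run_deleterious:
            stage = "deleterious"
            t0 = time.time()
            dele = identify_deleterious(data["annotations"], data["carriers"],
                                        manifest)
            pairs = find_complementary_pairs(data["annotations"],
                                             data["carriers"], manifest)
            supp = call_suppression(
                pairs, data["deleterious_hap_counts"],
                min_fold_log2=config.suppression_min_fold_log2,
                fdr_level=config.suppression_fdr)
            props = suppression_proportions(supp)
            pheno_hyb = (data["phenotypes"]
                         .loc[lambda d: d["role"] == "hybrid"]
                         .groupby("genotype_id")
                         .agg(release_year=("release_year", "first"))
                         .reset_index()
                         .rename(columns={"genotype_id": "hybrid_id"}))
            trends = gerp_region_trends(data["annotations"], data["carriers"],
                                        manifest, pheno_hyb,
                                        gerp_threshold=config.gerp_threshold)
            results.update({"deleterious": dele, "pairs": pairs,
                            "suppression": supp, "gerp_trends": trends})
            _write(dele, outdir, "deleterious_counts.tsv")
            _write(supp, outdir, "suppression_calls.tsv")
            _write(props, outdir, "suppression_proportions.tsv")
            _write(trends, outdir, "gerp_region_trends.tsv")
            report["deleterious"] = {
                "n_complementary_pairs": int(len(pairs)),
                "mean_suppressed_proportion": float(
                    props["proportion_suppressed"].mean()) if len(props) else None,
            }
            logger.info("deleterious done in %.1fs", time.time() - t0)

        if config.run_entropy or config.run_heterosis:
            stage = "heterosis"
            t0 = time.time()
            het = compute_heterosis(data["phenotypes"], manifest)
            results["heterosis"] = het
            _write(het, outdir, "heterosis.tsv")
            hyb_year = (data["phenotypes"]
                        .loc[lambda d: d["role"] == "hybrid"]
                        .groupby("genotype_id")["release_year"].first())
            merged = (het.groupby("hybrid_id")["absolute_heterosis"].mean()
                      .to_frame().join(hyb_year.rename("year")).dropna())
            if len(merged) >= 3 and merged["year"].nunique() >= 2:
                slope, intercept, r2 = genetic_gain(
                    merged["absolute_heterosis"], merged["year"])
                report["genetic_gain_heterosis"] = {
                    "slope": slope, "r_squared": r2}
            logger.info("heterosis done in %.1fs", time.time() - t0)

        if config.run_entropy:
            stage = "entropy"
            t0 = time.time()
            ent_rows = []
            for t in manifest.itertuples(index=False):
                res = trio_entropy(data["fpkm"], data["meta"], t.hybrid_id,
                                   t.female_id, t.male_id,
                                   min_mean_fpkm=config.entropy_min_mean_fpkm)
                ent_rows.append({k: res[k] for k in
                                 ("hybrid_id", "entropy_female", "entropy_male",
                                  "entropy_hybrid", "entropy_reduction",
                                  "n_genes")})
            ent = pd.DataFrame(ent_rows)
            results["entropy"] = ent
            _write(ent, outdir, "entropy_profiles.tsv")
            assoc = entropy_heterosis_association(
                ent.set_index("hybrid_id")["entropy_reduction"],
                results["heterosis"])
            results["entropy_heterosis"] = assoc
            _write(assoc, outdir, "entropy_heterosis.tsv")
            report["entropy"] = {
                "mean_entropy_reduction": float(ent["entropy_reduction"].mean()),
                "heterosis_association": assoc.to_dict("records"),
            }
            logger.info("entropy done in %.1fs", time.time() - t0)

    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest_doc = {
        "version": __version__,
        "seed": config.seed,
        "elapsed_seconds": round(time.time() - t_start, 2),
        "thresholds": {k: v for k, v in asdict(config).items()
                       if isinstance(v, (int, float, str, bool, tuple, list))},
        "notes": [
            "haplotype counts are per-SNP sums over phased sites "
            "(read-level de-duplication is assumed upstream)",
            "posterior p-values are two-sided tail probabilities of the "
            "SNP-level ASE ratio about the dataset median null",
        ],
    }
    manifest_doc["thresholds"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in manifest_doc["thresholds"].items()}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest_doc, fh, sort_keys=True)
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=True)
    results["report"] = report
    return results


def _plain(obj):
    """Recursively convert numpy scalars for YAML output."""
    import numpy as np
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


_SCHEMAS = {
    "allele_counts": ["snp_id", "hybrid_id", "density", "replicate",
                      "ref_count", "alt_count", "total_count"],
    "trio_manifest": ["hybrid_id", "female_id", "male_id"],
    "sample_metadata": ["sample_id", "genotype_id", "role", "stage",
                        "density", "replicate"],
    "phenotypes": ["genotype_id", "role", "trait", "density", "value"],
    "annotations": ["variant_id", "gene_id", "effect_category", "impact",
                    "gerp_rs", "region"],
    "snp_to_gene": ["snp_id", "gene_id"],
}


def validate_inputs(paths: dict) -> list[str]:
    """Schema-check input TSVs; returns an itemised violation list.

    ``paths`` maps schema names (see keys of the module-level registry) to
    file paths.  Unknown schema names and missing required columns are
    reported; an empty list means all inputs validate.
    """
    violations = []
    for name, path in paths.items():
        if name not in _SCHEMAS:
            violations.append(f"{name}: unknown input kind")
            continue
        p = Path(path)
        if not p.exists():
            violations.append(f"{name}: file not found: {p}")
            continue
        header = pd.read_csv(p, sep="\t", nrows=0).columns
        missing = [c for c in _SCHEMAS[name] if c not in header]
        if missing:
            violations.append(f"{name}: missing column(s) {missing} in {p}")
        else:
            n = sum(1 for _ in open(p)) - 1
            logger.info("%s: %d rows, %d columns", name, n, len(header))
    return violations
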