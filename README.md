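# hybridexpr

Allelic expression dynamics in F1 hybrid / parent trios: trio-based
phasing, Bayesian allele-specific expression, cis/trans regulatory
classification, expression-inheritance modes, deleterious-allele
suppression, and transcriptomic entropy — the computational chain used to
study how modern hybrid breeding reshapes gene and allele expression in
crops such as maize.

## Who this is for

Quantitative geneticists and computational biologists analysing RNA-seq of
single-cross hybrids together with their two inbred parents, across
treatments (e.g. planting densities) and developmental stages, who want a
tested, scriptable implementation of the standard trio analyses plus a
synthetic-data generator with known ground truth for validating every
stage at desk scale.

## What it computes

**Trio phasing.** At sites where the parents are opposite homozygotes the
hybrid's alleles are trivially assignable: `0|1` when the female parent is
`0/0` and the male `1/1`, `1|0` for the reverse. Sites heterozygous in a
parent, Mendelian-inconsistent sites, and uninformative sites are filtered
with labelled reasons.

**Population ASE.** For each genic SNP heterozygous in at least 10 hybrids
(≥ 10 reads), the alternative-allele count is modelled with a Bayesian
binomial mixed model

```
alt_gt ~ Binomial(total_gt, p_gt),   logit(p_gt) = β₀ + α_g + γ_t
```

with random effects of genotype (hybrid) `α_g ~ N(0, σ_α²)` and treatment
`γ_t ~ N(0, σ_γ²)`. The SNP's allelic bias is the posterior of
`invlogit(β₀)`; it is tested two-sidedly against the dataset-median null
ratio *m* (not 0.5 — global reference bias shifts the whole panel), with
Benjamini–Hochberg FDR control at 0.05.

**Per-hybrid haplotype ASE.** Phased per-SNP counts are summed to
gene-level maternal/paternal counts, tested with exact binomial tests, and
combined with parental differential expression to classify regulation:
*trans*-only (equal alleles despite parental DE), *cis*-only (allelic ratio
equals the parental fold change), *cis* + *trans* (same/opposite
direction), or unexpected (allelic bias opposing the parental direction),
via BIC over binomial likelihoods. Allele-specific responses to density
stress are classified as same-direction / opposite / female- or
male-specific.

**Expression inheritance.** Negative-binomial GLMs (log link, median-of-
ratios size factors, df-corrected gene-wise dispersion) drive multifactor
population DE (`~ stage + hybrid/inbred + density + interaction`; DE at
FDR < 0.01 and |log2FC| > 1), parental DE with two/four/eight-fold tiers,
single-parent expression (one parent FPKM < 0.1, the other > 1) and hybrid
complementation (hybrid FPKM > 1), the dominance/additivity ratio

```
D/A = (F1 − mean(P1, P2)) / (max(P1, P2) − mean(P1, P2))
```

and BIC-based classification of each gene into mid-parent (MP), partial
(PD_H/PD_L) and full (HP/LP) dominance or above/below-parent
overdominance (AHP/BLP).

**Deleterious load.** Genes carrying high-effect variants (frameshift,
stop gained/lost, splice donor/acceptor, …) on exactly one parental allele
form complementary pairs; a pair is *suppressed* when the functional
allele is expressed over two-fold above the deleterious one (exact
binomial FDR < 0.05). GERP-constrained sites (RS > 2) are split into CDS
versus 2-kb-upstream cis regions and correlated with release year and
yield.

**Transcriptomic entropy.** Each genotype's samples are converted to
expression-frequency vectors, averaged, and summarised by Shannon entropy
`H = −Σ pᵢ log₂ pᵢ`; the hybrid–parent entropy reduction
`ΔH = mean(H_female, H_male) − H_hybrid` is correlated with mid-parent
heterosis.

**Synthetic data.** `hybridexpr.simulate` generates all inputs — trio
genotypes, allele counts from the logit model, expression matrices with
planted inheritance modes and SPE/CE genes, annotations with planted
complementation/suppression, phenotypes with planted entropy–heterosis
correlation — with truth tables for every planted quantity and
byte-identical regeneration at a fixed seed.

## Worked example

```python
from hybridexpr import (SimulationConfig, simulate_all, phase_trio,
                        filter_ase_snps, compute_null_ratio,
                        fit_ase_population, ASEModelSpec)

cfg = SimulationConfig(n_hybrids=12, n_snps=80, n_genes=150, seed=7)
data = simulate_all(cfg)

phased = phase_trio(data["trios"])
print(phased["filter_reason"].value_counts().to_string())

obs = filter_ase_snps(data["allele_counts"], min_hybrids=8, min_total=10)
m = compute_null_ratio(obs)
fits = fit_ase_population(obs, ASEModelSpec(chains=2, draws=500,
                                            warmup=300, seed=7),
                          null_ratio=m)
print(f"null m = {m:.4f}; {int(fits['significant'].sum())} of {len(fits)} "
      f"SNPs significant at FDR < 0.05")
```

prints

```
filter_reason
kept             688
uninformative    143
parent_het        74
conflict          33
missing           22
null m = 0.5232; 3 of 63 SNPs significant at FDR < 0.05
```

Of 960 trio-site records, 688 are phaseable (opposite parental
homozygotes); the rest are removed for the printed reasons. Sixty-three
SNPs pass the heterozygosity/depth filters; the median alt-allele ratio
0.5232 becomes the null, and three SNPs show allelic bias that survives
FDR control — the strongest has posterior mean ratio 0.174 (97.5% CI
0.089–0.316) against a planted truth of 0.208.

The same stages are available from the shell:

```bash
hybridexpr simulate --outdir sim --seed 7
hybridexpr phase --vcf sim/genotypes.vcf --trios sim/trio_manifest.tsv --out phased
hybridexpr pipeline --outdir run --seed 7       # full chain + report.yaml
```

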