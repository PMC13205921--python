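# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hybridexpr`, and what the synthetic-data generator does
and does not emulate.

## Trio phasing

A biallelic site is phaseable in an F1 exactly when the parents are
opposite homozygotes; the maternal allele is written first (`0|1` when the
female parent carries the reference allele). The rule table is total:
every record receives exactly one label among `kept`, `parent_het`,
`conflict`, `uninformative`, `missing`.

Choices where the rules leave room:

* A hybrid *homozygous* at an informative site contradicts Mendelian
  expectation and is labelled `conflict` (likely genotyping error), not
  `uninformative`.
* Multi-allelic genotypes are labelled `uninformative` — the analysis is
  defined over biallelic SNPs.
* Any missing genotype in the trio gives `missing`; no imputation.
* Malformed genotype strings are rejected per record with a logged count
  rather than aborting a whole file.

## Population ASE: binomial mixed model

Counts at SNP *s* in hybrid *g* under treatment *t* (replicates within a
hybrid × treatment cell are summed — under the model they are exchangeable
Bernoulli trials):

    alt_gt ~ Binomial(total_gt, p_gt)
    logit(p_gt) = b0 + a_g + c_t,  a_g ~ N(0, s_a^2),  c_t ~ N(0, s_c^2)

Priors are weakly informative and configurable: `b0 ~ N(0, 2.5^2)`,
`s_a, s_c ~ HalfNormal(1)`. The null is the dataset median ratio *m* of
the filtered observations, which absorbs global reference-mapping
asymmetry; the reported p-value is the two-sided posterior tail
probability `2 · min(Pr[invlogit(b0) < m], Pr[> m])`, capped at 1, and
BH-adjusted across converged SNPs at level 0.05.

### Sampler

Inference is by an adaptive Metropolis-within-Gibbs sampler vectorised
across SNPs and chains: one numpy pass updates the intercept of every SNP
in every chain simultaneously, then the genotype effects (conditionally
independent across hybrids), the treatment effects, and the log random-
effect SDs (with the log-scale Jacobian). Proposal scales adapt per
parameter in batches of 50 toward 0.44 acceptance during warmup.

Because the likelihood identifies only `b0 + mean(a)` (and `b0 +
mean(c)`), a plain componentwise sampler mixes extremely slowly along that
ridge. Two *translation moves* per sweep propose shifting `b0` by δ and
every corresponding random effect by −δ; the likelihood is exactly
invariant, acceptance depends on the priors alone, and the chain slides
freely along the ridge. Chains start from the empirical pooled logit,
overdispersed per chain.

Defaults: 4 chains × 1000 retained sweeps after 500 warmup sweeps;
convergence is monitored with split-R̂ on `b0` (threshold 1.05);
non-converged SNPs are flagged, logged, and excluded from the BH family.
Fixed seeds give identical draws.

### What the posterior width means

With only two treatment levels, the split of the intercept versus the
*mean* treatment effect is prior-identified, not data-identified, so the
marginal posterior of `b0` honestly carries an extra `~s_c/sqrt(2)` of
width under the HalfNormal(1) prior. Credible intervals are therefore
conservative (empirical coverage near 1.0 rather than 0.975); point
estimates are unaffected (posterior-mean MAE ≈ 0.02 at depth 100 × 15
hybrids). Narrower intervals would require either more treatment levels or
a tighter prior on `s_c`; we keep the weakly-informative default and note
the conservatism.

## Per-hybrid haplotype ASE

Gene-level maternal/paternal counts are per-SNP sums over phased sites.
This assumes upstream counts are free of double-counted reads (a read
overlapping two heterozygous SNPs must be counted once); the synthetic
generator produces counts at the SNP level without double counting, and
the simplification is recorded in the run manifest. SNPs mapping to more
than one annotated gene are assigned to none.

Allelic imbalance is an exact two-sided binomial test against 0.5 on
counts pooled per hybrid × density, BH-adjusted within each hybrid ×
density family; genes below 20 total reads are not tested (artifact
choice, configurable).

### Cis/trans classification

For a parental-DE gene with parental fold change `L = log2(female/male)`
and pooled allelic counts (maternal, paternal), three allelic-ratio models
are compared by BIC on the binomial likelihood: equal alleles (trans-only,
p = 1/2), the parental ratio (cis-only, p = 2^L/(1+2^L)), and a free
ratio. The free model pays one parameter at `ln(total reads)`. If the two
best models are within ΔBIC 2 the gene is `ambiguous`. A winning free
model is split by sign and magnitude: allelic sign opposite the parental
direction → `unexpected`; |allelic ratio| below |L| → `cis_plus_trans_same`
(trans attenuates the cis difference); above → `cis_plus_trans_opposite`.
At read depth ≥ 500 this recovers planted cis-only / trans-only /
cis+trans genes at ≥ 90%.

Density consistency uses the per-density ASE flags and bias signs
(consistent / direction_shift / HPD_only / LPD_only); allele-specific
density response tests each allele's replicate counts high- versus
low-density with the pairwise NB GLM at |log2FC| > 1 and FDR < 0.01 (the
methods-level threshold; configurable).

## Differential expression and inheritance

All count models are NB2 GLMs with log link and library-size offsets from
median-of-ratios size factors (total-count fallback when too few
all-positive genes). Gene-wise dispersion matches the Pearson chi-square
to its residual degrees of freedom; plain plug-in ML is biased low when
the group means are themselves fitted from 2–3 replicates, which inflates
downstream likelihood-ratio differences. Dispersions are floored at 1e-4.
Wald tests per coefficient; BH per contrast family; population DE requires
FDR < 0.01 and |log2FC| > 1; parental DE requires FDR < 0.01 with nested
fold tiers DE_2/DE_4/DE_8 at |log2FC| ≥ 1, 2, 3.

SPE/CE: a gene is single-parent-expressed when one parent's replicate-mean
FPKM is below 0.1 and the other's above 1; complementarily expressed when
additionally the hybrid exceeds 1.

### Inheritance modes

D/A is computed on replicate-mean FPKM per stage × density cell. Candidate
models for the hybrid mean — mid-parent, either parent's level, or free —
are fitted by *joint* maximum likelihood: the parental means are
re-optimised under each constraint (Nelder–Mead on log means for the
additive model; a 1-D bounded search for the tied parent-hybrid mean in
the dominant models), with a shared Pearson-matched dispersion. Plugging
in fixed parental means instead would ignore the uncertainty of the
constrained mid-parent mean and roughly double the false non-additive
rate at three replicates. BIC counts 2 mean parameters for the constrained
models and 3 for the free model over all trio samples.

Decision rule: if the additive model is the winner *or* lies within ΔBIC 2
of the winner, the gene is MP (conservative: non-additivity is only called
with positive evidence) and flagged ambiguous in the latter case. A
winning dominant model gives HP/LP directly. The free model counts as
partial/over dominance only when it also beats both parental-level models
by the margin (its fitted mean is otherwise statistically
indistinguishable from a parent's level); it is then refined by the D/A
bands |D/A| ≤ 0.25 → MP, < 0.75 → PD_H/PD_L, ≤ 1.25 → HP/LP, beyond →
AHP/BLP (bands configurable; the seven categories are standard, the
numeric cutoffs are package defaults).

### The mode-recovery scenario

The recovery benchmark plants 500 modes at mean count 200 with three
replicates, choosing the unstated knobs as follows: NB dispersion 0.02
(the precision of a well-replicated controlled experiment — at field-level
dispersion 0.05 the Bayes-optimal classifier itself sits near 90% for
dominant genes at moderate folds, so recovery would measure noise, not
implementation quality); planted parental |log2FC| in 1.5–3 (parental-
level categories are only well-posed for clearly separated parents); and
a 30% DE fraction within a 1700-gene matrix, because median-of-ratios
normalisation needs a non-DE majority — at 50% planted DE the hybrid's
composition bias shifts every normalised hybrid mean by ~6% and biases
D/A by ~−0.15. Measured recovery is 0.92–0.94 across seeds.

## Deleterious load

Deleterious alleles are counted at gene level (any high-effect variant on
that allele; duplicates never double-count). Complementary pairs require
the high-effect variant in the *coding* sequence of exactly one parent.
Suppression requires the functional allele higher, |log2(functional/
deleterious)| > 1, and exact binomial FDR < 0.05, with the BH family per
hybrid (consistent with per-hybrid reporting). GERP trends count
complemented RS > 2 variant *sites* per region (CDS vs 2-kb upstream) per
hybrid and Pearson-correlate them with release year and trait values;
fewer than three hybrids is an error, zero variance a flagged NaN.

## Transcriptomic entropy

The expression frequency of gene *i* in sample *j* is its within-sample
FPKM share, so each sample's frequencies sum to 1 and the across-sample
average `p_i = (1/t) Σ_j p_ij` is a proper distribution; `H = −Σ p_i log2
p_i` is then a genuine Shannon entropy bounded by `log2 g`. This
within-sample normalisation is the only definition under which both
properties hold, and it makes H invariant to per-sample rescaling.
Entropy is computed over a genotype's full stage × density sample set.
Genes with mean FPKM < 1 across the trio's samples are removed first, and
the same retained universe applies to hybrid and parents (a threshold
stand-in for heavier clustering-based QC; configurable). The per-hybrid
scalar is `dH = mean(H_female, H_male) − H_hybrid`; both parental
entropies are also emitted.

## Synthetic data: what it does and does not emulate

The generator mirrors the emulated study design — 20 hybrids with distinct
parents, three stages, two planting densities, three replicates — and
plants, with truth tables: trio site classes at configurable rates; ASE
ratios through the exact logit model the estimator assumes; inheritance
modes (mix 55/19/23/1.4/1.6% additive/dominant-high/dominant-low/AHP/BLP,
matching the reported category proportions) with overdominants planted
directly in D/A space (F1 = mid ± 2.5 × the additive half-range; the
below-low-parent fold change is capped so the planted mean stays
positive); SPE genes with truly silent parents (mean 0) and 57% hybrid
complementation; deleterious complementary pairs with 53% suppression at
a 0.85 functional-allele fraction; release years uniform on 1960–2010
with a 0.5 unit/year mid-parent gain; an entropy–heterosis correlation of
0.5 planted through a shared latent factor; and GERP cis/CDS count–year
correlations (0.6 / 0.0) planted *exactly in sample* (noise orthogonalised
against the year vector), so recovery deviates only through integer
rounding.

Hybrid expression profiles are sharpened (power 1.3–1.7 on the unplanted
gene class, renormalised) so hybrids genuinely have lower transcriptomic
entropy; the sharpening must outweigh the entropy-*raising* effect of
mid-parent averaging on DE genes, which is why the exponent is not close
to 1. Sharpening excludes planted-mode and SPE genes so their means stay
exact. The latent factor plants the correlation at the level of the
per-hybrid scalars; the numeric value of the *computed* dH is not forced
to equal the latent dH.

Not emulated: read-level artefacts (mapping bias, double-counted
overlapping reads), linkage between SNPs, shared parents across hybrids,
GO term structure, batch effects, and any dependence between the ASE,
expression and phenotype components beyond the planted links. Passing
recovery tests therefore demonstrates correctness of the estimators under
their assumed models, not robustness to real-data artefacts. Depth is
NB(mean 100, dispersion 0.3) per SNP per sample — a stand-in, as the
empirical depth distribution is not specified.

Determinism: each component draws from an independent child stream of the
seed, and all outputs (TSV, minimal GT-only VCF, config YAML) are written
with fixed formatting, so a fixed seed regenerates byte-identical files.

## Numerical details and degenerate inputs

* BH adjustment rejects NaN p-values (the caller owns the family).
* Binomial log-likelihoods use `alt·η − total·softplus(η)` via
  `logaddexp` for stability; probabilities are clipped at 1e-12 in the
  cis/trans BIC.
* `compute_da` returns NaN (flagged) when the parents are equal; zero
  totals are dropped from suppression denominators and logged; all-zero
  samples are excluded from entropy frequencies and logged.
* `log2` allelic ratios use a 0.5 pseudocount only when a count is zero.
* IRLS NB fits fall back to least-squares solves on singular systems;
  zero-count genes short-circuit to log2FC 0, p 1.
* Validation scenarios scale: the null-calibration panel runs 2000 SNPs ×
  15 hybrids × 2 densities at depth 100 with 2 chains × 600 retained
  sweeps; recovery panels use 200 SNPs and 500 planted genes.

## Known limitations

* The marginal credible intervals of the population ASE model are
  conservative (see above); comparisons of interval widths are meaningful
  on the logit scale.
* The pairwise NB GLM uses plug-in (not moderated) dispersion; with two
  replicates per group, power is limited and tier boundaries are noisy
  near the cutoffs.
* Gene-level haplotype aggregation can over-weight genes with many phased
  SNPs relative to read-level haplotype counting.
* The pipeline's end-to-end mode runs on generated data; external files
  enter through the per-stage commands (`phase`, `ase-pop`, `ase-hybrid`,
  `delload`, `entropy`, `heterosis`) and the schema validator.
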