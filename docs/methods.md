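# Methods

This note documents the statistical models, parameter choices and known
limitations of `sexqtl`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external
results.

## Models

### Sex-differential expression

For each gene g the model is

    y_g = α + β_sex · s + Σ_k γ_k · SV_k + ε,   s ∈ {0 = male, 1 = female}

fit by OLS on residualized/Z-scored expression, with BH FDR across genes.
`β_sex` is the female-minus-male difference in SD units (on Z-scored
input). With no SVs and balanced design this reduces exactly to the
equal-variance two-sample t-test, which the suite asserts to 1e-8.

### Two-stage sb-QTL procedure

Stage 1 runs three cis scans (joint with sex as covariate, male-only,
female-only) over all gene-variant pairs within ±500 kb of the gene
body; a pair is carried forward if BH q < 0.05 in any scan. Stage 2 fits

    y = α + β_g · x + β_s · s + β_gxs · x·s + covariates + ε

and BH-corrects the interaction p-values over all stage-1 pairs
(the FDR universe is configurable; the stage-1-pairs universe is the
default). `β_gxs` is the female-minus-male difference in per-allele
effect. The `stage_p` threshold — the largest raw interaction p among
stage-2-significant records — is derived from the data at run time and
reused by the environment check.

Both scans use the Frisch–Waugh–Lovell decomposition: expression and
dosages are residualized on the covariate design once per gene, after
which every variant's coefficient, SE and t-test equal full per-pair OLS
exactly (asserted in the suite) at a fraction of the cost.

**X chromosome.** Males are hemizygous: dosages in {0, 2} in every mode.
Hardy–Weinberg filtering on X uses females only. Genetic PCs are
computed from autosomal variants only, because the male/female variance
difference on X would otherwise imprint sex on the covariates.

**Conditioning of stage 2 on stage 1.** Because stage-1 pairs selected
through a borderline single-sex scan are enriched for extreme
interaction statistics, the stage-2 BH correction over the selected set
is mildly anti-conservative under a global interaction null: across
null replicates the per-replicate false-discovery indicator averages
roughly 0.08–0.12 against the nominal 0.05. This is a property of the
two-stage design itself (in signal-rich data, where stage 1 is
dominated by real QTLs, the effect is negligible), and the alternative
FDR universe — BH over the interaction p-values of *all* scanned
pairs — is available via `AnalysisConfig.stage2_universe`.

**QQ diagnostics.** The interaction-term λ is reported for the scanned
set. On a global interaction null, λ over *all* cis pairs is ≈ 1.0
(acceptance checks [0.9, 1.1]); λ restricted to the stage-1-selected
subset is inflated *by construction* — pairs that enter stage 1 through
a borderline single-sex scan are enriched for extreme interaction
statistics even when no interaction exists. Diagnostic QQ plots should
therefore be read on the full scan, which is how the pipeline's null
calibration computes them.

### LD clumping

Greedy per gene (each gene's records are one phenotype's clump set): the
smallest-p unassigned record becomes an index (ties by position, then
variant id); unassigned records of the same gene within 250 kb of the
index with genotype r² ≥ 0.50 join its clump. r² is the squared
correlation of mean-imputed standardized dosages in the full analysis
sample (not per sex). Index counts at r² ≥ 0.10 are reported alongside.
The implementation is checked against a literal brute-force greedy
oracle on ≤ 20-SNP fixtures.

### Storey π1

π0 is estimated on the λ-grid 0.05…0.95 (step 0.05) as
#{p > λ} / (m(1 − λ)), smoothed with a natural cubic *smoothing* spline
at a fixed penalty giving ≈ 3 effective degrees of freedom on that grid,
evaluated at λ = 0.95 and clipped to [0, 1]; π1 = 1 − π0. An
interpolating spline is deliberately not used: the tail estimates have
variance ∝ 1/(m(1−λ)) and an interpolant chases them. Below m = 50 the
estimator falls back to the conservative fixed-λ = 0.5 form with a
warning. Even smoothed, the estimator's sampling sd is roughly 0.1 at
m ≈ 300 and 0.03 at m ≈ 4000, which is why the π1-recovery experiment
is sized to several thousand matched records. Two properties of π1 in
this design are worth noting: at replication fraction 1.0 the measured
π1 sits near 0.95, the missing 5% being exactly the discovery-stage
false discoveries (FDR 0.05); and small replication cohorts (the
pipeline default of 300, mimicking a typical confirmation set) yield
π1 well below 1 through power alone.

### Heritability, weights, PWAS, colocalization

- **cis heritability**: single variance component with kernel
  K = ZZᵀ/m on standardized cis dosages, REML by 41-point grid over
  h² ∈ [0, 0.999] plus bounded refinement in the eigenbasis of K; LRT
  against h² = 0 with the ½χ²₀ + ½χ²₁ boundary mixture; heritable at
  p < 0.01. Planted h² ∈ {0, 0.25, 0.5} is recovered within ±0.15 at
  n = 700.
- **weights**: ridge (the BLUP analogue), LASSO and elastic net
  (l1_ratio 0.5); penalties tuned by 5-fold CV on the full data, then
  each fixed-penalty model scored by out-of-fold R² with a seeded KFold;
  the best model's weights are kept. Tuning inside every outer fold
  would multiply cost without changing the winning family.
- **PWAS**: z = wᵀz_GWAS / √(wᵀ(R + 0.01·I)w) with R the LD correlation
  matrix of the model's variants (by default from the analysis/GWAS
  cohort itself; an external panel can be supplied). Allele
  harmonization flips z for swapped A1/A2 and drops strand-ambiguous
  (A/T, C/G) variants. BH FDR runs across genes within each sex stratum.
- **colocalization**: per-variant Wakefield log-ABF
  ½[log(1−r) + r·z²], r = W/(W + se²), prior effect SD 0.15
  (quantitative; 0.2 conventional for binary traits, configurable);
  hypothesis sums combined in log space with priors p1 = p2 = 1e-4,
  p12 = 1e-5. Posteriors sum to 1 within 1e-10. With several causal cis
  variants at a locus the single-causal-variant assumption pushes mass
  to PP3 — a genuine model property that the sparse-architecture
  recovery experiments respect.
- **sex-specific call**: one sex must pass PWAS q < 0.05 *and*
  PP4 > 0.75 while the other shows raw PWAS p > 0.05 or carries no PWAS
  record (not heritable in that stratum — the two reasons for a missing
  record are logged separately). The rule is exactly label-symmetric,
  asserted by swapping strata.

## Synthetic data: what it emulates, and what it does not

Genotypes come from two latent-Gaussian haplotypes per individual:
within a block of `ld_block_size` SNPs the latents correlate at
`ld_rho`, and an allele is carried when the latent exceeds the 1-MAF
quantile, giving Hardy–Weinberg genotype frequencies with tunable LD.
Males draw a single X haplotype (dosage 0/2). Besides the cis SNPs, the
simulator emits ~300 independent background X markers, the kind of
array content that anchors heterozygosity-based sex inference; with
only a few dozen X SNPs the female heterozygosity distribution is too
wide for a deterministic call. Paired cohorts share variant definitions
(positions and population MAFs) through a template mechanism.

Expression follows the linear generative model

    y_g = Σ β_cis·x + β_sex·s + Σ β_gxs·x·s + Σ λ·u + ε

with sparsity and effect SDs set in `SimConfig`. Defaults: 716 samples
(a realistic single-region discovery cohort), 60 genes × 12 SNPs,
MAF ∈ [0.05, 0.5], LD blocks of 6 at latent ρ = 0.8, 15% of genes with
a sex effect (SD 0.5), 50% of SNPs with cis effects (SD 0.4), 10% with
interactions (SD 0.4), 3 hidden factors (sex-independent by default; a
sex-correlated mode stresses the confounding check), unit noise. GWAS
cohorts default to 20,000 individuals so that mediated per-variant
z-scores are informative at desk scale.

Not emulated: recombination maps, allele-frequency/LD differences
between populations, genotyping error, missing-not-at-random
expression, batch×sex artifacts, and trans effects. Passing tests
therefore demonstrate the correctness and calibration of the
*procedures*, not performance on any real cohort.

## Deviations from common tool stacks (deliberate, self-contained)

- SVA is implemented as residual-SVD with permutation (parallel
  analysis) selection after projecting out intercept and sex, so every
  returned component is orthogonal to sex by construction (asserted to
  1e-8); a fixed component count can be forced instead.
- DESeq2-style variance stabilization is replaced by log2(CPM + 0.5)
  after the per-diagnosis CPM filter.
- KING kinship and EIGENSTRAT are replaced by correlation-based kinship
  (threshold 0.177, seeded greedy removal) and plain PCA; the QC report
  labels the substitution.
- BSLMM is omitted from weight training; the best-of-{ridge, lasso,
  elastic net} selection preserves the "best-performing model" contract.
- Multi-region shrinkage meta-analysis (MASH/LFSR) and fine-mapping
  (SuSiE) are out of scope; regions are analyzed side by side, with an
  optional Stouffer combination clearly labeled as a convenience, not
  part of the core procedure.

## Numerical choices

- OLS via pivoted QR; rank deficiency (tolerance 1e-10 relative)
  raises a collinearity error naming the offending columns.
- Fisher's exact two-sided p sums hypergeometric outcomes with
  probability ≤ observed (the doubling rule is not used); the 95% CI is
  a Haldane-corrected Wald interval on the log odds ratio, with the
  unbounded side reported as ∞ for degenerate cells.
- HWE exact test enumerates het counts by log-gamma, matching full
  enumeration exactly for totals ≤ 200 in the suite.
- λ uses the median-χ²₁ definition; p = 0 is clamped to the smallest
  positive float with a warning.
- Monomorphic (or within-stratum constant) variants are skipped with
  counts; missing dosages are mean-imputed for regression scans, PCA
  and r², never for MAF/HWE.
- Ties: clumping breaks p-ties by position then variant id; isoform
  selection breaks mean-abundance ties lexicographically.

## Experiment sizes

The calibration experiments are sized so that their Monte-Carlo error is
small relative to the tolerance being checked: the interaction null uses
50 replicates of 100 genes × 50 SNPs × 700 samples (FDR bound
0.05 + 2·MC-SE); bias uses 200 planted effects of magnitude 0.4
(estimate SE ≈ 0.01); power grids use 60 effects per cell at
β ∈ {0.2, 0.4, 0.6} and n ∈ {300, 500, 700}; π1 recovery uses 1600
genes (~4–5k matched records) with interaction magnitudes drawn
U(0.5, 0.9) so that retained effects replicate essentially surely;
sex-specific recovery uses 50 end-to-end runs of a 600-sample cohort
with one causal cis variant per gene and a 20,000-sample GWAS.

## Limitations

- Linear, homoscedastic models throughout; no mixed models or robust
  SEs, so cryptic relatedness beyond the kinship prune or strong
  variance heterogeneity between sexes is not handled.
- The two-stage design conditions stage 2 on stage 1; interaction
  effect estimates *conditioned on discovery* carry winner's curse (the
  unbiasedness check evaluates planted pairs unconditionally).
- Storey's π1 is noisy below a few hundred records and mildly
  conservative when alternatives keep mass above λ = 0.95.
- Colocalization assumes a single causal variant per trait per locus.
- The cis-heritability LRT mixture is asymptotic; at n well below a few
  hundred the p-values are approximate.
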