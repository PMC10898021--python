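# Methods

`prspipe` implements a clumping + thresholding (C+T) polygenic risk
score (PRS) pipeline for Alzheimer's disease case-control cohorts,
together with the downstream analyses such a score feeds: prediction
models, endophenotype association, and MCI→AD conversion analysis.
This note documents the statistical model, the defaults and why they
were chosen, the synthetic-data generator that the test suite runs
against, and the numerical choices made where the design was open.

## The score

For individual *i* the score over the selected SNP set is

    PRS_i = ( Σ_j β_j · x_ij ) / M

where β_j is the discovery-GWAS log-odds for SNP j, x_ij the counted
(effect) allele dosage in {0, 1, 2}, and M the number of SNPs in the
score.  The division by M is part of the score definition here (some
scoring tools report the unaveraged sum); it is a per-threshold constant
and therefore irrelevant to any rank- or regression-based downstream
quantity, but it is what the printed scores contain.  Missing genotypes
are mean-imputed per SNP (center-neutral with respect to the cohort);
M counts SNPs, not per-sample non-missing calls.

SNP selection is greedy LD clumping followed by p-value thresholding:

* **Clumping** (window 250 kb, r² > 0.1, defaults config-exposed):
  SNPs are visited in ascending discovery p (ties broken by genomic
  position); each unclaimed SNP becomes an index and claims all
  unclaimed SNPs within the window whose r² with it exceeds the cutoff.
* **Thresholding**: SNPs with p ≤ p_T enter the score; the grid is
  p_T ∈ {5e-8, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.5, 1.0}.
* **Threshold selection** maximizes Nagelkerke ΔR² between a full
  logistic model (PRS + first two ancestry components) and the null
  (components only), computed on CU vs ADD.

Score variants: `incAPOE` (all clumped SNPs); `noAPOE` removes ±500 kb
around the APOE top hit (chr19:45,403,412, boundary inclusive — "±500
kb" is read as a closed interval); `nochr19` removes chromosome 19
entirely; `adjLD` additionally collapses external-reference LD blocks.

### adjLD block rule

Pairs of retained SNPs with external r² > 0.5 define edges; any retained
SNP positioned between two linked SNPs belongs to their block, so blocks
are the union of overlapping edge intervals per chromosome.  Each block
keeps exactly its lowest-p SNP (ties: lowest position).  The r² table is
external (emulating a European reference panel) with a cohort-LD
fallback.  Pairs inside a block span that are absent from the table do
not error by default — positional membership is what defines the block;
a `strict` flag turns them into an error, and `consecutive_only`
restricts edges to consecutive retained SNPs for the narrower reading of
"adjacent".

## Quality control

Marker filters, in order: all markers at a duplicated chrom:pos are
removed (conservative: neither copy is trusted); missingness > 5%
(i.e. call rate < 95% — the sensible direction of the rule); exact
Hardy–Weinberg test in controls at p < 1e-5 (Wigginton conditional
test, no mid-p); MAF < 1%.  Sample filters: missingness > 1%;
autosomal heterozygosity |F| ≥ 0.2 with F = 1 − observed/expected
heterozygosity at cohort allele frequencies; pi-hat > 0.2 from
PLINK-style method-of-moments IBD on LD-pruned markers (window 50,
step 5, r² 0.2), removing the later-listed member of each pair
deterministically.  A sex-consistency check is recorded as skipped —
it needs X-chromosome genotypes, which the generator does not model.
Ancestry components come from PCA of the frequency-standardized dosage
matrix; classical (Torgerson) MDS of the Euclidean distances of the
same matrix is available and is identical up to sign, which is fixed by
making each component's largest-magnitude score positive.  Outlier
removal against an external reference panel is not reproduced; an
optional z-score rule on the first two components stands in for it.

## Prediction models

Logistic fits are unpenalized ML (IRLS); strict separation is flagged
and reported, never silently regularized.  Nagelkerke R² uses the
intercept-only model as the baseline LL₀ (the convention of the common
C+T scoring tool); R²cs = 1 − exp((2/n)(LL₀ − LLm)), R² = R²cs / (1 −
exp((2/n)LL₀)).  A covariate-null baseline is available via
`baseline="null"`.  AUCs carry DeLong structural-component variances
and normal-approximation 95% CIs (clipped to [0,1]); correlated AUCs
are compared with the paired DeLong z-test.  Cross-validation is
stratified five-fold on case status.  Group comparison of standardized
scores across CU/MCI/ADD uses Tukey's HSD.

## Endophenotype association

Three nested covariate models per outcome: (1) age, sex, education,
two components; (2) + ε4 dose; (3) + ε2 dose.  Continuous outcomes use
OLS; binary PET status uses logistic regression (the only coherent
reading of a slope-style estimate for a binary outcome).  The Wald p
for the standardized-PRS slope is BH-FDR corrected within each subject
group × model stratum.  Analyses are complete-case; volumes are
covariate-adjusted for intracranial volume (a ratio option exists).
Decile summaries assign deciles by rank with ties going to the lower
decile.

## Conversion analysis

Tertile cut-points are the 1/3 and 2/3 quantiles (linear interpolation)
of the *full-cohort* PRS distribution — not MCI only — with values at a
cut falling into the lower group.  MCI participants with ≥ 12 months of
follow-up enter the analysis; the 1st (low) vs 3rd (high) tertile are
compared.  The log-rank test uses PRS group only (covariates could
themselves differ between groups); the Cox proportional-hazards model
(Efron ties; Breslow by flag) adjusts age, sex, education, two
components, and ε4/ε2 doses, with ε4 as a numeric dose (carrier-binary
optional).  The analysis is repeated within ε4 carriers and
noncarriers, dropping the ε4 covariate within strata; inestimable
covariates (monotone likelihood, constant columns) are reported as NA
rows rather than numbers.  KM curves use the product-limit estimator
with Greenwood-based (log-log) intervals.

## Synthetic cohort generator

The generator produces every input the pipeline consumes, with the
statistical structure the analyses assume.  It emulates structure, not
the study's numbers: with 20 causal SNPs at liability h² = 0.25 in a
~700-SNP genome, the synthetic ΔR² and AUC are substantially larger
than anything a real AD cohort shows, so passing tests demonstrate the
machinery recovers designed truth — they say nothing about effect sizes
in real data.

* **Genotypes** — Gaussian-copula haplotypes: within each LD block the
  latent vector is AR(1) with parameter ρ (default 0.8); an allele is
  carried when the latent value falls below the MAF quantile.
  Single-SNP genotypes are Hardy–Weinberg by construction; dosage r²
  between block neighbours is an attenuated function of ρ (attenuation
  grows as MAF falls — dichotomization discards correlation).  120
  blocks of 6 SNPs span chromosomes 1–18 with block spans (5 kb) far
  below the clump window and inter-block gaps far above it; one extra
  block sits on chromosome 19 centered at the APOE top-hit position.
  A coalescent simulator would give realistic LD decay but no direct
  control of r², which the clumping/adjLD tests need.
* **Liability** — 20 causal SNPs (one per block, equal-magnitude
  random-sign effects summing to h² = 0.25) plus an APOE-like major
  locus (allele frequency 0.15, OR 3.0 mapped to the liability scale by
  β = log OR / 1.81, the standard logit→probit conversion) and a weak
  protective ε2-like locus (frequency 0.05).  Diagnosis is assigned by
  liability rank to reproduce the configured group sizes (145 CU /
  220 MCI / 139 ADD) exactly.  Equal causal magnitudes make every
  causal SNP individually detectable in the discovery scan, giving the
  threshold grid a well-defined causal band.
* **Discovery GWAS** — an independent 12,000-sample cohort with the
  same copula parameters; cases are the top 20% of liability; per-SNP
  marginal logistic betas and Wald p-values form the summary-statistic
  file.  12,000 samples put per-SNP power near the 1e-5 band of the
  grid, mirroring where real AD scans place their optimum.
* **Designed discovery table** — for threshold-scan recovery
  experiments `designed_sumstats` fixes the p-value layout: causal SNPs
  log-uniform in (1.2e-6, 1e-5], nulls in (2e-4, 1].  Two deliberate
  design choices: (a) under a natural marginal scan the *weakest*
  causal SNP's p is an extreme-value statistic spanning several decades,
  so "the grid point containing all causal SNPs" is not a stable design
  quantity; fixing the band makes the recovery experiment well-posed.
  (b) null betas use an effective discovery size of 2,000 — a few
  hundred desk-scale nulls with inflated sampling noise produce the
  same aggregate score-noise dilution at permissive thresholds that
  tens of thousands of nulls exert at full scale, preserving the
  characteristic rise-then-fall of the ΔR² profile.
* **Conversion** — exponential event times; baseline 36-month
  conversion 35%; hazard × 2.22 for the high-PRS tertile, by default
  only within ε4 noncarriers; exponential drop-out (rate 0.01/month),
  administrative censoring at 36 months, observation rounded up to a
  6-month visit grid (`visit_months=None` disables rounding for
  recovery experiments where grid ties would test tie handling rather
  than estimation).
* **Endophenotypes** — two CSF-ratio-like outcomes, slope 0.235 per SD
  of the true polygenic score applied in the MCI stratum only (plateau
  in CU/ADD), plus small age and ε4 terms and unit Gaussian noise.

Everything is driven by one `numpy.random.default_rng(seed)` stream;
fixed seed ⇒ byte-identical outputs.

## Numerical choices

* HWE exact test: probabilities by outward recurrence from the modal
  heterozygote count; the two-sided sum includes configurations whose
  probability is within a 1e-12 relative tolerance of the observed
  one, protecting exact ties against floating-point error.
* Harmonization flips dosage (x → 2 − x), never the betas: the weight
  file stays the single source of truth.  Strand-ambiguous A/T and C/G
  SNPs are dropped without frequency-based rescue.
* Tie-breaks everywhere are (lower p, then lower position), making
  every selection deterministic.
* Standardization uses the n−1 denominator.
* Degenerate inputs (constant scores, monomorphic LD, one-class ROC,
  zero events) raise typed errors rather than returning NaN.

## Problem sizes in tests

The acceptance suite runs: clumping vs a brute-force oracle on 200
random ≤60-SNP instances; BH-FDR vs a step-up oracle on 10,000 random
vectors; null calibration of the Wald/DeLong/log-rank tests at 2,000
replicates each; Cox HR recovery on 500 cohorts of n = 208 (~30%
events); slope recovery on 300 strata of n = 85; threshold-band
recovery on 12 designed replicates; and a closed-form AUC check at
n = 20,000.  These sizes were chosen to keep Monte-Carlo noise well
inside each asserted band.

## Known limitations

* LD is block-diagonal with AR(1) structure; there is no inter-block
  LD, no MAF-LD coupling, and no realistic recombination landscape.
* Diagnosis-by-rank makes the liability→diagnosis map deterministic;
  real diagnostic noise would attenuate every downstream effect.
* The ε4 dose equals the major-locus genotype exactly; real ε4 calls
  come from two separate variants with haplotype uncertainty.
* VCF input is GT-only (hard calls); dosage (DS) scoring and bgen are
  out of scope, as are phasing and imputation.
* The Wald test's small-sample anticonservatism (visible below n ≈ 250
  with balanced outcomes) is a property of the test, not corrected for.
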