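# Methods

This note documents the models, numerical choices and known limitations of
the `anxgwas` pipeline, in the order the stages run.

## Synthetic cohort generator

The generator exists so every downstream stage can be tested against known
ground truth; it emulates the *structure* of a large population cohort
screened with the HADS-A anxiety questionnaire, not any particular dataset.

**Genotypes.** Balding–Nichols model: each variant has an ancestral allele
frequency drawn uniformly from `maf_range` (default 0.05–0.5); each of
`n_populations` (default 2) subpopulations draws its own frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = fst` (default 0.05), and diploid
dosages are Binomial(2, population frequency). Missingness is completely at
random at `missing_rate`. Population frequencies are clipped to
[10⁻⁴, 1−10⁻⁴] to avoid fixation. `fst = 0` collapses exactly to one
panmictic Hardy–Weinberg population.

**Phenotype.** A liability
`L = Σ_j β_j z_j + covariate terms + ε`, with `z_j` the standardized dosage
of each of `n_causal` causal variants (default 20), `β_j ~ N(0,
causal_effect_sd²)` (default SD 0.25) and `ε ~ N(0, 1)`. The questionnaire
score is `Binomial(21, logistic(baseline_logit + scale·L))`, which makes it
a genuine bounded integer on 0–21, and the binary anxiety label is
`score ≥ 11`. The total-distress score adds a second, weakly coupled
Binomial(21, ·) component so it always dominates the anxiety subscore.

**Calibration.** Two marginal conditions define the default cohort:
label prevalence ≈ 0.14 and a female:male odds ratio ≈ 2 for the binary
label. `baseline_logit = −2.53` was found by bisection
(`calibrate_baseline_logit`, reproducible in-package), and the per-trial
female coefficient is 0.65: because the liability has spread ≈ 1.6 logit
units, a per-trial shift attenuates in the ≥ 11 tail, so the coefficient
needed for a tail OR of 2 is noticeably smaller than `log 2` would suggest
only on the per-trial scale — empirically 0.65 gives a tail OR ≈ 2.1.
Behavioural covariates (sleep, coffee, alcohol group, smoking, physical
activity, marital/parental/employment status) and the four metabolism
marker genotypes are drawn from realistic marginal frequencies with small
per-trial liability effects in the directions observed in the
epidemiological literature; they are conditions of the simulation, not
quantities the tests tune.

Note that prevalence depends on the total liability variance: configurations
with many strong causal variants thicken the score's upper tail, so
prevalence rises above 0.14 unless `baseline_logit` is recalibrated for
that configuration.

**What it does not emulate.** Linkage disequilibrium (variants are
independent), real allele-frequency spectra, chromosome maps, sample-level
artifacts (batch effects, call-rate variation, relatedness), and
genotype–covariate correlation beyond what population structure induces.
Tests passing on this generator therefore demonstrate the *statistical
machinery* — calibration, confounding control, leakage-free model
selection — not performance on real cohort data.

## Variant QC

Filters run in a fixed order — non-PASS, multiallelic, Hardy–Weinberg,
minor allele frequency — and each removal count is taken against the set
surviving the previous filter, so the report ledger always adds up.
The HWE test is the exact conditional test: conditioning on observed
allele counts, the p-value sums the probabilities of all heterozygote
counts no more probable than the observed one (tolerance factor 1+10⁻¹²
against ties at machine precision). Probabilities come from the standard
two-sided recurrence over heterozygote counts, O(rare-allele count) per
variant; beyond a configurable cost bound (default 10⁷) a 1-df chi-square
goodness-of-fit approximation substitutes. The test uses all samples
(cases and controls together), and missing genotypes are excluded from
both the HWE counts and the MAF denominator — no imputation at QC stage.
A variant with MAF exactly at the 1% threshold is retained (the rule
removes frequencies *below* the cutoff). A fully missing variant cannot
demonstrate MAF above a positive threshold and is removed under the MAF
flag; with `maf_min = 0` the filter is the identity.

## Structure PCA

A uniform random subsample (default 15,000) of variants with MAF ≥ 5%
stands in for a fixed genotyping-array manifest, which is not reproducible.
Missing dosages are mean-imputed per variant; columns are centered and
scaled to unit sample standard deviation (allele-frequency 2p(1−p) scaling
is a configurable alternative we do not default to, as results at these
scales are indistinguishable and sample SD needs no frequency model);
zero-variance columns are dropped. The decomposition is a full SVD, and
each component's sign is fixed by making its largest-magnitude loading
positive, so results are bit-reproducible. If the requested component
count exceeds the matrix rank it is reduced with a warning.

The stability diagnostic repeats select-and-decompose over independent
subsamples and reports the mean over runs and component indices of
`1 − |Pearson r|` between each run's scores and a reference run. The
metric is scale- and sign-invariant and directly thresholdable: below
0.05 counts as stable. With two simulated populations only one axis is
structural, so stability should be assessed at the number of expected
structure axes (populations − 1); trailing noise components are unstable
by construction.

## Association scans

Per variant, complete-case on that variant's non-missing dosages:

* binary label — maximum-likelihood logistic regression fitted by
  iteratively reweighted least squares (convergence when the largest
  coefficient update < 10⁻⁸, at most 100 iterations; working weights
  floored at 10⁻¹²), two-sided Wald p-value for the dosage term;
* continuous score — ordinary least squares on the raw 0–21 score (no
  rank-normalization), two-sided t-test.

A variant that fails — constant dosage, single outcome class, rank
deficiency, separation (detected as coefficient divergence beyond 10³),
or non-convergence — yields an *unfit* row with no p-value rather than an
unstable estimate; unfit rows are excluded from significance calling and
PRS selection, which protects the SNP-score ranking from pathological
β/p ratios. The per-variant age and sex coefficients and the intercept are
stored in every row because the PRS selection score consumes them.
P-values are floored at 10⁻³⁰⁰ so downstream ratios never divide by zero.

Genome-wide significance is the strict inequality p < 5×10⁻⁸. The genomic
inflation factor λ_gc is the median of the 1-df chi-square statistics
implied by the p-values divided by the theoretical null median (≈ 0.4549).
λ_gc from a single phenotype realization has sampling spread of a few
percent even at several thousand variants, so calibration checks average
it over phenotype replicates.

## Polygenic risk score

The procedure holds out a stratified 10% test set first; the per-variant
GWAS used for SNP scoring runs on the remaining 90% only (leakage guard),
which is then split 80/20 into training and validation, all stratified by
the anxiety label and reproducible from the seed.

Each fitted SNP's selection score is `(β_SNP / p) · β_age + β_sex +
intercept` (the "literal" parse). The printed form of this score in the
source analysis is typographically ambiguous, so a "magnitude" parse
`(β_SNP / p) · (β_age + β_sex + intercept)` is available behind a config
switch; neither is presented as certain. The original "threshold chosen at
random" step is replaced by a deterministic sweep over 20 evenly spaced
quantiles of the score distribution, for reproducibility. For each
threshold, SNPs with score ≥ threshold join age, sex and PC1–10 as
features; thresholds selecting no SNPs are skipped.

The ridge fit is the closed-form minimiser of squared error plus λ times
the sum of squared coefficients, intercept unpenalized, computed on
internally standardized features with coefficients returned on the
original scale; when features outnumber samples the equivalent dual
(kernel) system is solved. λ defaults to 1.0 on standardized features and
is *not* tuned inside the sweep — only the threshold is. At λ = 0 a
singular system raises an error advising λ > 0. The binary outcome is fit
with the squared-error objective (linear-probability ridge) rather than
logistic ridge: predictions serve only as ranking scores for ROC AUC,
where monotone transformations and calibration are irrelevant.

The model with the highest validation AUC wins; ties go to fewer SNPs
(the sweep visits thresholds from the sparsest downward and keeps strictly
better AUCs). The selected model is evaluated once on the test set, next
to two covariate-only baselines (age+sex, and age+sex+PCs) fitted with the
same ridge machinery. ROC AUC is the midrank Mann–Whitney statistic, so
ties count one half.

## Epidemiological statistics

Crude odds ratios come from 2×2 tables as (a·d)/(b·c) with Woolf 95%
confidence intervals on the log scale; the two-sided p-value is a
chi-square test, continuity-corrected when any cell is below 5, and a
Haldane–Anscombe 0.5 correction is applied (and flagged) only when a zero
cell occurs. Adjusted ORs exponentiate logistic coefficients with age and
sex as covariates; separation and non-convergence are flagged, not raised.
Caffeine- and alcohol-metabolism groups count risk substitutions across
their two marker genotypes (caffeine: rs762551 AC/CC, rs5751876 TT;
alcohol: rs671 AG/AA, rs1229984 CT/TT); both assignment functions are
total over their genotype alphabets. Per-group score summaries use a
two-sided one-sample t-test of each group against the overall cohort mean.
Multiple testing uses plain Bonferroni, `min(1, m·p)`. The multivariate
lifestyle model one-hot encodes categorical variables against fixed
reference levels (never-married, alcohol group 1, no children) and reports
in-sample ROC AUC; in-sample AUC carries optimism of a few hundredths from
the ~12 fitted parameters, which the permutation-null tests account for.

## Problem sizes in the test and acceptance runs

Simulated checks use cohorts of 1,000–3,000 samples and 5,000–10,000
variants: large enough that λ_gc, type-I error and AUC estimates have
useful precision (binomial/median standard errors of a few thousandths to
a few hundredths), small enough to iterate on. Null calibration uses
10,000 variants at n = 1,000; confounding control uses 6,000 variants at
n = 2,500 with λ averaged over three phenotype replicates; the PRS
experiment uses n = 3,000 with 5,000 variants, 20 causal variants of
effect SD 0.5 ("strong" effects, so selection has signal to find) in a
single unstructured population — structure is deliberately absent there so
the covariate-only baseline measures covariates alone and the PRS gain is
attributable to the SNPs; the permutation null averages five permuted
refits of the whole pipeline (a single permuted test AUC at 300 test
samples has SD ≈ 0.05).

## Known limitations

* No LD: selection and clumping behaviour on correlated variants is
  untested; there is no LD pruning before PCA and no clumping in the PRS.
* Linear-probability ridge is used for a binary outcome; only its ranking
  is meaningful, never its predicted values as probabilities.
* The exact HWE test's chi-square fallback is an approximation for
  extremely large allele counts.
* Sample-level QC (call rate, heterozygosity, relatedness) is out of
  scope.
* The per-variant scan is embarrassingly parallel (`n_jobs`), but memory
  is dense: dosages are held as a full samples × variants float matrix.
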