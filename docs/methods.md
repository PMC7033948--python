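# Methods

This note documents the models, estimators and numerical choices behind
`stratwas`, and what the synthetic-cohort experiments do and do not show.

## Synthetic cohorts

The generator (`stratwas.simcohort`) emulates the data structure of a
two-ancestry tumor-expression cohort, not any particular dataset.

**Genotypes.** Ancestral allele frequencies are drawn uniformly from
`maf_range`; two ancestral populations ("afr", "eur") receive
Balding–Nichols frequencies `p_s ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with
differentiation parameter `fst` (default 0.15, typical of African/European
comparisons). Haplotypes carry first-order autoregressive dependence: a
latent Gaussian AR(1) chain with autocorrelation `ld_decay` (default 0.9)
is thresholded at `Φ⁻¹(p)` per locus, which produces geometrically decaying
LD while keeping every marginal allele frequency exactly on target (a
literal allele-copying chain would bias marginals whenever frequencies vary
along the chromosome). The chain restarts at each gene's cis-window
boundary: gene blocks are tiled 1.2 Mb apart on one synthetic chromosome,
so cis/trans labels are unambiguous and blocks are genuinely unlinked.
The "WW" stratum draws haplotypes from one population; "AA" samples are
admixed with per-sample proportion `θ ~ Beta(α, α/4)` (mean 0.8 at the
default `admixture_alpha = 8`) and a per-haplotype Markov ancestry chain
(switch rate 0.05 per variant step). The latent ancestry dosage is exposed
directly as ground truth; no ancestry inference is simulated.

**Expression.** `E_g = X_g w_g + X_C β_C + ε` with `n_causal_cis` causal
cis variants per gene (default 3), weights rescaled so the realized genetic
variance fraction equals the configured cis-h²; covariates (age-like,
binary status, two PC surrogates) jointly contribute `covariate_var_frac`
(default 0.10) of the variance; ε is Gaussian. Causal sets and weights are
shared across strata by default; `stratum_specific_causals=True` draws them
independently per stratum, the regime in which cross-ancestry portability
visibly degrades at desk scale.

**Survival.** Latent times for the primary cause, the competing cause and
censoring are exponential with rates proportional to
`(event_rate, competing_rate, censor_rate)` — defaults (0.09, 0.085,
0.825), matching a cohort where roughly 9% die of the disease, a similar
fraction of other causes, and the rest are censored. The primary-cause
hazard multiplies `exp(β_g · GReX_g / sd + 0.2 · age_std)` using the *true*
genetic values. With all-exponential latent times the expected cause
fractions equal the configured rates exactly at null effect, with no tuning
loop.

**GWAS summary statistics.** `Z ~ N(√n · R b, R)` with `R` the realized
LD correlation of the reference panel (ridge-stabilized, ε = 1e-6) and `b`
standardized liability effects; monomorphic variants are dropped.

**What the generator does not emulate:** recombination maps, imputation
error, count-level (Nanostring-like) measurement noise, a mechanism for
ancestry-asymmetric trans-eQTLs (trans effects are parameterized per
stratum without one), or any relationship between expression and tumor
subtype labels. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
artifact of real tumor expression data.

## QC and normalization

Hardy–Weinberg uses a mid-p exact test on rounded hard calls (log-space
recurrence over heterozygote counts), the convention matching PLINK's
`--hardy midp`; variants fail at p < 1e-8. MAF is dosage-based with a 1%
default floor. Missing dosages are mean-imputed per variant at read time
(fraction logged) because all downstream linear algebra assumes complete
matrices. Panel intersection keys on (chrom, pos, ref, alt) and harmonizes
swapped alleles by reflecting dosages (2 − d).

Expression normalization chains upper-quartile scaling to the mean upper
quartile, `log2(x+1)` as the variance-stabilizing transform (the exact VST
used on count platforms is platform-specific; downstream methods only need
approximate homoskedasticity), and removal of `k_unwanted = 2` factors
taken as the top left-singular vectors of the centered control-gene
submatrix, regressed out of every gene with the grand mean retained.
Outlier flagging uses a robust (median/MAD) Mahalanobis distance on the top
two principal scores against the χ²(2) upper-α quantile; the criterion is a
documented choice, and α = 0 disables it. Rank-deficient covariate designs
drop later-listed collinear columns deterministically, with a warning.

## eQTL mapping

The scan residualizes expression and dosages on the covariate design once
(QR) and runs per-pair simple regressions with degrees of freedom
`n − p_cov − 1` — numerically identical to the joint model by
Frisch–Waugh–Lovell (asserted to 1e-8 in tests). Cis means distance ≤
500 kb from either gene end.

Hierarchical error control is two-stage: Simes combination per gene, BH
across genes at level 0.05 (selected genes = eGenes), then BH within each
selected gene at level × R/G. The reported `bbfdr` is the within-gene
BH-adjusted p rescaled by G/R (floored at the raw p, capped at 1), so
`bbfdr < level` inside a selected gene reproduces the stage-2 rejection
rule; eSNP = that event. Under a global-null simulation the fraction of
replicates with any false eGene stays at or below the nominal level
(acceptance suite, 200 replicates).

Local-ancestry adjustment residualizes expression, SNP dosage and ancestry
dosage on the covariates, standardizes each, and fits `g̃ ~ s̃ + l̃`;
zero-variance inputs are flagged, not fitted. Enrichment compares the
observed count of eSNPs within 1 kb of an annotation against the mean of
10,000 equal-size draws from the tested background, then applies Fisher's
exact test to the observed-vs-rounded-expected 2×2 table (Woolf logit 95%
CI); a tiling annotation yields a degenerate margin and is reported as an
infinite odds ratio.

## Cis-heritability

Cis variants are standardized and binned by MAF quantiles × LD-score
quantiles (LD score = sum of squared correlations with cis neighbours,
self included); each non-empty bin contributes a GRM `ZZ'/m`. Defaults are
2 × 2 bins at desk scale, exercising the stratified machinery with few
variants; the n = 1000 recovery suites use a single bin, where one
eigendecomposition makes every REML iteration O(n).

REML maximizes the restricted likelihood by average-information steps with
an active-set treatment of the non-negativity boundary (components pinned
at 1e-6·var(y) with non-positive score leave the Newton system), step
halving on overshoot, and EM fallback; convergence at log-likelihood change
< 1e-6 or 100 iterations, non-convergence flagged rather than hidden. The
single-GRM path is algebraically the same update sequence computed in the
GRM eigenbasis and agrees with a 1-D profile-likelihood grid oracle to
better than 0.01 in h². The LRT against the no-genetics null (closed-form
restricted likelihood) uses the boundary mixture
`p = 0.5·P(χ²₁ > LRT)` — a single aggregate test even with multiple
components, giving one nominal p per gene; genes pass at p < 0.10. Per-gene
SEs come from the delta method on the inverse AI matrix.

Note the estimand: h² is the genetic fraction of the *covariate-residual*
variance. When covariates carry variance, this exceeds the share of total
expression variance by the factor 1/(1 − covariate fraction); recovery
suites therefore simulate with zero covariate variance so the target is the
configured h² itself.

## Expression models

Feature set: cis window plus trans-eQTLs at BBFDR < 0.01. LD pruning is the
greedy sliding-window rule (window 50, step 5, r² > 0.5 removes the
later-positioned member). Two schemes share seeded fivefold folds:

- elastic net, mixing 0.5, λ minimizing CV MSE (scikit-learn path);
- BLUP: single-GRM REML variance components, weights = ridge with
  λ* = m·σ²_e/σ²_g in standardized coordinates, mapped back to the dosage
  scale (equal to the dual closed form to 1e-8); σ²_g at the boundary
  yields flagged all-zero weights.

CV R² is the squared Pearson correlation of out-of-fold predictions (0 if
they are constant); ties prefer the elastic net (sparser, cheaper to
impute). Weights are defined on covariate-residualized expression —
consumers must not re-add covariate effects. Selection inflation under the
null is bounded (median winning CV R² < 0.02 across null genes). A third,
sparse-mixed-model scheme is deliberately not registered; the registry is
{enet, blup} and `select_scheme` accepts any registered name.

## GReX validation

Imputation matches model variants by (chrom, pos, ref, alt), reflects
swapped alleles, drops unmatched variants (match rate logged) and omits
genes with zero matches. EV R² is the squared Spearman correlation —
deliberately rank-based, in contrast to the Pearson-based training CV R²;
both are recorded.

The permutation machinery permutes observed expression among samples
(within subgroup when stratified — exchangeability holds there), computes
the null of squared rank correlations, and reports the add-one empirical
p = (1 + #{null ≥ observed}) / (1 + B), never exactly zero and valid by
construction. Storey q-values use a fixed λ = 0.5 for π₀ (package versions
disagree on adaptive defaults), clipped to [1/m, 1].

**CI construction.** The 90% interval inverts the permutation acceptance
region via a translation pivot on the Fisher z-transform of the signed rank
correlation: `atanh(ρ)` has approximately constant sampling variance at any
true ρ, so the centered permutation null of z is a valid pivot away from
the null as well; the z-interval is mapped through `tanh` and squared (an
interval straddling zero maps to [0, max²]). A pivot on the raw R² scale is
*not* valid away from the null — its measured coverage at true rank-ρ² =
0.25, n = 100 is ≈ 0.21 versus ≈ 0.89 for the stabilized pivot — which is
why the stabilized scale is used. Coverage is verified by simulation in the
acceptance suite (1000 replicates, n = 100), and the duality "CI excludes 0
iff empirical p < 1 − level" holds up to quantile resolution. Degenerate
nulls and `level = 0` return point intervals.

## Survival association

Cause-specific Cox models treat competing-cause deaths and losses to
follow-up as censoring; fits use partial likelihood with Efron ties
(lifelines), so the baseline hazard λ₀k is never estimated. Exposures are
standardized, making `log_hr` the log-hazard per SD of GReX. Strata are
fully separate fits, never a shared-baseline stratified model. A
non-converging fit retries with a light ridge and is flagged. An
independent score-test helper (Breslow risk sets) equals the log-rank
statistic on two-group no-ties data and anchors the cross-check of the
fitted maximizer against a hand-evaluated partial-likelihood gradient.

**Empirical-null correction.** TWAS Z-statistics are modelled as a
three-component Gaussian mixture fitted by Gibbs sampling with conjugate
updates. Identification of the central (null) component is by prior:
weights Dirichlet(90, 5, 5), means N(0, 3²) / N(∓4, 4²), variances
inverse-gamma(3, 2); 5000 iterations with 2000 burn-in, seed-fixed, and a
split-R̂ diagnostic on the null-mean chain warns above 1.1. Bias and
inflation are the posterior means of the null component's location and
scale; corrected z = (z − bias)/inflation. Panels below 20 statistics skip
the correction (BH on raw p instead) — an empirical null is meaningless at
that size. Recovery of (bias, inflation) = (0.5, 1.3) from contaminated
draws is part of the acceptance suite.

BH at FDR 0.10 yields the final calls. The survival GWAS reuses the same
Cox routine per variant; conditional analysis appends the top cis survival
SNP's dosage to the covariates and flags |corr(GReX, SNP)| > 0.99 as
unstable rather than fitting. The burden test takes W as the trained model
weights (the operational stand-in for Σ_es Σ_ss⁻¹), Σ_ss from reference-
panel dosages with ridge ε = 1e-3, and is invariant to consistent allele
flips of (weights, Z, LD).

## Power

Both power analyses draw exponential event times under a
proportional-hazards effect, apply uniform censoring whose horizon is
bisection-tuned so the expected event fraction hits the target (10%
default), fit the Cox model and count Wald rejections; the 90th percentile
of event times is recorded as a landmark. The GWAS scenario: n = 3828,
per-allele log-hazard, risk-allele frequency 0.1, α = 1.70e-8. The TWAS
scenario resamples an observed GReX vector with replacement and loads the
hazard per raw GReX unit — so better-predicted (higher-variance) GReX gives
more power at the same hazard ratio — at α = 0.0096.

## Problem sizes

Chosen once as the desk-scale analogues of the study conditions: training
strata of ~600 samples (expression cohorts), survival testing at n = 1900
(one stratum of a ~3800-sample survival cohort), panels of 10–20 genes with
20–100 cis variants each. Replicate counts: 50 (REML recovery, n = 1000),
200 (Cox recovery at HR 1.3, n = 3000; hierarchical-FDR null), 300–500
(LRT and Cox type-I calibration), 1000 (CI coverage), 12 (end-to-end
planted-gene recovery, each a full train-impute-test cycle). The end-to-end
scenario plants two survival genes at |HR| = 1.4 per SD of true GReX on
weakly predicted expression (cis-h² = 0.1, CV R² ≈ 0.03–0.12) among eight
null genes.

## Known limitations

- The empirical-null sampler can mix slowly on small or heavily
  contaminated panels; the split-R̂ warning is advisory, not a gate.
- The HWE test uses hard calls rounded from dosages; heavily imputed
  low-quality dosages blur the test's meaning.
- `hierarchical_fdr` builds one family per gene over all its tested
  variants (cis and trans together); separate cis/trans hierarchies are not
  implemented.
- Burden-test weights from a sparse elastic net can match very few summary
  statistics; the match rate is logged and zero matches raise.
- FDR-adjusted confidence intervals for hazard ratios are not constructed;
  Wald intervals accompany the BH-adjusted p-values.
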