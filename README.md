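# stratwas

Ancestry-stratified transcriptome-wide association (TWAS) for disease
outcomes, built as a tested, reusable Python pipeline and exercised end to
end on synthetic two-ancestry cohorts with known ground truth.

## The problem

Germline genotype shapes tumor gene expression through cis- (and
occasionally trans-) eQTLs, and eQTL architecture differs between ancestry
groups: allele frequencies, LD, and admixture all vary, so a single
expression model trained in one population ports poorly to another.
`stratwas` implements the stratified workflow used to study such questions
in two-ancestry breast-cancer cohorts: everything — eQTL mapping,
heritability filtering, model training, survival testing — is run separately
per stratum, and validation explicitly accounts for the sampling variability
that small subgroups (a rare subtype, one ancestry group) induce.

## The pipeline

1. **QC and normalization** (`stratwas.gdata`): dosage-based MAF ≥ 1%,
   Hardy-Weinberg exact test (mid-p) at p ≥ 1e-8, panel intersection with
   allele harmonization; upper-quartile expression normalization, log2
   variance stabilization, removal of k factors of unwanted variation
   estimated from housekeeping controls, PCA outlier flagging, covariate
   residualization `Ẽ_g = E_g − X_C β̂_C`.
2. **eQTL mapping** (`stratwas.eqtl`): per (gene, variant) Wald test of
   `E_g = X_s β_s + X_C β_C + ε`; cis = within 500 kb of either gene end;
   hierarchical (Benjamini–Bogomolov) FDR — Simes gene-level p, BH across
   genes, then BH within selected genes at a rescaled level; eSNP/eGene
   calls at BBFDR < 0.05. Local-ancestry adjustment `g̃ ~ s̃ + l̃` and
   annotation enrichment (resampled expected counts + Fisher exact test).
3. **Cis-heritability** (`stratwas.herit`): MAF x LD-score stratified GRMs,
   multi-component AI-REML (EM fallback, non-negativity), cis-h² with a
   0.5·χ²(0) + 0.5·χ²(1) boundary LRT; genes kept at nominal p < 0.10.
4. **Expression models** (`stratwas.predmodel`): feature set = cis window
   plus trans-eQTLs at BBFDR < 0.01, LD-pruned (window 50, step 5,
   r² ≤ 0.5); weights `ŵ_g` by elastic net (α = 0.5, CV-tuned λ) or
   single-GRM BLUP (ridge with λ* = m·σ²_e/σ²_g), winner by shared
   fivefold CV R² (squared Pearson); models used downstream when
   CV R² > 0.01. Both schemes are scikit-learn estimators.
5. **GReX and validation** (`stratwas.grexval`): `GReX_g = X_g,new ŵ_g`
   with allele-swap reflection; EV R² = squared Spearman correlation of
   imputed vs observed expression; 10,000-permutation empirical p, Storey
   q-values at FDR 0.05, and 90% CIs by inverting the permutation
   acceptance region on a variance-stabilized scale — overall and per
   subgroup.
6. **Survival TWAS** (`stratwas.assoc`): cause-specific Cox model
   `λ_k(t) = λ_0k(t) exp(GReX_g β_g + Z_C β_C)` with competing deaths
   treated as censoring; TWAS Z-statistics recalibrated against an
   empirical null (central component of a three-part Gaussian mixture,
   Gibbs-fitted); BH at FDR 0.10; SNP-level survival GWAS comparison,
   conditional adjustment for the top cis survival SNP, and the weighted
   burden test `Z̃ = WZ / (W Σ_ss W')^{1/2}` against external GWAS
   summary statistics.
7. **Power** (`stratwas.power`): simulation-based power of the survival
   GWAS (n = 3828, α = 1.70e-8, risk-allele frequency 0.1, 10% events) and
   of the GReX survival test (α = 0.0096) over an empirical GReX
   distribution.
8. **Synthetic cohorts** (`stratwas.simcohort`): Balding–Nichols
   differentiated allele frequencies, AR(1)-correlated haplotypes restarted
   per gene block, admixed local ancestry, sparse cis + rare trans eQTL
   architecture, covariate-driven nuisance variation, and competing-risks
   survival loaded on true GReX — with every ground-truth quantity exposed.

## Worked example

```python
import numpy as np
import stratwas as sw
from stratwas import pipeline

cfg = sw.SimConfig(n_samples_per_stratum=400, n_genes=6,
                   n_variants_per_gene_cis=20, n_trans_variants=4,
                   cis_h2_per_gene=0.3, survival_beta={"gene000": np.log(1.5)},
                   seed=7)
coh = sw.simulate_cohort(cfg)
res = pipeline.run_twas_pipeline(coh.genotypes, coh.expression,
                                 coh.covariates, coh.survival, coh.genes,
                                 seed=1)
print(res.twas["AA"][["gene", "hr", "z", "p_raw", "p_fdr", "significant"]]
      .round(4).to_string(index=False))
```

prints

```
   gene     hr       z  p_raw  p_fdr  significant
gene000 1.5116  2.7610 0.0058 0.0346         True
gene001 1.1000  0.5223 0.6014 0.6014        False
gene002 1.3628  1.8468 0.0648 0.1943        False
gene003 0.8848 -0.7536 0.4511 0.5900        False
gene004 0.8441 -0.9363 0.3491 0.5900        False
gene005 1.1278  0.6876 0.4917 0.5900        False
```

`gene000` was planted with a true hazard ratio of 1.5 per SD of its
genetically regulated expression; the pipeline estimates HR ≈ 1.51 and it
is the only call at FDR 0.10.  Upstream, all six genes pass the
heritability filter (cis-ĥ² ≈ 0.27–0.40 against a simulated 0.3, each with
boundary-LRT p ≈ 0) and train models with CV R² ≈ 0.23–0.37.

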