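"""End-to-end orchestration: from genotypes + expression to survival TWAS.

Stages are the public functions of the stage modules; this module only
wires them together in the order the analysis prescribes:

1. residualize expression on the eQTL covariates,
2. stratified cis/trans eQTL scan + hierarchical FDR,
3. per-gene cis-heritability, keep genes with LRT p < 0.10,
4. train per-(gene, stratum) expression models, keep CV R^2 > 0.01,
5. impute GReX into the target panel,
6. cause-specific survival TWAS with empirical-null correction and BH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import assoc, eqtl, gdata, grexval, herit, predmodel
from .containers import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class TwasPipelineResult:
    eqtl_results: dict
    heritability: dict
    heritable_genes: dict
    models: dict
    grex: dict
    twas: dict
    bacon: dict
    extras: dict = field(default_factory=dict)


def run_twas_pipeline(
    genotypes: dict,
    expression: dict,
    covariates: dict,
    survival: dict,
    gene_table: pd.DataFrame,
    target_genotypes: dict | None = None,
    survival_covariates: dict | None = None,
    cis_window: int = 500_000,
    h2_p_max: float = 0.10,
    cv_r2_min: float = 0.01,
    n_maf_bins: int = 2,
    n_ld_bins: int = 2,
    fdr: float = 0.10,
    bacon_iterations: int = 2000,
    bacon_burn_in: int = 500,
    seed: int = 0,
    run_eqtl: bool = True,
    min_bacon: int = 20,
) -> TwasPipelineResult:
    """Run the stratified TWAS pipeline on aligned per-stratum containers.

    ``target_genotypes`` defaults to the training panels (imputation into
    the survival cohort itself); pass held-out panels for external
    validation scenarios.
    """
    if target_genotypes is None:
        target_genotypes = genotypes
    if survival_covariates is None:
        survival_covariates = covariates
    eqtl_results, heritability, heritable, resid = {}, {}, {}, {}
    for stratum, g in genotypes.items():
        e = expression[stratum]
        c = covariates[stratum]
        resid[stratum] = gdata.residualize(e, c)
        if run_eqtl:
            scan = eqtl.scan_eqtl(e, g, c, cis_window=cis_window)
            eqtl_results[stratum] = eqtl.hierarchical_fdr(scan)
        ests = []
        for _, gene in gene_table.iterrows():
            try:
                ests.append(herit.estimate_cis_h2(
                    g, resid[stratum].column(gene["id"]), gene,
                    cis_window, n_maf_bins, n_ld_bins))
            except Exception as err:  # < 2 cis variants etc.
                log.warning("h2 %s/%s failed: %s", stratum, gene["id"], err)
        heritability[stratum] = ests
        heritable[stratum] = herit.select_heritable_genes(ests, h2_p_max)

    models = predmodel.train_all(
        genotypes, resid, gene_table, heritable,
        eqtl_results=eqtl_results if run_eqtl else None, seed=seed)
    usable = {k: m for k, m in models.items() if m.cv_r2 > cv_r2_min}

    grex, twas, bacon = {}, {}, {}
    for stratum in genotypes:
        strat_models = [m for (s, _), m in usable.items() if s == stratum]
        if not strat_models:
            continue
        gx = grexval.harmonize_and_impute(strat_models,
                                          target_genotypes[stratum])
        grex[stratum] = gx
        surv = survival[stratum]
        cov = survival_covariates[stratum]
        scan = assoc.twas_scan(gx, _survival_covariates(cov), surv,
                               stratum=stratum)
        if scan["z"].notna().sum() >= min_bacon:
            scan, fit = assoc.finalize_twas(
                scan, iterations=bacon_iterations, burn_in=bacon_burn_in,
                seed=seed, fdr=fdr)
            bacon[stratum] = fit
        else:
            # too few genes for a stable empirical null: BH on raw p
            scan = scan.copy()
            ok = scan["p_raw"].notna()
            scan["z_corrected"] = scan["z"]
            scan["p_corrected"] = scan["p_raw"]
            adj, calls = assoc.bh_adjust(scan.loc[ok, "p_raw"].to_numpy(), fdr)
            scan.loc[ok, "p_fdr"] = adj
            scan["significant"] = False
            scan.loc[ok, "significant"] = calls
        twas[stratum] = scan
    return TwasPipelineResult(eqtl_results, heritability, heritable,
                              usable, grex, twas, bacon)


def _survival_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Survival-model covariates: age-like and status-like columns only."""
    keep = [c for c in cov.columns if c in ("age", "status", "er", "stage", "phase")]
    return cov[keep] if keep else cov.iloc[:, :0]
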