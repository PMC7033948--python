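"""Stratified cis/trans eQTL scanning with hierarchical FDR control.

The scan fits, per (gene, variant) pair, the additive model
``E_g = X_s beta_s + X_C beta_C + eps`` and Wald-tests ``beta_s = 0``.
Associations are labelled cis when the variant lies within ``cis_window``
of either gene end and trans otherwise.  Multiplicity is controlled with a
two-stage Benjamini-Bogomolov hierarchy: Simes-combined gene-level p-values
are BH-adjusted across genes, then variant-level p-values are BH-adjusted
within each selected gene at a level scaled by the gene-selection fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GenotypeMatrix, StratwasError, align_samples
from .gdata import design_matrix, residualize_vector


def cis_distance(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    """Distance from variant position to the nearest gene end (0 inside)."""
    return np.maximum.reduce([np.zeros_like(pos), start - pos, pos - end])


def scan_eqtl(
    e: ExpressionMatrix,
    g: GenotypeMatrix,
    c: pd.DataFrame | None = None,
    cis_window: int = 500_000,
    subtypes: pd.Series | None = None,
    exclude_subtypes: tuple = ("Normal-like",),
) -> pd.DataFrame:
    """All-pairs covariate-adjusted eQTL scan.

    Samples whose subtype label is in ``exclude_subtypes`` are dropped
    before fitting.  Returns one row per (gene, variant) with columns
    gene, variant, chrom, pos, ref, alt, beta, se, t, p, type.
    """
    if subtypes is not None:
        keep = [s for s in e.samples
                if s not in subtypes.index or subtypes.loc[s] not in exclude_subtypes]
        e = e.take_samples([s for s in e.samples if s in set(keep)])
    if c is not None:
        e, g, c = align_samples(e, g, c)
    else:
        e, g = align_samples(e, g)
    n = e.n_samples
    x_c = design_matrix(c, n=n)
    p_cov = x_c.shape[1]
    if n < p_cov + 2:
        raise StratwasError(f"need at least covariates+2 samples, have {n}")

    # Frisch-Waugh: residualize both sides on covariates, then per-variant
    # simple regression with df = n - p_cov - 1
    q, _ = np.linalg.qr(x_c)
    e_res = e.values - q @ (q.T @ e.values)
    g_res = g.dosages - q @ (q.T @ g.dosages)
    gg = (g_res ** 2).sum(axis=0)
    gg_safe = np.where(gg > 0, gg, np.nan)
    cross = g_res.T @ e_res                      # variants x genes
    beta = cross / gg_safe[:, None]
    ee = (e_res ** 2).sum(axis=0)
    df = n - p_cov - 1
    sse = np.maximum(ee[None, :] - beta ** 2 * gg_safe[:, None], 0.0)
    sigma2 = sse / df
    se = np.sqrt(sigma2 / gg_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pval = 2.0 * stats.t.sf(np.abs(t), df)

    v = g.variants
    pos = v["pos"].to_numpy()
    rows = []
    for gi in range(e.n_genes):
        gene = e.genes.iloc[gi]
        dist = cis_distance(pos, gene["start"], gene["end"])
        same_chrom = (v["chrom"] == gene["chrom"]).to_numpy()
        is_cis = same_chrom & (dist <= cis_window)
        rows.append(pd.DataFrame({
            "gene": gene["id"],
            "variant": v["id"].to_numpy(),
            "chrom": v["chrom"].to_numpy(),
            "pos": pos,
            "ref": v["ref"].to_numpy(),
            "alt": v["alt"].to_numpy(),
            "beta": beta[:, gi],
            "se": se[:, gi],
            "t": t[:, gi],
            "p": pval[:, gi],
            "type": np.where(is_cis, "cis", "trans"),
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.dropna(subset=["p"]).reset_index(drop=True)


def simes(p: np.ndarray) -> float:
    """Simes combination of a family of p-values."""
    p = np.sort(np.asarray(p, float))
    m = p.size
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def hierarchical_fdr(records: pd.DataFrame, level: float = 0.05) -> pd.DataFrame:
    """Two-stage Benjamini-Bogomolov adjustment over gene families.

    Stage 1: Simes gene-level p-values, BH across genes at ``level``; a
    selected gene is an eGene.  Stage 2: within each gene, BH across its
    variants at ``level * R / G`` (R selected of G genes); the reported
    ``bbfdr`` is the within-gene BH-adjusted p rescaled by G/R, so that
    ``bbfdr < level`` reproduces the stage-2 rejection rule.  Variants in
    selected genes with ``bbfdr < level`` are eSNPs.
    """
    if records.empty:
        raise StratwasError("no eQTL records to adjust")
    out = records.copy()
    gene_p = out.groupby("gene", sort=True)["p"].apply(lambda s: simes(s.to_numpy()))
    n_genes = len(gene_p)
    gene_adj = pd.Series(
        multipletests(gene_p.to_numpy(), method="fdr_bh")[1], index=gene_p.index
    )
    selected = gene_adj < level
    n_sel = int(selected.sum())
    factor = n_genes / max(n_sel, 1)

    bbfdr = np.empty(len(out))
    for gene, idx in out.groupby("gene", sort=False).groups.items():
        p = out.loc[idx, "p"].to_numpy()
        adj_within = multipletests(p, method="fdr_bh")[1]
        bbfdr[out.index.get_indexer(idx)] = np.minimum(1.0, adj_within * factor)
    out["bbfdr"] = np.maximum(bbfdr, out["p"].to_numpy())
    out["is_egene"] = out["gene"].map(selected).to_numpy()
    out["is_esnp"] = out["is_egene"] & (out["bbfdr"] < level)
    out.attrs["gene_p"] = gene_p.to_dict()
    out.attrs["gene_adjusted_p"] = gene_adj.to_dict()
    return out


def hard_call_maf_filter(records: pd.DataFrame, g: GenotypeMatrix,
                         maf_min: float = 0.05) -> pd.DataFrame:
    """Post-hoc eQTL QC: drop records whose variant fails a hard-call MAF cut.

    Dosages are rounded to additive genotype calls (0/1/2) and the minor
    allele frequency recomputed from those; significant eQTLs driven by a
    handful of fractional dosages at rare variants are removed this way.
    """
    hard = np.clip(np.rint(g.dosages), 0, 2)
    p = hard.mean(axis=0) / 2.0
    maf = pd.Series(np.minimum(p, 1 - p), index=g.variants["id"])
    keep = records["variant"].map(maf) >= maf_min
    return records[keep.fillna(False)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# local-ancestry adjustment
# ---------------------------------------------------------------------------

@dataclass
class AncestryAdjustedRecord:
    gene: str
    variant: str
    beta_unadjusted: float
    beta_ancestry_adjusted: float
    p_unadjusted: float
    p_adjusted: float
    flagged: bool = False


def _standardize_residual(v: np.ndarray, x_c: np.ndarray):
    r = residualize_vector(np.asarray(v, float), x_c)
    s = r.std()
    if s < 1e-12:
        return None
    return (r - r.mean()) / s


def adjust_local_ancestry(
    e_g: np.ndarray, s: np.ndarray, l: np.ndarray,
    c: pd.DataFrame | None = None,
    gene: str = "", variant: str = "",
) -> AncestryAdjustedRecord:
    """Local-ancestry-adjusted eQTL effect.

    Expression, SNP dosage and local-ancestry dosage are each residualized
    on the covariates, scaled to zero mean / unit variance, and the joint
    model ``g ~ s + l`` is fitted; the unadjusted effect comes from
    ``g ~ s`` on the same residualized-and-scaled vectors.
    """
    n = len(e_g)
    x_c = design_matrix(c, n=n)
    gt = _standardize_residual(e_g, x_c)
    st = _standardize_residual(s, x_c)
    lt = _standardize_residual(l, x_c)
    if gt is None or st is None or lt is None:
        return AncestryAdjustedRecord(gene, variant, np.nan, np.nan, np.nan, np.nan,
                                      flagged=True)

    def ols(y, x):
        xd = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
        resid = y - xd @ beta
        df = n - xd.shape[1]
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(xd.T @ xd)
        se = np.sqrt(np.diag(cov))
        tstat = beta / se
        p = 2 * stats.t.sf(np.abs(tstat), df)
        return beta[1], p[1]

    b0, p0 = ols(gt, st[:, None])
    b1, p1 = ols(gt, np.column_stack([st, lt]))
    return AncestryAdjustedRecord(gene, variant, float(b0), float(b1),
                                  float(p0), float(p1))


# ---------------------------------------------------------------------------
# annotation enrichment
# ---------------------------------------------------------------------------

def _near_interval(positions: np.ndarray, intervals: pd.DataFrame, window: int) -> np.ndarray:
    """True where a position lies within ``window`` of any interval (1-based)."""
    starts = intervals["start"].to_numpy() - window
    ends = intervals["end"].to_numpy() + window
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    # merge overlapping windows so a searchsorted test suffices
    m_starts, m_ends = [], []
    for s, e in zip(starts, ends):
        if m_ends and s <= m_ends[-1]:
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    m_starts = np.asarray(m_starts)
    m_ends = np.asarray(m_ends)
    idx = np.searchsorted(m_starts, positions, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(positions.shape, bool)
    hit[ok] = positions[ok] <= m_ends[idx[ok]]
    return hit


def enrichment_test(
    esnp_positions: np.ndarray,
    background_positions: np.ndarray,
    annotations: pd.DataFrame,
    window: int = 1000,
    n_reps: int = 10_000,
    seed: int = 0,
):
    """Resampling + Fisher enrichment of eSNPs near annotation intervals.

    Counts eSNPs within ``window`` of any interval, estimates the expected
    count from ``n_reps`` equal-size draws from the background, and runs a
    Fisher exact test on the observed-vs-expected 2x2 table.

    Returns (observed, expected_mean, odds_ratio, (ci_lo, ci_hi), p).
    """
    if window < 0:
        raise StratwasError("window must be non-negative")
    if annotations.empty:
        raise StratwasError("empty annotation set")
    esnp_positions = np.asarray(esnp_positions)
    background_positions = np.asarray(background_positions)
    k = esnp_positions.size
    if k == 0:
        raise StratwasError("no eSNPs to test")
    hit_bg = _near_interval(background_positions, annotations, window)
    observed = int(_near_interval(esnp_positions, annotations, window).sum())
    rng = np.random.default_rng(seed)
    draws = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(background_positions.size, size=k, replace=False)
        draws[r] = hit_bg[idx].sum()
    expected = float(draws.mean())
    exp_in = int(round(expected))
    table = np.array([[observed, k - observed], [exp_in, k - exp_in]])
    if (table[:, 1] == 0).any() or (table[:, 0] == 0).all():
        # degenerate margin: OR undefined/infinite
        orat = np.inf if observed > exp_in else (0.0 if observed < exp_in else 1.0)
        return observed, expected, orat, (np.nan, np.nan), 1.0
    orat, p = stats.fisher_exact(table)
    # Woolf logit interval
    with np.errstate(divide="ignore"):
        se = np.sqrt((1.0 / np.maximum(table, 0.5)).sum())
    lo = np.exp(np.log(orat) - 1.959963984540054 * se) if orat > 0 else 0.0
    hi = np.exp(np.log(orat) + 1.959963984540054 * se) if orat > 0 else np.inf
    return observed, expected, float(orat), (float(lo), float(hi)), float(p)
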