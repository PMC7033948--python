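"""Genotype QC, panel harmonization and expression normalization.

QC mirrors standard GWAS practice on dosage data: variants are dropped when
the dosage-based minor allele frequency falls below 1% or when a
Hardy-Weinberg exact test on rounded hard calls rejects at p < 1e-8.
Expression normalization chains upper-quartile scaling, a log2 variance
stabilization, and removal of unwanted-variation factors estimated from
housekeeping control genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix, GenotypeMatrix, StratwasError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (mid-p)
# ---------------------------------------------------------------------------

def hwe_midp_exact(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Mid-p Hardy-Weinberg exact test on hard genotype calls.

    Uses the standard recurrence over heterozygote counts conditional on the
    minor-allele count.  The mid-p variant sums probabilities strictly below
    the observed configuration plus half the observed probability, matching
    PLINK's ``--hardy midp`` behaviour.
    """
    n_het, n_hom_minor, n_hom_major = int(n_het), int(n_hom_minor), int(n_hom_major)
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * n_hom_minor + n_het       # minor allele count
    if rare > n:  # ensure "rare" really is the minor allele
        return hwe_midp_exact(n_het, n_hom_major, n_hom_minor)

    # het counts share the parity of the rare-allele count
    het_max = min(rare, 2 * n - rare)
    hets = np.arange(rare % 2, het_max + 1, 2)
    if hets.size == 0:
        return 1.0
    mid = int(np.searchsorted(hets, n_het))
    if mid >= hets.size or hets[mid] != n_het:
        raise ValueError("heterozygote count inconsistent with allele count")
    # log-space recurrence (overflow-safe for large panels):
    # P(h+2)/P(h) = 4*(n_a)(n_b) / ((h+2)(h+1)) with n_a, n_b hom counts at h
    logp = np.empty(hets.size)
    logp[0] = 0.0
    for i in range(1, hets.size):
        h = hets[i - 1]
        na = (rare - h) // 2          # minor homs at h
        nb = n - h - na               # major homs at h
        logp[i] = logp[i - 1] + np.log(4.0 * na * nb) - np.log((h + 2.0) * (h + 1.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[mid]
    # tolerance for FP equality in the tail definition
    lower = probs < p_obs * (1 - 1e-12)
    equal = ~lower & (probs <= p_obs * (1 + 1e-12))
    p = probs[lower].sum() + 0.5 * probs[equal].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# variant QC and panel intersection
# ---------------------------------------------------------------------------

def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-8,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants by dosage MAF and Hardy-Weinberg exact p.

    Returns the filtered panel and an exclusion report with one row per
    removed variant (columns: id, reason, value).
    """
    maf = g.maf()
    hard = np.clip(np.rint(g.dosages), 0, 2).astype(int)
    exclusions = []
    keep = np.ones(g.n_variants, bool)
    for j in range(g.n_variants):
        if maf[j] < maf_min:
            keep[j] = False
            exclusions.append((g.variants["id"].iloc[j], "maf", maf[j]))
            continue
        counts = np.bincount(hard[:, j], minlength=3)
        p_hwe = hwe_midp_exact(counts[1], counts[2], counts[0])
        if p_hwe < hwe_p_min:
            keep[j] = False
            exclusions.append((g.variants["id"].iloc[j], "hwe", p_hwe))
    if not keep.any():
        raise StratwasError("QC removed every variant (empty panel)")
    report = pd.DataFrame(exclusions, columns=["id", "reason", "value"])
    return g.take_variants(np.flatnonzero(keep)), report


def intersect_panels(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Restrict two panels to shared variants keyed by (chrom, pos, ref, alt).

    A variant present in ``b`` with ref/alt swapped relative to ``a`` is
    harmonized by reflecting its dosage (2 - d) and noted in the report.
    Order follows panel ``a``.
    """
    key_a = {k: i for i, k in enumerate(a.variant_keys())}
    key_b = {k: i for i, k in enumerate(b.variant_keys())}
    idx_a, idx_b, flip, notes = [], [], [], []
    for k, ia in key_a.items():
        chrom, pos, ref, alt = k
        if k in key_b:
            idx_a.append(ia)
            idx_b.append(key_b[k])
            flip.append(False)
        elif (chrom, pos, alt, ref) in key_b:
            idx_a.append(ia)
            idx_b.append(key_b[(chrom, pos, alt, ref)])
            flip.append(True)
            notes.append((a.variants["id"].iloc[ia], "ref/alt swapped in second panel; dosage reflected"))
    if not idx_a:
        raise StratwasError("panels share no variants")
    a2 = a.take_variants(idx_a)
    b2 = b.take_variants(idx_b)
    flip = np.asarray(flip)
    if flip.any():
        d = b2.dosages.copy()
        d[:, flip] = 2.0 - d[:, flip]
        v = b2.variants.copy()
        v.loc[flip, ["ref", "alt"]] = v.loc[flip, ["alt", "ref"]].to_numpy()
        b2 = replace(b2, dosages=d, variants=v)
    report = pd.DataFrame(notes, columns=["id", "note"])
    return a2, b2, report


# ---------------------------------------------------------------------------
# expression normalization
# ---------------------------------------------------------------------------

class ExpressionNormalizer(BaseEstimator, TransformerMixin):
    """Upper-quartile scaling + log2 VST + control-gene factor removal.

    Each sample is scaled so its upper quartile matches the across-sample
    mean upper quartile; values then pass through log2(x + 1) as the
    variance-stabilizing transform.  ``k_unwanted`` factors of unwanted
    variation are estimated by singular decomposition of the centered
    control-gene submatrix and regressed out of every gene.

    Parameters
    ----------
    control_idx : indices of control (housekeeping) genes in the input
    k_unwanted : number of unwanted-variation factors to remove (default 2)
    """

    def __init__(self, control_idx=(), k_unwanted: int = 2):
        self.control_idx = control_idx
        self.k_unwanted = k_unwanted

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if (X < 0).any():
            raise StratwasError("raw expression must be non-negative")
        if self.k_unwanted > 0 and len(self.control_idx) == 0:
            raise StratwasError("k_unwanted > 0 requires control genes")
        self.target_uq_ = float(np.mean(np.percentile(X, 75, axis=1)))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        uq = np.percentile(X, 75, axis=1)
        if (uq <= 0).any():
            raise StratwasError("sample with non-positive upper quartile")
        scaled = X * (self.target_uq_ / uq)[:, None]
        vst = np.log2(scaled + 1.0)
        if self.k_unwanted == 0:
            return vst
        ctrl = vst[:, list(self.control_idx)]
        ctrl = ctrl - ctrl.mean(axis=0)
        u, s, _ = np.linalg.svd(ctrl, full_matrices=False)
        k = min(self.k_unwanted, s.size)
        w = u[:, :k]  # samples x k unwanted factors
        design = np.column_stack([np.ones(vst.shape[0]), w])
        beta, *_ = np.linalg.lstsq(design, vst, rcond=None)
        # keep the intercept (grand mean), remove factor contributions
        return vst - design[:, 1:] @ beta[1:]


def normalize_expression(
    e: ExpressionMatrix, control_genes: list[str], k_unwanted: int = 2
) -> ExpressionMatrix:
    """Container-level wrapper around :class:`ExpressionNormalizer`."""
    gene_ids = e.genes["id"].tolist()
    missing = [g for g in control_genes if g not in gene_ids]
    if missing:
        raise StratwasError(f"control genes absent from panel: {missing}")
    ctrl_idx = [gene_ids.index(g) for g in control_genes]
    norm = ExpressionNormalizer(control_idx=ctrl_idx, k_unwanted=k_unwanted)
    out = norm.fit(e.values).transform(e.values)
    return replace(e, values=out)


def flag_expression_outliers(e: ExpressionMatrix, alpha: float = 0.01) -> np.ndarray:
    """Flag samples far out on the top-2 principal scores.

    Robust Mahalanobis distance (median / scaled-MAD per score) is compared
    against the chi-square(2) upper-``alpha`` quantile.  ``alpha = 0``
    disables flagging.
    """
    if e.n_samples < 10:
        raise StratwasError("need >= 10 samples for outlier statistics")
    if alpha <= 0:
        return np.zeros(e.n_samples, bool)
    x = e.values - e.values.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :2] * s[:2]
    med = np.median(scores, axis=0)
    mad = stats.median_abs_deviation(scores, axis=0, scale="normal")
    mad = np.where(mad > 0, mad, 1.0)
    d2 = (((scores - med) / mad) ** 2).sum(axis=1)
    return d2 > stats.chi2.ppf(1.0 - alpha, df=2)


# ---------------------------------------------------------------------------
# covariate design and residualization
# ---------------------------------------------------------------------------

def design_matrix(c: pd.DataFrame | None, n: int | None = None) -> np.ndarray:
    """Intercept-first design from a covariate table.

    Constant columns are dropped with a warning (the intercept covers them);
    later-listed collinear columns are dropped deterministically.
    """
    if c is None or c.shape[1] == 0:
        if n is None:
            raise ValueError("n required when covariates are empty")
        return np.ones((n, 1))
    x = np.column_stack([np.ones(len(c)), c.to_numpy(float)])
    names = ["(intercept)"] + list(c.columns)
    keep = [0]
    for j in range(1, x.shape[1]):
        cand = x[:, keep + [j]]
        if np.ptp(x[:, j]) == 0:
            warnings.warn(f"dropping constant covariate {names[j]!r}")
            continue
        if np.linalg.matrix_rank(cand) <= len(keep):
            warnings.warn(f"dropping collinear covariate {names[j]!r}")
            continue
        keep.append(j)
    return x[:, keep]


def residualize_vector(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def residualize(e: ExpressionMatrix, c: pd.DataFrame | None) -> ExpressionMatrix:
    """Per-gene OLS residuals of expression on covariates (intercept included)."""
    x = design_matrix(c, n=e.n_samples)
    if e.n_samples <= x.shape[1]:
        raise StratwasError("fewer samples than covariate design columns")
    beta, *_ = np.linalg.lstsq(x, e.values, rcond=None)
    return replace(e, values=e.values - x @ beta)
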