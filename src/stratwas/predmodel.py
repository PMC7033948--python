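"""Per-gene, per-stratum germline expression models.

For each gene the feature set is its cis window (variants within 500 kb of
either gene end) plus any trans-eQTLs at BBFDR < 0.01, LD-pruned with a
50-variant window, step 5 and r^2 threshold 0.5.  Weights on residualized
expression are estimated by the better of two schemes under shared fivefold
cross-validation: elastic net (mixing 0.5, penalty tuned by CV) or BLUP from
a single-GRM mixed model (equivalently ridge with penalty m * sigma_e^2 /
sigma_g^2).  The winning scheme's out-of-fold squared Pearson correlation is
the model's CV R^2.

The two schemes are scikit-learn estimators (fit/predict, ``coef_`` on the
dosage scale) and compose with sklearn model selection; the module-level
``fit_enet`` / ``fit_blup`` / ``select_scheme`` functions are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .containers import GenotypeMatrix, StratwasError
from .eqtl import cis_distance
from .herit import Grm, reml_fit

log = logging.getLogger(__name__)


@dataclass
class ExpressionModel:
    """Trained sparse weight vector for one (gene, stratum)."""

    gene: str
    stratum: str
    weights: pd.DataFrame          # columns: id, chrom, pos, ref, alt, weight
    scheme: str
    cv_r2: float
    cv_p: float
    feature_spec: dict = field(default_factory=dict)
    seed: int | None = None
    flagged: bool = False

    @property
    def usable(self) -> bool:
        """Passes the downstream CV R^2 > 0.01 filter."""
        return self.cv_r2 > 0.01


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def build_feature_matrix(
    g: GenotypeMatrix,
    gene,
    eqtl_results: pd.DataFrame | None = None,
    cis_window: int = 500_000,
    trans_bbfdr: float = 0.01,
) -> GenotypeMatrix:
    """Cis-window variants plus qualifying trans-eQTL variants for one gene."""
    pos = g.variants["pos"].to_numpy()
    same = (g.variants["chrom"] == gene["chrom"]).to_numpy()
    keep = same & (cis_distance(pos, gene["start"], gene["end"]) <= cis_window)
    if eqtl_results is not None and len(eqtl_results):
        sub = eqtl_results[
            (eqtl_results["gene"] == gene["id"])
            & (eqtl_results["type"] == "trans")
            & (eqtl_results["bbfdr"] < trans_bbfdr)
        ]
        trans_ids = set(sub["variant"])
        keep = keep | g.variants["id"].isin(trans_ids).to_numpy()
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise StratwasError(f"gene {gene['id']}: empty feature set")
    return g.take_variants(idx)


def ld_prune(x: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.5) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning (later-positioned member removed).

    Within each ``window``-variant window over the currently surviving set,
    any pair with squared correlation above ``r2_max`` loses its
    later-positioned member; the window then advances by ``step`` variants.
    """
    m = x.n_variants
    keep = np.ones(m, bool)
    d = x.dosages
    sd = d.std(axis=0)
    start = 0
    while start < m:
        idx = np.flatnonzero(keep)
        win = idx[(idx >= start) & (idx < start + window)]
        changed = True
        while changed and win.size > 1:
            changed = False
            for ai in range(win.size):
                a = win[ai]
                if sd[a] == 0:
                    continue
                for bi in range(ai + 1, win.size):
                    b = win[bi]
                    if sd[b] == 0:
                        continue
                    r = np.corrcoef(d[:, a], d[:, b])[0, 1]
                    if r * r > r2_max:
                        keep[b] = False
                        win = np.delete(win, bi)
                        changed = True
                        break
                if changed:
                    break
        start += step
    return x.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# estimation schemes (sklearn estimators)
# ---------------------------------------------------------------------------

class ElasticNetScheme(BaseEstimator, RegressorMixin):
    """Elastic net with fixed mixing 0.5 and CV-tuned penalty."""

    name = "enet"

    def __init__(self, l1_ratio: float = 0.5, n_folds: int = 5,
                 seed: int | None = 0, n_alphas: int = 50):
        self.l1_ratio = l1_ratio
        self.n_folds = n_folds
        self.seed = seed
        self.n_alphas = n_alphas

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if y.std() == 0:
            self.coef_ = np.zeros(X.shape[1])
            self.intercept_ = float(y.mean()) if y.size else 0.0
            self.flagged_ = True
            return self
        cv = KFold(self.n_folds, shuffle=True, random_state=self.seed)
        net = ElasticNetCV(l1_ratio=self.l1_ratio, cv=cv,
                           alphas=self.n_alphas, max_iter=5000)
        net.fit(X, y)
        self.coef_ = net.coef_
        self.intercept_ = float(net.intercept_)
        self.alpha_ = float(net.alpha_)
        self.flagged_ = False
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, float) @ self.coef_ + self.intercept_


class BlupScheme(BaseEstimator, RegressorMixin):
    """BLUP weights from a single-GRM mixed model.

    Variance components come from REML on A = ZZ'/m over standardized
    dosages; the BLUP solves the equivalent ridge problem with penalty
    lambda* = m * sigma_e^2 / sigma_g^2 in the standardized coordinates and
    ``coef_`` is reported back on the dosage scale.
    """

    name = "blup"

    def __init__(self):
        pass

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, m = X.shape
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        ok = sd > 0
        z = np.zeros_like(X)
        z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
        m_eff = int(ok.sum())
        if m_eff == 0 or y.std() == 0:
            self.coef_ = np.zeros(m)
            self.intercept_ = float(y.mean())
            self.flagged_ = True
            return self
        grm = Grm(z[:, ok] @ z[:, ok].T / m_eff, m_eff)
        est = reml_fit(y - y.mean(), [grm])
        sigma_g, sigma_e = est.components[0], est.components[1]
        self.sigma_g_, self.sigma_e_ = float(sigma_g), float(sigma_e)
        vy = y.var(ddof=1)
        if sigma_g <= 2e-6 * vy:  # component at the non-negativity floor
            self.coef_ = np.zeros(m)
            self.intercept_ = float(y.mean())
            self.flagged_ = True
            return self
        lam = m_eff * sigma_e / sigma_g
        zk = z[:, ok]
        w_std = np.linalg.solve(zk.T @ zk + lam * np.eye(m_eff), zk.T @ (y - y.mean()))
        coef = np.zeros(m)
        coef[ok] = w_std / sd[ok]
        self.coef_ = coef
        self.intercept_ = float(y.mean() - mu @ coef)
        self.flagged_ = False
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, float) @ self.coef_ + self.intercept_


DEFAULT_SCHEMES = ("enet", "blup")
#: ties in CV R^2 resolve in this order (elastic net preferred: sparser)
SCHEME_PRIORITY = {"enet": 0, "blup": 1}


def make_scheme(name: str, seed: int | None = 0):
    if name == "enet":
        return ElasticNetScheme(seed=seed)
    if name == "blup":
        return BlupScheme()
    raise StratwasError(f"unknown scheme {name!r}")


def fit_enet(x: np.ndarray, y: np.ndarray, alpha: float = 0.5,
             n_folds: int = 5, seed: int | None = 0) -> np.ndarray:
    """Elastic-net weights (dosage scale); thin wrapper over the estimator."""
    est = ElasticNetScheme(l1_ratio=alpha, n_folds=n_folds, seed=seed).fit(x, y)
    return est.coef_


def fit_blup(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """BLUP / ridge-equivalent weights (dosage scale)."""
    return BlupScheme().fit(x, y).coef_


# ---------------------------------------------------------------------------
# cross-validated scheme selection
# ---------------------------------------------------------------------------

def _cv_r2(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(pred, obs)
    return float(r * r), float(p)


def select_scheme(
    x: np.ndarray,
    y: np.ndarray,
    schemes: tuple = DEFAULT_SCHEMES,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[str, np.ndarray, float, float, dict]:
    """Pick the scheme with the best out-of-fold squared Pearson correlation.

    Fold assignment is seeded and shared across schemes; the winner is refit
    on all samples.  Returns (scheme, weights, cv_r2, cv_p, per-scheme R^2).
    """
    if len(schemes) < 1:
        raise StratwasError("no schemes registered")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    folds = list(KFold(n_folds, shuffle=True, random_state=seed).split(x))
    results = {}
    for name in schemes:
        oof = np.full(y.size, np.nan)
        for tr, te in folds:
            est = make_scheme(name, seed=seed)
            est.fit(x[tr], y[tr])
            oof[te] = est.predict(x[te])
        assert not np.isnan(oof).any()
        results[name] = _cv_r2(oof, y)
    winner = max(schemes, key=lambda s: (results[s][0], -SCHEME_PRIORITY[s]))
    final = make_scheme(winner, seed=seed).fit(x, y)
    r2, p = results[winner]
    return winner, final.coef_, r2, p, {s: results[s][0] for s in schemes}


def train_gene(
    g: GenotypeMatrix,
    y: np.ndarray,
    gene,
    stratum: str,
    eqtl_results: pd.DataFrame | None = None,
    cis_window: int = 500_000,
    trans_bbfdr: float = 0.01,
    schemes: tuple = DEFAULT_SCHEMES,
    n_folds: int = 5,
    seed: int = 0,
) -> ExpressionModel:
    """Feature construction + LD pruning + scheme selection for one gene."""
    feats = build_feature_matrix(g, gene, eqtl_results, cis_window, trans_bbfdr)
    pruned = ld_prune(feats)
    scheme, w, r2, p, all_r2 = select_scheme(pruned.dosages, y, schemes,
                                             n_folds, seed)
    weights = pruned.variants.copy()
    weights["weight"] = w
    return ExpressionModel(
        gene=gene["id"], stratum=stratum, weights=weights, scheme=scheme,
        cv_r2=r2, cv_p=p,
        feature_spec={"cis_window": cis_window, "trans_bbfdr": trans_bbfdr,
                      "n_features": pruned.n_variants, "scheme_r2": all_r2},
        seed=seed,
    )


def train_all(
    genotypes: dict,
    expression: dict,
    gene_table: pd.DataFrame,
    heritable_genes: dict,
    eqtl_results: dict | None = None,
    min_samples: int = 30,
    schemes: tuple = DEFAULT_SCHEMES,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """One ExpressionModel per (stratum, gene passing the h^2 filter).

    ``expression`` must hold residualized expression per stratum; weights
    are defined on that scale and consumers must not re-add covariate
    effects.
    """
    store: dict[tuple[str, str], ExpressionModel] = {}
    for stratum, g in genotypes.items():
        if g.n_samples < min_samples:
            log.warning("stratum %s skipped: n=%d < %d", stratum, g.n_samples,
                        min_samples)
            continue
        e = expression[stratum]
        eq = None if eqtl_results is None else eqtl_results.get(stratum)
        for _, gene in gene_table.iterrows():
            if gene["id"] not in set(heritable_genes.get(stratum, [])):
                continue
            y = e.column(gene["id"])
            try:
                model = train_gene(g, y, gene, stratum, eq, schemes=schemes,
                                   n_folds=n_folds, seed=seed)
            except StratwasError as err:
                log.warning("gene %s/%s skipped: %s", stratum, gene["id"], err)
                continue
            store[(stratum, gene["id"])] = model
    return store


def model_store_tables(store: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a model store into (weights table, metadata table)."""
    wrows, mrows = [], []
    for (stratum, gene), m in store.items():
        w = m.weights.copy()
        w.insert(0, "gene", gene)
        w.insert(0, "stratum", stratum)
        wrows.append(w[w["weight"] != 0])
        mrows.append({"stratum": stratum, "gene": gene, "scheme": m.scheme,
                      "cv_r2": m.cv_r2, "cv_p": m.cv_p, "seed": m.seed})
    weights = pd.concat(wrows, ignore_index=True) if wrows else pd.DataFrame()
    return weights, pd.DataFrame(mrows)
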