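"""Synthetic two-stratum cohorts with known ground truth.

The generator emulates the data structure of a two-ancestry breast-cancer
cohort: two strata ("AA"-like, admixed between two ancestral populations,
and "WW"-like, drawn from one of them) with Balding-Nichols differentiated
allele frequencies, first-order autoregressive within-haplotype LD, sparse
cis plus rare trans eQTL architecture on a single synthetic chromosome,
covariate-driven nuisance variation in expression, and competing-risks
survival driven by the genetically regulated component of expression.

Every output is a deterministic function of the config (including its seed):
independent sub-streams are derived from the seed per generation stage, so
re-running any stage with the same config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CAUSE_CENSORED,
    CAUSE_COMPETING,
    CAUSE_PRIMARY,
    ExpressionMatrix,
    GenotypeMatrix,
    InvalidConfigError,
)

#: ancestry-switch probability per variant step along admixed haplotypes
ANCESTRY_SWITCH_RATE = 0.05

#: spacing between gene starts on the synthetic chromosome; cis windows of
#: +/-500 kb around 10-kb gene bodies never overlap at this tiling
GENE_SPACING = 1_200_000
GENE_LENGTH = 10_000
CIS_SPAN = 400_000  # cis variants placed within +/-400 kb of the gene body

STRATA = ("AA", "WW")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the structure of the motivating study: two strata of
    roughly 600 genotyped-and-expressed samples each, a targeted expression
    panel of a few dozen genes, allele-frequency differentiation typical of
    African/European comparisons (Fst ~ 0.15), strong local LD, and a
    survival mix of ~9% primary-cause deaths, ~8.5% competing deaths and the
    rest censored.
    """

    n_samples_per_stratum: int = 600
    n_genes: int = 20
    n_variants_per_gene_cis: int = 30
    n_trans_variants: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.15
    ld_decay: float = 0.9
    cis_h2_per_gene: float | list[float] = 0.2
    n_causal_cis: int = 3
    trans_h2: float = 0.0
    stratum_specific_causals: bool = False
    admixture_alpha: float = 8.0
    covariate_var_frac: float = 0.1
    covariate_spec: tuple = (("age", "normal"), ("status", "binary"),
                             ("pc1", "normal"), ("pc2", "normal"))
    survival_beta: float | dict = 0.0
    event_rate: float = 0.09
    competing_rate: float = 0.085
    censor_rate: float = 0.825
    gwas_effects: dict | None = None
    n_gwas: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.n_samples_per_stratum < 2:
            raise InvalidConfigError("need at least 2 samples per stratum")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie in (0, 0.5]")
        if self.fst < 0:
            raise InvalidConfigError("fst must be >= 0")
        if not (0 <= self.ld_decay < 1):
            raise InvalidConfigError("ld_decay must be in [0, 1)")
        rates = (self.event_rate, self.competing_rate, self.censor_rate)
        if any(r < 0 for r in rates):
            raise InvalidConfigError("rates must be non-negative")
        if abs(sum(rates) - 1.0) > 1e-9:
            raise InvalidConfigError("event + competing + censor rates must sum to 1")
        for h2 in self.h2_list():
            if not (0 <= h2 < 1):
                raise InvalidConfigError("cis h2 must be in [0, 1)")
            if h2 > 0 and self.n_causal_cis == 0:
                raise InvalidConfigError("cis h2 > 0 unreachable with n_causal_cis = 0")
            if h2 + self.trans_h2 + self.covariate_var_frac > 1:
                raise InvalidConfigError(
                    "cis h2 + trans h2 + covariate variance fraction must be <= 1"
                )

    def h2_list(self) -> list[float]:
        if np.isscalar(self.cis_h2_per_gene):
            return [float(self.cis_h2_per_gene)] * self.n_genes
        h2 = list(self.cis_h2_per_gene)
        if len(h2) != self.n_genes:
            raise InvalidConfigError("cis_h2_per_gene length must equal n_genes")
        return [float(x) for x in h2]

    def beta_map(self) -> dict[str, float]:
        genes = [f"gene{g:03d}" for g in range(self.n_genes)]
        if isinstance(self.survival_beta, dict):
            return {g: float(self.survival_beta.get(g, 0.0)) for g in genes}
        return {g: float(self.survival_beta) for g in genes}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["covariate_spec"] = [list(x) for x in self.covariate_spec]
        return d

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream for a generation stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    causal_weights: dict = field(default_factory=dict)  # stratum -> gene -> variant -> effect
    true_cis_h2: dict = field(default_factory=dict)     # stratum -> gene -> realized fraction
    true_survival_beta: dict = field(default_factory=dict)  # gene -> log-hazard
    local_ancestry: dict = field(default_factory=dict)  # stratum -> samples x variants dosage
    variant_freqs: dict = field(default_factory=dict)   # population -> per-variant freq

    def to_json_dict(self) -> dict:
        return {
            "causal_weights": self.causal_weights,
            "true_cis_h2": self.true_cis_h2,
            "true_survival_beta": self.true_survival_beta,
        }


# ---------------------------------------------------------------------------
# variant map
# ---------------------------------------------------------------------------

def variant_map(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic variant and gene tables on one synthetic chromosome.

    Genes are tiled ``GENE_SPACING`` apart so that 500-kb cis windows never
    overlap; trans variants sit in a block beyond the last gene, > 500 kb
    from every gene.
    """
    genes = []
    rows = []
    for g in range(config.n_genes):
        start = 500_000 + g * GENE_SPACING
        end = start + GENE_LENGTH
        genes.append((f"gene{g:03d}", "chr1", start, end))
        m = config.n_variants_per_gene_cis
        offsets = np.linspace(-CIS_SPAN, GENE_LENGTH + CIS_SPAN, m).astype(int)
        for k, off in enumerate(offsets):
            rows.append((f"g{g:03d}v{k:03d}", "chr1", start + off, "A", "G"))
    tail = 500_000 + config.n_genes * GENE_SPACING + 600_000
    for t in range(config.n_trans_variants):
        rows.append((f"trans{t:03d}", "chr1", tail + t * 1_000, "A", "G"))
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    variants = variants.sort_values("pos", kind="stable").reset_index(drop=True)
    gene_df = pd.DataFrame(genes, columns=["id", "chrom", "start", "end"])
    return variants, gene_df


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _ar1_gaussian(rng, n_hap: int, m: int, rho: float,
                  block: np.ndarray | None = None) -> np.ndarray:
    """AR(1) Gaussian chain per haplotype; restarts at block boundaries.

    Blocks delimit gene cis windows (and the trans tail), which sit far
    apart on the chromosome: variants in different blocks are unlinked.
    """
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1))
        scaled = innov * np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            if block is not None and block[j] != block[j - 1]:
                z[:, j] = innov[:, j - 1]
            else:
                z[:, j] = rho * z[:, j - 1] + scaled[:, j - 1]
    return z


def _balding_nichols(rng, p_anc: np.ndarray, fst: float) -> np.ndarray:
    if fst == 0:
        return p_anc.copy()
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-3, 1 - 1e-3)


def simulate_genotypes(config: SimConfig):
    """Generate per-stratum genotype panels and latent local ancestry.

    Two ancestral populations ("afr", "eur") receive Balding-Nichols
    frequencies around shared ancestral frequencies.  The "WW" stratum draws
    haplotypes from the "eur" population; "AA" samples are admixed, with a
    per-sample admixture proportion and a Markov ancestry chain along each
    haplotype.  Within-haplotype LD follows a first-order autoregressive
    Gaussian threshold scheme with autocorrelation ``ld_decay``, which keeps
    every per-locus allele frequency exactly on target.

    Returns (dict stratum -> GenotypeMatrix, SimTruth with local_ancestry
    and population frequencies filled in).
    """
    variants, _ = variant_map(config)
    m = len(variants)
    n = config.n_samples_per_stratum
    rng = config.rng(1)

    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    p_pop = {
        "afr": _balding_nichols(rng, p_anc, config.fst),
        "eur": _balding_nichols(rng, p_anc, config.fst),
    }
    thresh = {k: stats.norm.ppf(v) for k, v in p_pop.items()}

    # LD blocks: one per gene cis window, trans variants each standalone
    vid = variants["id"].astype(str)
    block = np.where(vid.str.startswith("trans"),
                     vid.str.replace("trans", "9"),
                     vid.str.slice(1, 4))

    truth = SimTruth(variant_freqs={k: v.copy() for k, v in p_pop.items()})
    out = {}
    for stratum in STRATA:
        n_hap = 2 * n
        z = _ar1_gaussian(rng, n_hap, m, config.ld_decay, block)
        if stratum == "WW":
            alleles = (z < thresh["eur"][None, :]).astype(float)
            local = np.zeros((n, m))
        else:
            a = config.admixture_alpha
            theta = rng.beta(a, a / 4.0, size=n)  # mean 0.8 afr ancestry
            theta_h = np.repeat(theta, 2)
            origin = np.empty((n_hap, m), dtype=bool)  # True = afr
            origin[:, 0] = rng.random(n_hap) < theta_h
            switch = rng.random((n_hap, m)) < ANCESTRY_SWITCH_RATE
            redraw = rng.random((n_hap, m)) < theta_h[:, None]
            for j in range(1, m):
                origin[:, j] = np.where(switch[:, j], redraw[:, j], origin[:, j - 1])
            t = np.where(origin, thresh["afr"][None, :], thresh["eur"][None, :])
            alleles = (z < t).astype(float)
            local = (origin[0::2].astype(float) + origin[1::2].astype(float))
        dosages = alleles[0::2] + alleles[1::2]
        samples = [f"{stratum}{i:05d}" for i in range(n)]
        out[stratum] = GenotypeMatrix(dosages, variants.copy(), samples, stratum)
        truth.local_ancestry[stratum] = local
    return out, truth


# ---------------------------------------------------------------------------
# expression + covariates
# ---------------------------------------------------------------------------

def _draw_covariates(rng, n: int, spec) -> pd.DataFrame:
    cols = {}
    for name, dist in spec:
        if dist == "normal":
            cols[name] = rng.standard_normal(n)
        elif dist == "binary":
            cols[name] = rng.binomial(1, 0.5, size=n).astype(float)
        else:
            raise InvalidConfigError(f"unknown covariate distribution {dist!r}")
    return pd.DataFrame(cols)


def simulate_expression(genotypes: dict, config: SimConfig, truth: SimTruth):
    """Generate expression, covariates, and the causal-weight ground truth.

    Per gene g and stratum: E_g = X_g w_g + X_C beta_C + eps, with w_g
    supported on ``n_causal_cis`` cis variants (plus one trans variant when
    ``trans_h2 > 0``) and rescaled so the realized genetic variance fraction
    matches the configured cis h2.  Covariates jointly contribute
    ``covariate_var_frac`` of the total variance; eps is Gaussian.

    Returns (dict stratum -> ExpressionMatrix, dict stratum -> covariate
    DataFrame, truth updated in place).
    """
    variants, gene_df = variant_map(config)
    h2s = config.h2_list()
    rng = config.rng(2)

    vid = variants["id"].to_numpy()
    pos = variants["pos"].to_numpy()
    is_trans = np.char.startswith(vid.astype(str), "trans")

    # shared causal architecture drawn once; per-stratum redrawn if requested
    def draw_architecture(r):
        arch = {}
        for g in range(config.n_genes):
            gid = gene_df["id"].iloc[g]
            start, end = gene_df["start"].iloc[g], gene_df["end"].iloc[g]
            cis_idx = np.flatnonzero(
                (~is_trans) & (pos >= start - 500_000) & (pos <= end + 500_000)
            )
            k = min(config.n_causal_cis, cis_idx.size)
            chosen = r.choice(cis_idx, size=k, replace=False) if k else np.array([], int)
            w = r.standard_normal(k)
            t_idx = None
            if config.trans_h2 > 0 and is_trans.any():
                t_idx = int(r.choice(np.flatnonzero(is_trans)))
            arch[gid] = (np.sort(chosen), w, t_idx, r.standard_normal())
        return arch

    shared_arch = draw_architecture(rng)
    expr, covs = {}, {}
    for stratum in STRATA:
        g_mat = genotypes[stratum]
        n = g_mat.n_samples
        arch = draw_architecture(rng) if config.stratum_specific_causals else shared_arch
        cov = _draw_covariates(rng, n, config.covariate_spec)
        cov.index = g_mat.samples
        # covariate effects split the covariate variance budget equally
        n_cov = cov.shape[1]
        cov_std = (cov - cov.mean()) / cov.std(ddof=0).replace(0.0, 1.0)
        cov_eff = np.sqrt(config.covariate_var_frac / max(n_cov, 1))

        values = np.empty((n, config.n_genes))
        truth.causal_weights.setdefault(stratum, {})
        truth.true_cis_h2.setdefault(stratum, {})
        for g in range(config.n_genes):
            gid = gene_df["id"].iloc[g]
            cis_idx, w_raw, t_idx, w_t_raw = arch[gid]
            h2 = h2s[g]
            genetic = np.zeros(n)
            weights = {}
            if h2 > 0 and cis_idx.size:
                gv = g_mat.dosages[:, cis_idx] @ w_raw
                v = gv.var()
                scale = np.sqrt(h2 / v) if v > 0 else 0.0
                genetic = gv * scale
                weights = {vid[j]: float(w_raw[k] * scale)
                           for k, j in enumerate(cis_idx)}
            if config.trans_h2 > 0 and t_idx is not None:
                tv = g_mat.dosages[:, t_idx] * w_t_raw
                v = tv.var()
                tscale = np.sqrt(config.trans_h2 / v) if v > 0 else 0.0
                genetic = genetic + tv * tscale
                weights[vid[t_idx]] = float(w_t_raw * tscale)
            nuisance = cov_std.to_numpy() @ np.full(n_cov, cov_eff)
            noise_var = max(1.0 - h2 - config.trans_h2 - config.covariate_var_frac, 0.0)
            eps = rng.standard_normal(n) * np.sqrt(noise_var)
            e = genetic + nuisance + eps
            values[:, g] = e
            truth.causal_weights[stratum][gid] = weights
            denom = e.var()
            truth.true_cis_h2[stratum][gid] = float(genetic.var() / denom) if denom > 0 else 0.0
        expr[stratum] = ExpressionMatrix(values, gene_df.copy(), g_mat.samples)
        covs[stratum] = cov
    return expr, covs, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(grex_true: np.ndarray, covariates: pd.DataFrame,
                      config: SimConfig, gene_ids: list[str] | None = None,
                      stage: int = 3) -> pd.DataFrame:
    """Competing-risks event times from exponential cause-specific hazards.

    The primary-cause hazard loads ``survival_beta`` on the standardized true
    GReX of each gene (plus a modest age effect); the competing-cause and
    censoring hazards are constant.  The three baseline rates are set
    proportional to (event_rate, competing_rate, censor_rate), so at null
    effect the expected cause fractions equal the configured rates exactly.
    """
    n = grex_true.shape[0]
    betas = config.beta_map()
    if gene_ids is None:
        gene_ids = list(betas)[: grex_true.shape[1]]
    rng = config.rng(stage)
    sd = grex_true.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (grex_true - grex_true.mean(axis=0)) / sd
    eta = z @ np.array([betas[g] for g in gene_ids])
    if "age" in covariates.columns:
        age = covariates["age"].to_numpy(float)
        s = age.std()
        if s > 0:
            eta = eta + 0.2 * (age - age.mean()) / s

    r1 = config.event_rate * np.exp(eta)
    r2 = np.full(n, config.competing_rate)
    rc = np.full(n, config.censor_rate)

    def draw(rate):
        with np.errstate(divide="ignore"):
            return np.where(rate > 0, rng.exponential(1.0, n) / np.where(rate > 0, rate, 1.0), np.inf)

    t1, t2, tc = draw(r1), draw(r2), draw(rc)
    time = np.minimum(np.minimum(t1, t2), tc)
    cause = np.where(t1 <= time, CAUSE_PRIMARY,
                     np.where(t2 <= time, CAUSE_COMPETING, CAUSE_CENSORED))
    time = np.maximum(time, 1e-12)
    return pd.DataFrame({"time": time, "cause": cause}, index=covariates.index)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_sumstats(truth: SimTruth, genotypes: GenotypeMatrix,
                      config: SimConfig, ridge_eps: float = 1e-6) -> pd.DataFrame:
    """Per-variant GWAS Z-scores propagated through the realized LD.

    E[Z] = sqrt(n_gwas) * R @ b, with b the standardized per-variant
    liability effects (``config.gwas_effects``, absent variants at 0) and R
    the realized dosage correlation matrix; noise is drawn N(0, R).  R is
    ridge-stabilized with ``ridge_eps`` before the Cholesky factorization.
    """
    d = genotypes.dosages
    sd = d.std(axis=0)
    poly = sd > 0
    if not poly.all():
        genotypes = genotypes.take_variants(np.flatnonzero(poly))
        d, sd = genotypes.dosages, sd[poly]
    x = (d - d.mean(axis=0)) / sd
    m = x.shape[1]
    r = (x.T @ x) / x.shape[0]
    r = (1.0 - ridge_eps) * r + ridge_eps * np.eye(m)
    b = np.zeros(m)
    if config.gwas_effects:
        idx = {v: j for j, v in enumerate(genotypes.variants["id"])}
        for v, eff in config.gwas_effects.items():
            if v in idx:
                b[idx[v]] = eff
    mean = np.sqrt(config.n_gwas) * (r @ b)
    chol = np.linalg.cholesky(r)
    rng = config.rng(4)
    z = mean + chol @ rng.standard_normal(m)
    out = genotypes.variants.copy()
    out["z"] = z
    return out


# ---------------------------------------------------------------------------
# one-call cohort
# ---------------------------------------------------------------------------

@dataclass
class SimCohort:
    config: SimConfig
    genotypes: dict
    expression: dict
    covariates: dict
    survival: dict
    truth: SimTruth
    genes: pd.DataFrame


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate genotypes, expression, covariates and survival for both strata."""
    genotypes, truth = simulate_genotypes(config)
    expr, covs, truth = simulate_expression(genotypes, config, truth)
    _, gene_df = variant_map(config)
    gene_ids = gene_df["id"].tolist()
    surv = {}
    for k, stratum in enumerate(STRATA):
        # true GReX = genetic value under the stratum's causal weights
        g = genotypes[stratum]
        vid_index = {v: j for j, v in enumerate(g.variants["id"])}
        grex = np.zeros((g.n_samples, len(gene_ids)))
        for gi, gid in enumerate(gene_ids):
            for v, w in truth.causal_weights[stratum][gid].items():
                grex[:, gi] += g.dosages[:, vid_index[v]] * w
        surv[stratum] = simulate_survival(grex, covs[stratum], config,
                                          gene_ids, stage=30 + k)
    truth.true_survival_beta = config.beta_map()
    return SimCohort(config, genotypes, expr, covs, surv, truth, gene_df)
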