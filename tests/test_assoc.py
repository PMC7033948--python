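"""Survival association: Cox partial-likelihood cross-checks, empirical-null
recovery, BH arithmetic, conditional analysis and the burden test."""

import numpy as np
import pandas as pd
import pytest

import stratwas as sw
from stratwas import assoc
from stratwas.containers import CAUSE_PRIMARY, StratwasError
from stratwas.predmodel import ExpressionModel

from conftest import make_genotypes


def _surv(times, events, samples=None):
    idx = samples or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({
        "time": times,
        "cause": [CAUSE_PRIMARY if e else "censored" for e in events],
    }, index=idx)


def logrank_oracle(times, events, group):
    """Two-group log-rank by direct risk-set accounting (no ties)."""
    order = np.argsort(times)
    t, e, g = np.asarray(times)[order], np.asarray(events)[order], \
        np.asarray(group)[order]
    o_minus_e = 0.0
    var = 0.0
    n = len(t)
    for i in range(n):
        if not e[i]:
            continue
        at_risk = g[i:]
        n1 = at_risk.sum()
        ntot = len(at_risk)
        o_minus_e += g[i] - n1 / ntot
        var += (n1 / ntot) * (1 - n1 / ntot)
    return o_minus_e ** 2 / var


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def test_score_test_equals_logrank_on_two_group_toy():
    times = [2.1, 3.5, 1.2, 4.8, 0.9, 2.9, 3.9, 1.7]
    events = [1, 1, 1, 1, 1, 1, 1, 1]  # no censoring
    group = np.array([0, 1, 0, 1, 1, 0, 1, 0], float)
    surv = _surv(times, events)
    u, v, chi2 = assoc.cox_score_test(group, surv)
    want = logrank_oracle(times, events, group)
    assert chi2 == pytest.approx(want, abs=1e-8)


def test_cox_mle_zeroes_independent_partial_likelihood_gradient(rng):
    n = 120
    x = rng.standard_normal(n)
    t = rng.exponential(1.0, n) / np.exp(0.5 * x)
    c = rng.exponential(2.0, n)
    times = np.minimum(t, c)
    events = t <= c
    surv = _surv(times, events)
    res = assoc.coxph_cause_specific(x, None, surv)

    def pl_grad(beta):
        order = np.argsort(times)
        xs, ev = x[order], np.asarray(events)[order]
        grad = 0.0
        for i in range(n):
            if not ev[i]:
                continue
            risk = xs[i:]
            w = np.exp(beta * risk)
            grad += xs[i] - (w * risk).sum() / w.sum()
        return grad

    assert abs(pl_grad(res.beta)) < 1e-3
    assert abs(pl_grad(0.0)) > 1.0  # sanity: gradient is informative


def test_cox_no_events_errors(rng):
    surv = _surv([1.0, 2.0, 3.0], [0, 0, 0])
    with pytest.raises(StratwasError):
        assoc.coxph_cause_specific(np.array([0.0, 1.0, 2.0]), None, surv)


def test_competing_events_treated_as_censoring(rng):
    n = 300
    x = rng.standard_normal(n)
    t = rng.exponential(1.0, n)
    surv = pd.DataFrame({
        "time": t,
        "cause": np.where(np.arange(n) % 3 == 0, CAUSE_PRIMARY,
                          np.where(np.arange(n) % 3 == 1, "competing",
                                   "censored")),
    }, index=[f"s{i}" for i in range(n)])
    res = assoc.coxph_cause_specific(x, None, surv)
    assert res.n_events == (surv["cause"] == CAUSE_PRIMARY).sum()
    # identical fit when competing relabeled as censored
    surv2 = surv.replace({"cause": {"competing": "censored"}})
    res2 = assoc.coxph_cause_specific(x, None, surv2)
    assert res.beta == pytest.approx(res2.beta, abs=1e-10)


def test_twas_scan_duplicated_gene_columns_identical(small_cohort, rng):
    n = 120
    gx = pd.DataFrame({"a": rng.standard_normal(n)},
                      index=small_cohort.survival["AA"].index)
    gx["b"] = gx["a"]
    out = assoc.twas_scan(gx, None, small_cohort.survival["AA"])
    a, b = out.set_index("gene").loc["a"], out.set_index("gene").loc["b"]
    assert a["log_hr"] == b["log_hr"]
    assert a["p_raw"] == b["p_raw"]


# ---------------------------------------------------------------------------
# empirical-null correction
# ---------------------------------------------------------------------------

def test_bacon_recovers_standard_null(rng):
    z = rng.standard_normal(800)
    fit, zc = assoc.bacon_correct(z, iterations=1500, burn_in=400, seed=2)
    assert abs(fit.bias) < 0.08
    assert abs(fit.inflation - 1.0) < 0.08
    assert fit.weights[0] > 0.8


def test_bacon_transform_applies_bias_and_scale(rng):
    z = rng.standard_normal(200) * 1.4 + 0.6
    fit, zc = assoc.bacon_correct(z, iterations=1200, burn_in=300, seed=4)
    np.testing.assert_allclose(zc, (z - fit.bias) / fit.inflation, atol=1e-12)
    assert abs(zc.mean()) < 0.15
    assert abs(zc.std() - 1.0) < 0.15


def test_bh_adjust_hand_values():
    adj, calls = assoc.bh_adjust(np.array([0.01, 0.02, 0.03, 0.9]), fdr=0.10)
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.9], atol=1e-12)
    assert calls.tolist() == [True, True, True, False]
    adj1, _ = assoc.bh_adjust(np.array([0.37]))
    assert adj1[0] == pytest.approx(0.37)
    _, none_called = assoc.bh_adjust(np.ones(5))
    assert not none_called.any()


# ---------------------------------------------------------------------------
# GWAS / conditional
# ---------------------------------------------------------------------------

def test_gwas_scan_identical_columns_and_monomorphic_skip(rng):
    n = 200
    v = rng.binomial(2, 0.4, n).astype(float)
    d = np.column_stack([v, v, np.zeros(n)])
    g = make_genotypes(d)
    t = rng.exponential(1.0, n)
    surv = _surv(t, rng.random(n) < 0.5, samples=g.samples)
    out = assoc.gwas_scan(g, None, surv)
    assert set(out["variant"]) == {"v0", "v1"}  # monomorphic skipped
    assert out["beta"].nunique() == 1


def test_conditional_independent_snp_leaves_beta(rng):
    n = 600
    grex = rng.standard_normal(n)
    snp = rng.binomial(2, 0.3, n).astype(float)
    t = rng.exponential(1.0, n) / np.exp(0.4 * grex)
    surv = _surv(t, np.ones(n, bool))
    res = assoc.conditional_adjust("g", grex, snp, None, surv)
    assert abs(res["conditional"].beta - res["unconditional"].beta) < 0.1


def test_conditional_full_mediation_kills_beta(rng):
    n = 600
    snp = rng.binomial(2, 0.4, n).astype(float)
    grex = snp * 0.8  # GReX built entirely from the SNP
    t = rng.exponential(1.0, n) / np.exp(0.5 * snp)
    surv = _surv(t, np.ones(n, bool))
    res = assoc.conditional_adjust("g", grex, snp, None, surv)
    assert res["collinear"]
    assert res["conditional"] is None
    # partial overlap: GReX = SNP + noise
    grex2 = snp + rng.standard_normal(n)
    res2 = assoc.conditional_adjust("g", grex2, snp, None, surv)
    assert abs(res2["conditional"].beta) < abs(res2["unconditional"].beta)


def test_top_cis_snp_selection():
    gwas = pd.DataFrame({
        "variant": ["a", "b", "c"], "chrom": "chr1",
        "pos": [900_000, 1_200_000, 9_000_000],
        "p": [0.01, 0.001, 1e-9],
    })
    gene = pd.Series({"id": "g", "chrom": "chr1", "start": 1_000_000,
                      "end": 1_010_000})
    assert assoc.top_cis_snp(gwas, gene) == "b"


# ---------------------------------------------------------------------------
# burden test
# ---------------------------------------------------------------------------

def _ld_ref_with_r(r, n=4):
    # two dosage columns with exact correlation r
    x1 = np.array([1.0, 1.0, -1.0, -1.0])
    xp = np.array([1.0, -1.0, 1.0, -1.0])
    x2 = r * x1 + np.sqrt(1 - r * r) * xp
    d = np.column_stack([1 + 0.5 * x1, 1 + 0.5 * x2])
    return make_genotypes(d, positions=[100, 200])


def _burden_model(weights):
    w = pd.DataFrame({
        "id": [f"v{j}" for j in range(len(weights))],
        "chrom": "chr1", "pos": [100, 200][: len(weights)],
        "ref": "A", "alt": "G", "weight": weights,
    })
    return ExpressionModel("g", "AA", w, "enet", 0.3, 0.01)


def test_burden_two_variant_hand_arithmetic():
    # W=(1,1), Z=(2,2), LD 0.5 -> 4 / sqrt(1 + 1 + 2*0.5) = 4/sqrt(3)
    ld = _ld_ref_with_r(0.5)
    ss = pd.DataFrame({"chrom": "chr1", "pos": [100, 200], "ref": "A",
                       "alt": "G", "z": [2.0, 2.0], "id": ["v0", "v1"]})
    res = assoc.burden_test(_burden_model([1.0, 1.0]), ss, ld, ridge_eps=0.0)
    assert res.z_tilde == pytest.approx(4 / np.sqrt(3), abs=1e-8)
    assert res.significant


def test_burden_single_variant_identity_and_zero():
    ld = _ld_ref_with_r(0.5)
    ss = pd.DataFrame({"chrom": "chr1", "pos": [100], "ref": "A", "alt": "G",
                       "z": [1.7], "id": ["v0"]})
    res = assoc.burden_test(_burden_model([1.0]), ss, ld, ridge_eps=0.0)
    assert res.z_tilde == pytest.approx(1.7, abs=1e-10)
    ss0 = ss.assign(z=0.0)
    assert assoc.burden_test(_burden_model([1.0]), ss0, ld).z_tilde == 0.0


def test_burden_invariant_to_consistent_allele_flip():
    ld = _ld_ref_with_r(0.5)
    ss = pd.DataFrame({"chrom": "chr1", "pos": [100, 200], "ref": "A",
                       "alt": "G", "z": [2.0, 1.0], "id": ["v0", "v1"]})
    base = assoc.burden_test(_burden_model([1.0, -0.5]), ss, ld,
                             ridge_eps=1e-6)
    # flip variant 2 everywhere: sumstats alleles + sign of z and LD alleles
    ss_f = ss.copy()
    ss_f.loc[1, ["ref", "alt"]] = ["G", "A"]
    ss_f.loc[1, "z"] = -1.0
    v = ld.variants.copy()
    v.loc[1, ["ref", "alt"]] = ["G", "A"]
    d = ld.dosages.copy()
    d[:, 1] = 2 - d[:, 1]
    ld_f = sw.GenotypeMatrix(d, v, ld.samples)
    flipped = assoc.burden_test(_burden_model([1.0, -0.5]), ss_f, ld_f,
                                ridge_eps=1e-6)
    assert flipped.z_tilde == pytest.approx(base.z_tilde, abs=1e-8)


def test_burden_no_matches_errors():
    ld = _ld_ref_with_r(0.2)
    ss = pd.DataFrame({"chrom": "chr2", "pos": [1], "ref": "A", "alt": "G",
                       "z": [1.0], "id": ["x"]})
    with pytest.raises(StratwasError):
        assoc.burden_test(_burden_model([1.0]), ss, ld)
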