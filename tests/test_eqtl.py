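"""eQTL scan against a normal-equations oracle; hierarchical FDR against a
hand-executed Simes + BH computation; ancestry adjustment; enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stratwas as sw
from stratwas import eqtl
from stratwas.containers import StratwasError

from conftest import make_expression, make_genotypes


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def ols_oracle(y, snp, covs):
    """Explicit (X'X)^-1 X'y with Wald t against the t-distribution."""
    x = np.column_stack([np.ones(len(y)), snp] + list(covs))
    beta = np.linalg.inv(x.T @ x) @ x.T @ y
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta[1], se, t, p


def test_scan_matches_normal_equations_oracle():
    # 6-sample toy with one covariate
    snp = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
    cov = np.array([0.3, -0.2, 0.5, 1.0, -1.2, 0.1])
    y = np.array([0.1, 0.9, 2.3, -0.4, 1.1, 1.8])
    g = make_genotypes(snp[:, None], positions=[1_000_100])
    e = make_expression(y[:, None],
                        genes=pd.DataFrame({"id": ["gene0"], "chrom": "chr1",
                                            "start": 1_000_000, "end": 1_010_000}))
    c = pd.DataFrame({"c1": cov}, index=g.samples)
    res = eqtl.scan_eqtl(e, g, c).iloc[0]
    b, se, t, p = ols_oracle(y, snp, [cov])
    assert res["beta"] == pytest.approx(b, abs=1e-10)
    assert res["se"] == pytest.approx(se, abs=1e-10)
    assert res["t"] == pytest.approx(t, abs=1e-10)
    assert res["p"] == pytest.approx(p, abs=1e-10)


def test_scan_perfect_association():
    snp = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0, 1.0, 0.0])
    g = make_genotypes(snp[:, None])
    e = make_expression(snp[:, None])
    res = eqtl.scan_eqtl(e, g).iloc[0]
    assert res["beta"] == pytest.approx(1.0, abs=1e-10)
    assert res["p"] < 1e-12


def test_cis_trans_distance_rule(rng):
    gene = pd.DataFrame({"id": ["gene0"], "chrom": "chr1",
                         "start": 2_000_000, "end": 2_010_000})
    positions = [2_000_000 - 500_001, 2_000_000 - 499_999, 2_005_000,
                 2_010_000 + 500_000, 2_010_000 + 500_001]
    d = rng.binomial(2, 0.5, (30, 5)).astype(float)
    g = make_genotypes(d, positions=positions)
    e = make_expression(rng.standard_normal((30, 1)), genes=gene)
    res = eqtl.scan_eqtl(e, g)
    assert res.set_index("pos")["type"].to_dict() == {
        1_499_999: "trans", 1_500_001: "cis", 2_005_000: "cis",
        2_510_000: "cis", 2_510_001: "trans",
    }


def test_scan_frisch_waugh_equivalence(rng):
    """Effect from residualized-both-sides scan equals the joint model."""
    n = 40
    d = rng.binomial(2, 0.4, (n, 3)).astype(float)
    c = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)},
                     index=[f"s{i}" for i in range(n)])
    e_vals = rng.standard_normal((n, 2)) + 0.5 * c[["a"]].to_numpy()
    g = make_genotypes(d)
    e = make_expression(e_vals)
    joint = eqtl.scan_eqtl(e, g, c)
    from stratwas.gdata import design_matrix
    x = design_matrix(c)
    q, _ = np.linalg.qr(x)
    d_res = d - q @ (q.T @ d)
    e_res = e_vals - q @ (q.T @ e_vals)
    g2 = sw.GenotypeMatrix(d_res, g.variants, g.samples)
    e2 = sw.ExpressionMatrix(e_res, e.genes, e.samples)
    sep = eqtl.scan_eqtl(e2, g2)
    np.testing.assert_allclose(joint["beta"].to_numpy(), sep["beta"].to_numpy(),
                               atol=1e-8)


def test_scan_excludes_flagged_subtype(rng):
    n = 30
    d = rng.binomial(2, 0.4, (n, 2)).astype(float)
    g = make_genotypes(d)
    e = make_expression(rng.standard_normal((n, 1)))
    subtypes = pd.Series("LumA", index=g.samples)
    subtypes.iloc[:5] = "Normal-like"
    res = eqtl.scan_eqtl(e, g, subtypes=subtypes)
    # df reflects 25 samples: n - 1 (intercept) - 1 (snp) = 23
    b = res.iloc[0]
    assert b["p"] == pytest.approx(2 * stats.t.sf(abs(b["t"]), 23), abs=1e-12)


def test_scan_too_few_samples_errors(rng):
    g = make_genotypes(rng.binomial(2, 0.5, (3, 2)).astype(float))
    e = make_expression(rng.standard_normal((3, 1)))
    c = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.5]},
                     index=g.samples)
    with pytest.raises(StratwasError):
        eqtl.scan_eqtl(e, g, c)


# ---------------------------------------------------------------------------
# hierarchical FDR
# ---------------------------------------------------------------------------

def _records(p_by_gene):
    rows = []
    for gene, ps in p_by_gene.items():
        for j, p in enumerate(ps):
            rows.append({"gene": gene, "variant": f"{gene}v{j}", "p": p,
                         "type": "cis"})
    return pd.DataFrame(rows)


def test_hierarchy_matches_hand_simes_bh_oracle():
    # hand execution: Simes per gene = [.004, .16, .9]; BH over 3 genes at
    # 0.05 selects only A (adjusted [.012, .24, .9]); stage-2 BH within A
    # ([.004, .02, .4, .9]) rescaled by G/R = 3 and capped at 1
    recs = _records({
        "A": [0.001, 0.01, 0.3, 0.9],
        "B": [0.04, 0.2, 0.5, 0.8],
        "C": [0.5, 0.6, 0.7, 0.9],
    })
    out = eqtl.hierarchical_fdr(recs, level=0.05)
    gene_adj = out.attrs["gene_adjusted_p"]
    np.testing.assert_allclose([gene_adj[g] for g in "ABC"],
                               [0.012, 0.24, 0.9], atol=1e-12)
    a = out[out["gene"] == "A"].sort_values("p")
    np.testing.assert_allclose(a["bbfdr"], [0.012, 0.06, 1.0, 1.0], atol=1e-12)
    assert a["is_esnp"].tolist() == [True, False, False, False]
    assert set(out.loc[out["is_egene"], "gene"]) == {"A"}
    assert not out.loc[out["gene"] != "A", "is_esnp"].any()


def test_hierarchy_all_ones_no_calls():
    out = eqtl.hierarchical_fdr(_records({"A": [1.0] * 3, "B": [1.0] * 3}))
    assert not out["is_egene"].any()
    assert not out["is_esnp"].any()


def test_hierarchy_single_gene_single_variant_is_identity():
    for p in (0.004, 0.3, 0.9):
        out = eqtl.hierarchical_fdr(_records({"A": [p]}))
        assert out["bbfdr"].iloc[0] == pytest.approx(p, abs=1e-14)


def test_bbfdr_dominates_p(rng):
    ps = {f"g{i}": rng.uniform(0, 1, 6) for i in range(5)}
    out = eqtl.hierarchical_fdr(_records(ps))
    assert (out["bbfdr"] >= out["p"] - 1e-15).all()
    assert out["bbfdr"].between(0, 1).all()


def test_hard_call_maf_filter_drops_rare_hard_calls(rng):
    n = 100
    common = rng.binomial(2, 0.4, n).astype(float)
    # fractional dosages that round to zero copies almost everywhere
    rare = np.full(n, 0.2)
    rare[:3] = 1.0
    g = make_genotypes(np.column_stack([common, rare]))
    recs = pd.DataFrame({"gene": "g", "variant": ["v0", "v1"],
                         "p": [0.01, 0.001]})
    out = eqtl.hard_call_maf_filter(recs, g, maf_min=0.05)
    assert out["variant"].tolist() == ["v0"]


# ---------------------------------------------------------------------------
# local ancestry adjustment
# ---------------------------------------------------------------------------

def test_ancestry_adjustment_matches_two_covariate_oracle():
    g = np.array([0.2, 1.1, -0.4, 0.9, -1.0])
    s = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
    l = np.array([0.5, 1.5, 0.2, 1.8, 0.1])
    rec = eqtl.adjust_local_ancestry(g, s, l)

    def std(v):
        v = v - v.mean()
        return v / v.std()

    gt, st, lt = std(g), std(s), std(l)
    x = np.column_stack([np.ones(5), st, lt])
    want = (np.linalg.inv(x.T @ x) @ x.T @ gt)[1]
    assert rec.beta_ancestry_adjusted == pytest.approx(want, abs=1e-12)
    x0 = np.column_stack([np.ones(5), st])
    want0 = (np.linalg.inv(x0.T @ x0) @ x0.T @ gt)[1]
    assert rec.beta_unadjusted == pytest.approx(want0, abs=1e-12)


def test_ancestry_no_confounding_limit(rng):
    n = 2000
    l = rng.binomial(2, 0.5, n).astype(float)
    s = rng.binomial(2, 0.3, n).astype(float)
    g = 0.3 * s + rng.standard_normal(n)
    rec = eqtl.adjust_local_ancestry(g, s, l)
    assert abs(rec.beta_ancestry_adjusted - rec.beta_unadjusted) < 0.05


def test_ancestry_planted_confounder_removed(rng):
    n = 2000
    l = rng.binomial(2, 0.5, n).astype(float)
    s = 0.8 * l + rng.normal(0, 0.5, n)
    g = 0.6 * l + rng.normal(0, 1.0, n)  # expression driven by ancestry only
    rec = eqtl.adjust_local_ancestry(g, s, l)
    assert abs(rec.beta_unadjusted) > 0.15
    assert abs(rec.beta_ancestry_adjusted) < 0.08


def test_ancestry_zero_variance_flagged(rng):
    n = 50
    rec = eqtl.adjust_local_ancestry(rng.standard_normal(n),
                                     np.ones(n), rng.binomial(2, 0.5, n))
    assert rec.flagged


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrichment_matches_hypergeometric_oracle():
    # background of 20 positions, 6 within the annotation; 10 eSNPs of
    # which 8 overlap -> observed-vs-expected table (8,2 / 3,7)
    inside = np.arange(10_000, 10_006) * 10
    outside = np.arange(50_000, 50_014) * 10
    background = np.concatenate([inside, outside])
    esnps = np.concatenate([inside, inside[:2],  # 8 hits (6 inside + 2 dup? no)
                            ])
    # build eSNP set: 8 positions near the annotation, 2 far away
    near_extra = inside[:2] + 3  # still within the 1-kb window
    esnps = np.concatenate([inside, near_extra, outside[:2]])
    ann = pd.DataFrame({"chrom": "chr1", "start": inside, "end": inside})
    obs, exp_mean, orat, ci, p = eqtl.enrichment_test(
        esnps, background, ann, window=1000, n_reps=4000, seed=9)
    assert obs == 8
    assert exp_mean == pytest.approx(10 * 6 / 20, abs=0.15)
    table = np.array([[8, 2], [3, 7]])
    want_or = (8 * 7) / (2 * 3)
    # two-sided Fisher p by hypergeometric enumeration
    n11 = np.arange(0, 11)
    pmf = stats.hypergeom.pmf(n11, 20, 11, 10)
    want_p = pmf[pmf <= pmf[8] * (1 + 1e-9)].sum()
    assert orat == pytest.approx(want_or, rel=1e-9)
    assert p == pytest.approx(want_p, rel=1e-6)


def test_enrichment_null_calibration(rng):
    background = np.sort(rng.choice(5_000_000, 400, replace=False)) + 1
    ann_pos = rng.choice(background, 40, replace=False)
    ann = pd.DataFrame({"chrom": "chr1", "start": ann_pos, "end": ann_pos})
    non_sig = 0
    for rep in range(10):
        esnps = np.random.default_rng(rep).choice(background, 30, replace=False)
        *_, p = eqtl.enrichment_test(esnps, background, ann, n_reps=300,
                                     seed=rep)
        non_sig += p > 0.05
    assert non_sig >= 9


def test_enrichment_input_validation(rng):
    bg = np.arange(1, 100) * 50
    ann = pd.DataFrame({"chrom": "chr1", "start": [10], "end": [20]})
    with pytest.raises(StratwasError):
        eqtl.enrichment_test(bg[:5], bg, ann.iloc[:0])
    with pytest.raises(StratwasError):
        eqtl.enrichment_test(bg[:5], bg, ann, window=-1)
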