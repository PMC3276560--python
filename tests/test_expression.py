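"""Expression association, surrogate variables, q-values, permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from memgrowth import (
    ExpressionMatrix, IntrinsicPhenotype, associate, compare_power,
    estimate_sv, permutation_null, qvalues,
)
from memgrowth.errors import ValidationError


def _pheno(values, samples):
    return IntrinsicPhenotype(
        values=pd.Series(values, index=pd.Index(samples, name="line_id")),
        provenance={},
    )


def _expr(arr, samples, genes=None):
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


@pytest.fixture()
def noise_expr():
    rng = np.random.default_rng(42)
    samples = [f"S{i}" for i in range(100)]
    expr = _expr(rng.normal(size=(1000, 100)), samples)
    ig = _pheno(rng.normal(size=100), samples)
    return expr, ig


# ---------------------------------------------------------------------------
# associate
# ---------------------------------------------------------------------------

def test_exact_linear_gene_recovers_coefficient():
    samples = [f"S{i}" for i in range(30)]
    g = np.linspace(-1, 1, 30)
    expr = _expr(np.vstack([2.0 * g, np.ones(30)]), samples)
    res = associate(expr, _pheno(g, samples))
    assert res.loc["G0", "beta"] == pytest.approx(2.0, abs=1e-10)
    assert res.loc["G0", "p"] < 1e-200
    # constant gene flagged, not an exception
    assert res.loc["G1", "constant"]
    assert res.loc["G1", "p"] == 1.0


def test_associate_matches_brute_force_normal_equations():
    rng = np.random.default_rng(0)
    n = 12
    samples = [f"S{i}" for i in range(n)]
    y = rng.normal(size=n)
    Y = rng.normal(size=(3, n))
    covar = pd.DataFrame({"sex": rng.choice(["a", "b"], size=n)}, index=samples)
    res = associate(_expr(Y, samples), _pheno(y, samples), covar)
    M = np.column_stack([np.ones(n), y, (covar["sex"] == "b").to_numpy(float)])
    for gi in range(3):
        beta = np.linalg.solve(M.T @ M, M.T @ Y[gi])
        resid = Y[gi] - M @ beta
        s2 = resid @ resid / (n - 3)
        se = np.sqrt(s2 * np.linalg.inv(M.T @ M)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), n - 3)
        assert res.iloc[gi]["beta"] == pytest.approx(beta[1], abs=1e-10)
        assert res.iloc[gi]["p"] == pytest.approx(p, abs=1e-10)


def test_null_pvalues_uniform(noise_expr):
    expr, ig = noise_expr
    res = associate(expr, ig)
    assert stats.kstest(res["p"], "uniform").pvalue > 0.01


def test_too_few_shared_samples_rejected():
    samples = [f"S{i}" for i in range(5)]
    expr = _expr(np.zeros((2, 5)), samples)
    with pytest.raises(ValidationError, match="shared"):
        associate(expr, _pheno(np.zeros(5), samples))


def test_growth_linked_genes_enriched_at_fdr():
    """Truly linked genes reach q < 0.10 at >=10x the rate of null genes."""
    from dataclasses import replace
    from memgrowth import fit_mem, intrinsic_phenotype, scenario, simulate
    cfg = replace(scenario("planted_growth", seed=3), n_lines=180,
                  n_snps=2, n_eqtls=0, snp_growth_effect=0.0)
    sim = simulate(cfg)
    fit = fit_mem(sim.phenotypes)
    ig = intrinsic_phenotype(fit, sim.phenotypes)
    res = associate(sim.expression, ig, sim.phenotypes.line_covariates())
    hit = res["q"] < 0.10
    linked = sim.truth.genes["is_growth"]
    rate_linked = hit[linked].mean()
    rate_null = max(hit[~linked].mean(), 1e-12)
    assert rate_linked / rate_null >= 10


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def test_qvalues_hand_computed_example():
    out = qvalues(np.array([0.01, 0.02, 0.9, 1.0]), lam=0.5)
    assert out["pi0"] == pytest.approx(1.0)
    assert np.allclose(out["q"], [0.04, 0.04, 1.0, 1.0])


def test_qvalues_all_ones():
    out = qvalues(np.ones(7))
    assert out["pi0"] == 1.0
    assert (out["q"] == 1.0).all()


def test_qvalues_empty_rejected():
    with pytest.raises(ValidationError):
        qvalues(np.array([]))


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_qvalue_properties(pvals):
    """q is monotone in p, bounded by [pi0*p, 1], and equals BH when pi0 = 1."""
    p = np.asarray(pvals)
    out = qvalues(p)
    q, pi0 = out["q"], out["pi0"]
    assert ((q >= pi0 * p - 1e-12) & (q <= 1.0 + 1e-12)).all()
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()
    if pi0 == 1.0:
        bh = stats.false_discovery_control(p, method="bh")
        assert np.allclose(q, np.minimum(bh, 1.0), atol=1e-12)


# ---------------------------------------------------------------------------
# surrogate variables
# ---------------------------------------------------------------------------

def test_planted_batch_factor_recovered():
    rng = np.random.default_rng(1)
    n = 80
    samples = [f"S{i}" for i in range(n)]
    batch = rng.normal(size=n)
    ig_vals = rng.normal(size=n)
    loadings = rng.normal(0, 2.0, size=300)
    Y = np.outer(loadings, batch) + rng.normal(size=(300, n))
    sv = estimate_sv(_expr(Y, samples), _pheno(ig_vals, samples), seed=0)
    assert sv.k >= 1
    r = np.corrcoef(sv.matrix.iloc[:, 0], batch)[0, 1]
    assert abs(r) > 0.9
    # columns orthonormal
    M = sv.matrix.to_numpy()
    assert np.allclose(M.T @ M, np.eye(sv.k), atol=1e-8)


def test_pure_noise_selects_no_components():
    hits = 0
    for s in range(100):
        rng = np.random.default_rng(s)
        samples = [f"S{i}" for i in range(40)]
        Y = rng.normal(size=(150, 40))
        sv = estimate_sv(_expr(Y, samples), _pheno(rng.normal(size=40), samples),
                         n_perm=20, seed=s)
        hits += sv.k == 0
    assert hits >= 90  # component retained only ~alpha of the time by construction


def test_factor_collinear_with_phenotype_absorbed():
    rng = np.random.default_rng(4)
    n = 60
    samples = [f"S{i}" for i in range(n)]
    ig_vals = rng.normal(size=n)
    loadings = rng.normal(0, 2.0, size=200)
    Y = np.outer(loadings, ig_vals) + rng.normal(size=(200, n))
    sv = estimate_sv(_expr(Y, samples), _pheno(ig_vals, samples), seed=0)
    assert sv.k == 0


def test_sva_with_zero_components_matches_unadjusted(noise_expr):
    expr, ig = noise_expr
    sv = estimate_sv(expr, ig, seed=1)
    assert sv.k == 0
    res_adj = associate(expr, ig, sv=sv)
    res_unadj = associate(expr, ig)
    pd.testing.assert_frame_equal(res_adj, res_unadj)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def test_permutation_null_uniform_and_deterministic():
    from dataclasses import replace
    from memgrowth import fit_mem, intrinsic_phenotype, scenario, simulate
    cfg = replace(scenario("planted_growth", seed=8), n_lines=150,
                  n_snps=2, n_eqtls=0, snp_growth_effect=0.0)
    sim = simulate(cfg)
    fit = fit_mem(sim.phenotypes)
    ig = intrinsic_phenotype(fit, sim.phenotypes)
    cov = sim.phenotypes.line_covariates()
    null1 = permutation_null(sim.expression, ig, cov, n_perm=200,
                             genes_per_perm=5, seed=123)
    null2 = permutation_null(sim.expression, ig, cov, n_perm=200,
                             genes_per_perm=5, seed=123)
    pd.testing.assert_frame_equal(null1, null2)
    assert stats.kstest(null1["p"], "uniform").pvalue > 0.01
    # planted growth-linked genes do not inflate the permuted null
    assert abs(null1["p"].mean() - 0.5) < 0.02


# ---------------------------------------------------------------------------
# power comparison
# ---------------------------------------------------------------------------

def test_compare_power_identity_column(noise_expr):
    expr, ig = noise_expr
    out = compare_power(expr, ig, {"self": ig.values})
    assert np.allclose(out["p"]["igrowth"], out["p"]["self"])
    assert np.allclose(out["qq"]["igrowth"], out["qq"]["self"])


def test_compare_power_no_systematic_dominance_under_null(noise_expr):
    """Averaged over replicate null phenotype pairs, neither source dominates.

    Per-seed dominance fractions are highly variable (the sorted curves move
    coherently), so the check is on the mean over independent pairs.
    """
    expr, _ = noise_expr
    samples = expr.sample_ids
    doms = []
    for s in range(20):
        rng = np.random.default_rng(200 + s)
        a = _pheno(rng.normal(size=len(samples)), samples)
        b = pd.Series(rng.normal(size=len(samples)), index=samples)
        out = compare_power(expr, a, {"other": b})
        doms.append(np.mean(out["qq"]["igrowth"] >= out["qq"]["other"]))
    assert 0.35 <= float(np.mean(doms)) <= 0.65
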