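"""Mixed-model estimation: closed forms, oracles, invariances, and LRTs.

The helper :func:`direct_reml_criterion` evaluates -2 x restricted
log-likelihood directly from the dense marginal covariance
V = s2_line Z1 Z1' + s2_cond Z2 Z2' + s2_resid I (GLS beta, slogdet), a code
path entirely independent of the fitter's profiled Henderson-equation
criterion, so it can serve as an oracle.
"""

import subprocess
import sys
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from memgrowth import (
    MemSpec, PhenotypeTable, fit_mem, intrinsic_phenotype, lrt_fixed_effect,
    scenario, simulate,
)
from memgrowth.errors import ConfigurationError, EstimationError
from memgrowth.mem import _fixed_design

from conftest import balanced_single_condition


def direct_reml_criterion(table: PhenotypeTable, spec: MemSpec, variances, s2_resid):
    """-2 restricted log-likelihood from the explicit marginal covariance."""
    df = table.data
    y = df["value"].to_numpy(dtype=float)
    X, _, _ = _fixed_design(df, spec.fixed_effects)
    n, p = X.shape
    V = s2_resid * np.eye(n)
    for factor, s2 in zip(spec.random_effects, variances):
        Z = pd.get_dummies(df[factor]).to_numpy(dtype=float)
        V += s2 * Z @ Z.T
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    A = XtVi @ X
    sign_a, logdet_A = np.linalg.slogdet(A)
    beta = np.linalg.solve(A, XtVi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    return logdet_V + logdet_A + quad + (n - p) * np.log(2 * np.pi)


def fit_criterion(table, spec, fit):
    vs = [fit.variance_components[f] for f in spec.random_effects]
    return direct_reml_criterion(table, spec, vs, fit.sigma2_resid)


# ---------------------------------------------------------------------------
# closed forms and limits
# ---------------------------------------------------------------------------

def test_balanced_single_condition_blup_closed_form():
    """In a balanced one-condition design, the BLUP is the shrunken line-mean
    deviation with factor n s2_line / (n s2_line + s2_resid)."""
    table = balanced_single_condition(n_lines=12, n_reps=5)
    spec = MemSpec(random_effects=("line_id",))
    fit = fit_mem(table, spec)
    n_rep = 5
    shrink = n_rep * fit.sigma2_line / (n_rep * fit.sigma2_line + fit.sigma2_resid)

    df = table.data
    X, names, _ = _fixed_design(df, spec.fixed_effects)
    fitted_fixed = X @ fit.beta.to_numpy()
    resid = df["value"].to_numpy() - fitted_fixed
    line_mean_resid = pd.Series(resid).groupby(df["line_id"].to_numpy()).mean()
    expected = shrink * line_mean_resid
    assert np.allclose(fit.blup_line.sort_index(), expected.sort_index(), atol=1e-6)


def test_zero_noise_limit_degenerates_cleanly():
    """Identical replicates within and across conditions leave all variation
    to the line component: condition and residual variances collapse to ~0
    and BLUPs are the unshrunk line deviations from the fixed fit."""
    rows = []
    for i, val in enumerate([100.0, 110.0, 120.0, 130.0]):
        for j in range(2):
            for k in range(2):
                rows.append((f"L{i}", "CEU", "male" if i % 2 else "female",
                             f"C{j}", f"r{k}", val))
    table = PhenotypeTable(pd.DataFrame(
        rows, columns=["line_id", "population", "gender", "condition_id",
                       "replicate_id", "value"]))
    spec = MemSpec(fixed_effects=("gender",))
    fit = fit_mem(table, spec)
    scale = np.var(table.data["value"])
    assert fit.sigma2_cond < 1e-6 * scale
    assert fit.sigma2_resid < 1e-6 * scale
    X, _, _ = _fixed_design(table.data, spec.fixed_effects)
    resid = table.data["value"].to_numpy() - X @ fit.beta.to_numpy()
    dev = pd.Series(resid).groupby(table.data["line_id"].to_numpy()).mean()
    assert np.allclose(fit.blup_line.sort_index(), dev.sort_index(), atol=1e-4)


def test_reml_beats_coarse_grid(toy_table):
    """The optimizer's criterion is at least as good as a coarse grid search
    evaluated through the independent dense-V code path."""
    spec = MemSpec()
    fit = fit_mem(toy_table, spec)
    crit_fit = fit_criterion(toy_table, spec, fit)
    total = float(np.var(toy_table.data["value"]))
    grid = np.linspace(total * 1e-3, total * 1.5, 12)
    best = np.inf
    for a in grid:
        for b in grid:
            for c in grid:
                best = min(best, direct_reml_criterion(toy_table, spec, (a, b), c))
    assert crit_fit <= best + 1e-6


def test_lme4_oracle_agreement(tmp_path):
    """Variance components, fixed effects, and BLUPs match R lme4's REML fit."""
    cfg = replace(scenario("null", seed=5), n_lines=80, n_conditions=8,
                  sigma_cond=12_000.0, n_genes=2, n_snps=2, n_eqtls=0)
    sim = simulate(cfg)
    fit = fit_mem(sim.phenotypes)
    pheno_path = tmp_path / "p.tsv"
    from memgrowth.io import write_phenotypes
    write_phenotypes(sim.phenotypes, pheno_path)
    rscript = tmp_path / "fit.R"
    rscript.write_text(f"""
suppressMessages(library(lme4))
d <- read.delim("{pheno_path}")
m <- lmer(value ~ gender + population + (1|line_id) + (1|condition), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(m))
cat(vc$vcov[vc$grp=="line_id"], vc$vcov[vc$grp=="condition"],
    vc$vcov[vc$grp=="Residual"], fixef(m)["(Intercept)"], "\\n")
r <- ranef(m)$line_id
write.table(data.frame(line=rownames(r), blup=r[,1]), "{tmp_path}/blup.tsv",
            sep="\\t", row.names=FALSE, quote=FALSE)
""")
    out = subprocess.run(["Rscript", str(rscript)], capture_output=True, text=True,
                         timeout=300)
    assert out.returncode == 0, out.stderr
    s2l, s2c, s2e, intercept = map(float, out.stdout.split())
    scale = s2l + s2c + s2e
    assert fit.sigma2_line == pytest.approx(s2l, rel=1e-3, abs=1e-5 * scale)
    assert fit.sigma2_cond == pytest.approx(s2c, rel=1e-3, abs=1e-5 * scale)
    assert fit.sigma2_resid == pytest.approx(s2e, rel=1e-3, abs=1e-5 * scale)
    assert fit.beta["Intercept"] == pytest.approx(intercept, rel=1e-6)
    blup_r = pd.read_csv(tmp_path / "blup.tsv", sep="\t").set_index("line")["blup"]
    assert np.allclose(fit.blup_line.sort_index(), blup_r.sort_index(), rtol=1e-3,
                       atol=1e-3 * np.abs(blup_r).max())


# ---------------------------------------------------------------------------
# invariances and structural properties
# ---------------------------------------------------------------------------

def test_shift_invariance(toy_table):
    """Adding a constant shifts the intercept only; variance components and
    BLUPs are unchanged."""
    fit0 = fit_mem(toy_table)
    shifted = PhenotypeTable(toy_table.data.assign(value=toy_table.data["value"] + 500.0))
    fit1 = fit_mem(shifted)
    assert fit1.beta["Intercept"] - fit0.beta["Intercept"] == pytest.approx(500.0, abs=1e-6)
    scale = float(np.var(toy_table.data["value"]))
    for f in fit0.variance_components:
        assert fit1.variance_components[f] == pytest.approx(
            fit0.variance_components[f], rel=1e-4, abs=1e-6 * scale)
    assert np.allclose(fit0.blup_line, fit1.blup_line, atol=1e-5 * np.sqrt(scale))


def test_blup_shrinks_toward_zero(small_sim):
    """|BLUP| never exceeds the raw line-mean residual magnitude."""
    table = small_sim.phenotypes
    fit = fit_mem(table)
    df = table.data
    X, _, _ = _fixed_design(df, fit.spec.fixed_effects)
    resid = df["value"].to_numpy() - X @ fit.beta.to_numpy()
    # remove condition effects before comparing per-line means
    resid = resid - fit.blup_cond.reindex(df["condition_id"]).to_numpy()
    line_mean = pd.Series(resid).groupby(df["line_id"].to_numpy()).mean()
    blup = fit.blup_line.sort_index()
    assert (np.abs(blup.to_numpy())
            <= np.abs(line_mean.sort_index().to_numpy()) + 1e-8).all()


def test_intrinsic_gender_difference_is_exact_coefficient(toy_table):
    fit = fit_mem(toy_table)
    ig = intrinsic_phenotype(fit, toy_table)
    # L0 (male) and L1 (female) share population CEU
    diff = (ig.values["L1"] - fit.blup_line["L1"]) - (ig.values["L0"] - fit.blup_line["L0"])
    assert diff == pytest.approx(fit.beta["gender[male]"] * -1.0, abs=1e-10)


def test_intrinsic_tracks_truth_better_than_any_single_condition():
    cfg = replace(scenario("null", seed=21), n_lines=150, n_conditions=5,
                  sigma_cond=9000.0, n_genes=2, n_snps=2, n_eqtls=0)
    sim = simulate(cfg)
    fit = fit_mem(sim.phenotypes)
    ig = intrinsic_phenotype(fit, sim.phenotypes)
    truth = sim.truth.lines["true_intrinsic"]
    r_ig = np.corrcoef(ig.values, truth.loc[ig.values.index])[0, 1]
    for cond, series in sim.phenotypes.per_condition_means().items():
        r_cond = np.corrcoef(series, truth.loc[series.index])[0, 1]
        assert r_ig > r_cond


def test_singleton_lines_warned(caplog):
    rows = [("L1", "CEU", "male", "C1", "r1", 10.0),
            ("L1", "CEU", "male", "C2", "r1", 11.0),
            ("L2", "CEU", "female", "C1", "r1", 12.0),
            ("L2", "CEU", "female", "C2", "r1", 13.0),
            ("L3", "YRI", "male", "C1", "r1", 14.0)]
    table = PhenotypeTable(pd.DataFrame(
        rows, columns=["line_id", "population", "gender", "condition_id",
                       "replicate_id", "value"]))
    with caplog.at_level("WARNING"):
        fit_mem(table)
    assert any("L3" in rec.message for rec in caplog.records)


def test_rank_deficient_fixed_design_raises():
    rows = []  # gender perfectly aliased with population
    for i in range(6):
        pop = "CEU" if i < 3 else "YRI"
        gen = "female" if pop == "CEU" else "male"
        for j in range(2):
            rows.append((f"L{i}", pop, gen, f"C{j}", "r1", float(i + j)))
    table = PhenotypeTable(pd.DataFrame(
        rows, columns=["line_id", "population", "gender", "condition_id",
                       "replicate_id", "value"]))
    with pytest.raises(EstimationError, match="aliased"):
        fit_mem(table)


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

def test_lrt_single_level_effect_rejected(toy_table):
    mono = PhenotypeTable(toy_table.data.assign(gender="female"))
    with pytest.raises(ConfigurationError, match="single level"):
        lrt_fixed_effect(mono, MemSpec(), "gender")


def test_lrt_detects_strong_effect_with_correct_df():
    cfg = replace(scenario("null", seed=9), n_lines=200, n_conditions=4,
                  gender_effect=-0.15, n_genes=2, n_snps=2, n_eqtls=0)
    sim = simulate(cfg)
    res = lrt_fixed_effect(sim.phenotypes, MemSpec(), "gender")
    assert res["df"] == 1
    assert res["p"] < 0.01
    res_pop = lrt_fixed_effect(sim.phenotypes, MemSpec(), "population")
    assert res_pop["df"] == 3


def test_lrt_null_pvalues_approximately_uniform():
    """Under no gender effect the LRT p-value is ~ Uniform(0, 1)."""
    from scipy import stats
    ps = []
    for s in range(120):
        cfg = replace(scenario("null", seed=1000 + s), n_lines=60, n_conditions=3,
                      n_genes=2, n_snps=2, n_eqtls=0)
        sim = simulate(cfg)
        ps.append(lrt_fixed_effect(sim.phenotypes, MemSpec(), "gender")["p"])
    assert stats.kstest(ps, "uniform").pvalue > 0.01
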