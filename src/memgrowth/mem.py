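"""Crossed-random-effects linear mixed model for intrinsic-phenotype estimation.

The model for a replicated measurement of line *i* under experimental
condition *j*, replicate *k*, is

    y_ijk = x_i' beta + u_i + v_j + e_ijk,

with u ~ N(0, sigma2_line I), v ~ N(0, sigma2_cond I), e ~ N(0, sigma2_resid I)
mutually independent; the two grouping factors are crossed, not nested.
Fixed covariates (gender, population by default) are treatment-coded.

Variance components are estimated by REML (ML on request) by profiling beta
and the residual variance out of the Gaussian likelihood and optimizing over
the log variance ratios gamma_f = sigma2_f / sigma2_resid.  For a candidate
gamma the criterion is evaluated through the mixed-model (Henderson) normal
equations

    C = [[X'X, X'Z], [Z'X, Z'Z + diag(1/gamma)]],

whose Cholesky factor yields both the generalized-least-squares beta, the
BLUPs, and the log-determinants needed for the (restricted) likelihood:

    -2 l_REML = (n-p) (1 + log(2 pi rss/(n-p))) + log|C| + sum_f q_f log gamma_f
    -2 l_ML   = n (1 + log(2 pi rss/n)) + log|Z'Z + diag(1/gamma)| + sum_f q_f log gamma_f

where rss is the minimized penalized residual sum of squares, which equals
the GLS quadratic form (y - X beta)' V^-1 (y - X beta) in residual-variance
units.  The intrinsic phenotype of a line is its BLUP plus the estimated
fixed-effect contributions (intercept included), so values stay on the
measurement scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import ConfigurationError, EstimationError
from .io import PhenotypeTable

log = logging.getLogger(__name__)

LINE_FACTOR = "line_id"

#: optimization bounds on log variance ratios; gamma spans ~[3e-7, 3e6],
#: wide enough to represent an effectively-zero or unshrunk component while
#: keeping the normal equations numerically well posed.
_LOG_GAMMA_BOUNDS = (-15.0, 15.0)


@dataclass(frozen=True)
class MemSpec:
    """Model specification: which covariates are fixed, which factors random."""

    fixed_effects: tuple[str, ...] = ("gender", "population")
    random_effects: tuple[str, ...] = (LINE_FACTOR, "condition_id")
    reml: bool = True

    def __post_init__(self) -> None:
        if LINE_FACTOR not in self.random_effects:
            raise ConfigurationError(
                f"{LINE_FACTOR!r} must be a random effect (it defines the intrinsic value)"
            )
        overlap = set(self.fixed_effects) & set(self.random_effects)
        if overlap:
            raise ConfigurationError(f"factors cannot be both fixed and random: {sorted(overlap)}")


@dataclass
class MemFit:
    """Fitted mixed model: coefficients, variance components, BLUPs, likelihood."""

    beta: pd.Series                      # intercept + treatment-coded coefficients
    variance_components: dict[str, float]  # per random factor
    sigma2_resid: float
    blups: dict[str, pd.Series]          # per random factor, indexed by level
    loglik: float                        # maximized (restricted) log-likelihood
    converged: bool
    reml: bool
    n_obs: int
    group_sizes: dict[str, int]
    spec: MemSpec
    fixed_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sigma2_line(self) -> float:
        return self.variance_components[LINE_FACTOR]

    @property
    def sigma2_cond(self) -> float | None:
        for f, v in self.variance_components.items():
            if f != LINE_FACTOR:
                return v
        return None

    @property
    def blup_line(self) -> pd.Series:
        return self.blups[LINE_FACTOR]

    @property
    def blup_cond(self) -> pd.Series | None:
        for f, v in self.blups.items():
            if f != LINE_FACTOR:
                return v
        return None

    @property
    def n_lines(self) -> int:
        return self.group_sizes[LINE_FACTOR]

    @property
    def n_conds(self) -> int:
        return sum(v for f, v in self.group_sizes.items() if f != LINE_FACTOR)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "variance_components": self.variance_components,
            "sigma2_resid": self.sigma2_resid,
            "loglik": self.loglik,
            "converged": self.converged,
            "reml": self.reml,
            "n_obs": self.n_obs,
            "group_sizes": self.group_sizes,
            "fixed_effects": list(self.spec.fixed_effects),
            "random_effects": list(self.spec.random_effects),
        }


@dataclass
class IntrinsicPhenotype:
    """Per-line intrinsic phenotype on the measurement scale."""

    values: pd.Series  # index: line_id
    provenance: dict

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _fixed_design(df: pd.DataFrame, fixed_effects: tuple[str, ...]):
    """Intercept + treatment-coded dummies; reference = lexicographically first level."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["Intercept"]
    levels_map: dict[str, list[str]] = {}
    for factor in fixed_effects:
        if factor not in df.columns:
            raise ConfigurationError(f"fixed effect {factor!r} not found in phenotype table")
        levels = sorted(df[factor].unique())
        levels_map[factor] = levels
        for lev in levels[1:]:
            cols.append((df[factor] == lev).to_numpy(dtype=float))
            names.append(f"{factor}[{lev}]")
    X = np.column_stack(cols)
    # rank check with pivoted QR so aliased columns can be named
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise EstimationError(f"fixed-effect design is rank deficient; aliased: {aliased}")
    return X, names, levels_map


def _random_design(df: pd.DataFrame, factor: str):
    if factor not in df.columns:
        raise ConfigurationError(f"random effect {factor!r} not found in phenotype table")
    levels = sorted(df[factor].unique())
    idx = {lev: i for i, lev in enumerate(levels)}
    codes = df[factor].map(idx).to_numpy()
    Z = np.zeros((len(df), len(levels)))
    Z[np.arange(len(df)), codes] = 1.0
    return Z, levels


# ---------------------------------------------------------------------------
# profiled (RE)ML criterion
# ---------------------------------------------------------------------------

class _Workspace:
    """Pre-computed cross-products for repeated criterion evaluations."""

    def __init__(self, y, X, Z_blocks):
        self.y = y
        self.n, self.p = X.shape
        self.q_sizes = [Z.shape[1] for Z in Z_blocks]
        self.q = sum(self.q_sizes)
        Z = np.hstack(Z_blocks) if Z_blocks else np.empty((self.n, 0))
        M = np.hstack([X, Z])
        self.MtM = M.T @ M
        self.Mty = M.T @ y
        self.yty = float(y @ y)

    def solve(self, gammas: np.ndarray):
        """Return (solution a=[beta, u], rss, logdet C, logdet (Z'Z + D))."""
        C = self.MtM.copy()
        d = np.concatenate([np.full(q, 1.0 / g) for q, g in zip(self.q_sizes, gammas)]) \
            if self.q else np.empty(0)
        idx = np.arange(self.p, self.p + self.q)
        C[idx, idx] += d
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        a = linalg.cho_solve(cf, self.Mty, check_finite=False)
        rss = self.yty - float(self.Mty @ a)
        rss = max(rss, 1e-300)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        # Schur complement of X'X block gives |C| = |X'X block part| * ...; we
        # need |Z'Z + D| separately for the ML criterion
        ZtZD = self.MtM[self.p:, self.p:].copy()
        jdx = np.arange(self.q)
        ZtZD[jdx, jdx] += d
        try:
            cfz = linalg.cho_factor(ZtZD, lower=True, check_finite=False)
            logdet_Z = 2.0 * float(np.sum(np.log(np.diag(cfz[0]))))
        except linalg.LinAlgError:
            return None
        return a, rss, logdet_C, logdet_Z

    def criterion(self, log_gammas: np.ndarray, reml: bool) -> float:
        """-2 times the profiled (restricted) log-likelihood."""
        out = self.solve(np.exp(log_gammas))
        if out is None:
            return np.inf
        _, rss, logdet_C, logdet_Z = out
        qlog = float(np.dot(self.q_sizes, log_gammas))
        if reml:
            nmp = self.n - self.p
            return nmp * (1.0 + np.log(2.0 * np.pi * rss / nmp)) + logdet_C + qlog
        return self.n * (1.0 + np.log(2.0 * np.pi * rss / self.n)) + logdet_Z + qlog


def _moment_start(y, X, df, factors) -> np.ndarray:
    """ANOVA-flavoured starting ratios: between-group share of OLS residual variance."""
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    tot = max(float(np.var(resid)), 1e-12)
    start = []
    for factor in factors:
        gm = pd.Series(resid).groupby(df[factor].to_numpy()).mean()
        between = float(np.var(gm.to_numpy())) if len(gm) > 1 else 0.0
        start.append(np.clip(between / tot, 1e-3, 1e3))
    return np.log(np.asarray(start))


def fit_mem(table: PhenotypeTable, spec: MemSpec | None = None) -> MemFit:
    """Fit the crossed-random-effects model and return estimates and BLUPs.

    Variance components maximize the REML criterion (ML when ``spec.reml`` is
    False); beta is the GLS estimate at the optimum and the BLUPs solve
    Henderson's mixed-model equations there.  A boundary estimate (a variance
    component indistinguishable from zero) is a valid outcome.
    """
    spec = spec or MemSpec()
    df = table.data
    y = df["value"].to_numpy(dtype=float)

    X, fixed_names, fixed_levels = _fixed_design(df, spec.fixed_effects)
    Z_blocks, level_lists = [], []
    for factor in spec.random_effects:
        Z, levels = _random_design(df, factor)
        Z_blocks.append(Z)
        level_lists.append(levels)

    singletons = df[LINE_FACTOR].value_counts()
    singletons = singletons[singletons == 1].index.tolist()
    if singletons:
        log.warning("line(s) with a single observation (BLUP strongly shrunk): %s",
                    singletons[:20])

    ws = _Workspace(y, X, Z_blocks)
    lam0 = _moment_start(y, X, df, spec.random_effects)
    lam0 = np.clip(lam0, *_LOG_GAMMA_BOUNDS)

    res = optimize.minimize(
        ws.criterion, lam0, args=(spec.reml,), method="L-BFGS-B",
        bounds=[_LOG_GAMMA_BOUNDS] * len(lam0),
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    # derivative-free polish; cheap and robust to finite-difference noise
    polish = optimize.minimize(
        ws.criterion, res.x, args=(spec.reml,), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    best = polish if polish.fun <= res.fun else res
    lam_hat = np.clip(best.x, *_LOG_GAMMA_BOUNDS)
    converged = bool(res.success or polish.success)
    if not converged:
        log.warning("mixed-model optimizer did not report convergence: %s", best.message)

    gammas = np.exp(lam_hat)
    out = ws.solve(gammas)
    if out is None:
        raise EstimationError("normal equations singular at the reported optimum")
    a, rss, _, _ = out
    denom = ws.n - ws.p if spec.reml else ws.n
    sigma2_resid = rss / denom

    beta = pd.Series(a[: ws.p], index=fixed_names)
    blups: dict[str, pd.Series] = {}
    offset = ws.p
    variance_components: dict[str, float] = {}
    group_sizes: dict[str, int] = {}
    for factor, levels, g in zip(spec.random_effects, level_lists, gammas):
        q = len(levels)
        blups[factor] = pd.Series(a[offset: offset + q], index=levels)
        offset += q
        variance_components[factor] = float(g * sigma2_resid)
        group_sizes[factor] = q

    return MemFit(
        beta=beta,
        variance_components=variance_components,
        sigma2_resid=float(sigma2_resid),
        blups=blups,
        loglik=-0.5 * float(best.fun),
        converged=converged,
        reml=spec.reml,
        n_obs=ws.n,
        group_sizes=group_sizes,
        spec=spec,
        fixed_levels=fixed_levels,
    )


# ---------------------------------------------------------------------------
# intrinsic phenotype
# ---------------------------------------------------------------------------

def intrinsic_phenotype(fit: MemFit, table: PhenotypeTable) -> IntrinsicPhenotype:
    """Compose per-line intrinsic values: intercept + fixed-effect contributions + BLUP.

    The intercept is included so values stay on the assay measurement scale.
    """
    line_cov = table.line_covariates()
    blup = fit.blup_line
    missing = [l for l in line_cov.index if l not in blup.index]
    if missing:
        raise KeyError(f"line(s) absent from fit: {missing[:10]}")
    values = {}
    for line, row in line_cov.iterrows():
        v = fit.beta["Intercept"]
        for factor in fit.spec.fixed_effects:
            key = f"{factor}[{row[factor]}]"
            if key in fit.beta.index:
                v += fit.beta[key]
        values[line] = v + blup[line]
    series = pd.Series(values, name="igrowth")
    series.index.name = "line_id"
    provenance = {
        "model": fit.to_dict(),
        "definition": "intercept + fixed-effect estimates (population, gender) + line BLUP",
    }
    return IntrinsicPhenotype(values=series, provenance=provenance)


def write_intrinsic(ipheno: IntrinsicPhenotype, fit: MemFit, table: PhenotypeTable,
                    tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """TSV of line_id, igrowth, blup, population, gender plus a JSON fit sidecar."""
    cov = table.line_covariates()
    df = pd.DataFrame({
        "igrowth": ipheno.values,
        "blup": fit.blup_line.reindex(ipheno.values.index),
        "population": cov["population"],
        "gender": cov["gender"],
    })
    df.to_csv(tsv_path, sep="\t", index_label="line_id")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(ipheno.provenance, indent=2, default=float))


# ---------------------------------------------------------------------------
# likelihood-ratio tests for fixed effects
# ---------------------------------------------------------------------------

def lrt_fixed_effect(table: PhenotypeTable, spec: MemSpec, effect: str) -> dict:
    """Likelihood-ratio test for one fixed effect; both fits use ML.

    Returns ``{"chi2": ..., "df": ..., "p": ...}`` where df is the number of
    treatment-coded columns the reduced model drops.
    """
    spec = spec or MemSpec()
    if effect not in spec.fixed_effects:
        raise ConfigurationError(f"{effect!r} is not a fixed effect of the model")
    n_levels = table.data[effect].nunique()
    df_test = n_levels - 1
    if df_test == 0:
        raise ConfigurationError(
            f"fixed effect {effect!r} has a single level; the test is undefined"
        )
    full_spec = replace(spec, reml=False)
    reduced_spec = replace(
        spec, reml=False,
        fixed_effects=tuple(f for f in spec.fixed_effects if f != effect),
    )
    full = fit_mem(table, full_spec)
    reduced = fit_mem(table, reduced_spec)
    if not reduced.converged:
        raise EstimationError(f"reduced model (without {effect!r}) failed to converge")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df_test))
    return {"chi2": float(chi2), "df": int(df_test), "p": p}
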