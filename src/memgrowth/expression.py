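"""Per-gene association of expression with the intrinsic phenotype.

Each gene's log expression is regressed (OLS) on the intrinsic phenotype,
categorical covariates (population, gender), and optionally a small set of
surrogate variables capturing expression heterogeneity.  The per-gene p-value
is the two-sided t-test on the intrinsic-phenotype coefficient; false
discovery rates use Storey q-values.  A permutation-null generator produces
the reference distribution for QQ plots.

The surrogate variables are estimated in a two-step form: the expression
matrix is residualized against the full primary model, the residuals are
decomposed by singular values, and the number of components to keep is
chosen by parallel analysis against row-wise permutations of the residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EstimationError, ValidationError
from .io import ExpressionMatrix
from .mem import IntrinsicPhenotype

log = logging.getLogger(__name__)

MIN_SHARED_SAMPLES = 10


@dataclass
class SurrogateVariables:
    """Orthonormal sample-space factors for expression heterogeneity."""

    matrix: pd.DataFrame       # samples x k, orthonormal columns
    k: int
    trace: pd.DataFrame        # observed vs permuted variance shares per component

    def __len__(self) -> int:
        return self.k


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _covariate_design(samples: list[str], covariates: pd.DataFrame | None) -> np.ndarray:
    """Treatment-coded covariate columns (no intercept), aligned to ``samples``."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((len(samples), 0))
    cov = covariates.loc[samples]
    cols = []
    for name in cov.columns:
        col = cov[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            for lev in sorted(col.unique())[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(samples), 0))


def _shared_samples(expr: ExpressionMatrix, igrowth: IntrinsicPhenotype) -> list[str]:
    shared = [s for s in expr.sample_ids if s in igrowth.values.index]
    dropped = len(expr.sample_ids) - len(shared)
    if dropped:
        log.info("dropping %d expression sample(s) without an intrinsic value", dropped)
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValidationError(
            f"only {len(shared)} samples shared between expression and phenotype; "
            f"need at least {MIN_SHARED_SAMPLES}"
        )
    return shared


def _design(samples, phenotype: np.ndarray, covariates, sv: SurrogateVariables | None):
    parts = [np.ones(len(samples)), np.asarray(phenotype, dtype=float)]
    names = ["Intercept", "igrowth"]
    C = _covariate_design(samples, covariates)
    for j in range(C.shape[1]):
        parts.append(C[:, j])
        names.append(f"cov{j}")
    if sv is not None and sv.k > 0:
        S = sv.matrix.loc[samples].to_numpy()
        for j in range(S.shape[1]):
            parts.append(S[:, j])
            names.append(f"sv{j + 1}")
    M = np.column_stack(parts)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise EstimationError("association design matrix is rank deficient")
    return M, names


def _ols_many(Y: np.ndarray, M: np.ndarray, coef_index: int = 1):
    """Vectorized OLS of every row of Y on M; stats for column ``coef_index``.

    Returns (beta, se, t, p, dof) arrays, one entry per row of Y.  Rows with
    zero variance get beta 0, p 1 (flagged by the caller).
    """
    n, d = M.shape
    dof = n - d
    if dof <= 0:
        raise EstimationError(f"no residual degrees of freedom (n={n}, d={d})")
    MtM_inv = np.linalg.inv(M.T @ M)
    H = MtM_inv @ M.T                       # d x n
    B = Y @ H.T                             # genes x d
    resid = Y - B @ M.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / dof
    var_scale = MtM_inv[coef_index, coef_index]
    se = np.sqrt(np.maximum(sigma2 * var_scale, 0.0))
    beta = B[:, coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p, dof


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def associate(expr: ExpressionMatrix, igrowth: IntrinsicPhenotype,
              covariates: pd.DataFrame | None = None,
              sv: SurrogateVariables | None = None,
              qvalue_lambda: float = 0.5) -> pd.DataFrame:
    """Per-gene OLS of log expression on the intrinsic phenotype.

    Returns a DataFrame indexed by gene with columns beta, se, t, p, q and a
    ``constant`` flag for zero-variance genes (which get p = 1 rather than an
    exception, keeping the number of tests stable for the FDR step).
    """
    samples = _shared_samples(expr, igrowth)
    Y = expr.values[samples].to_numpy(dtype=float)
    g = igrowth.values.loc[samples].to_numpy()
    M, _ = _design(samples, g, covariates, sv)
    beta, se, t, p, _ = _ols_many(Y, M)
    const = Y.std(axis=1) == 0.0
    beta = np.where(const, 0.0, beta)
    se = np.where(const, np.nan, se)
    t = np.where(const, 0.0, t)
    p = np.where(const, 1.0, p)
    qres = qvalues(p, lam=qvalue_lambda)
    return pd.DataFrame(
        {"beta": beta, "se": se, "t": t, "p": p, "q": qres["q"], "constant": const},
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


def qvalues(p: np.ndarray, lam: float = 0.5) -> dict:
    """Storey q-values with a single tuning parameter lambda.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) m)); the q-value of the i-th
    smallest p is min over j >= i of pi0 * m * p_(j) / j, returned in the
    original order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 <= lam < 1:
        raise ConfigurationError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = min(1.0, float(np.sum(p > lam)) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return {"q": q, "pi0": pi0}


def estimate_sv(expr: ExpressionMatrix, primary: IntrinsicPhenotype,
                covariates: pd.DataFrame | None = None,
                n_perm: int = 20, alpha: float = 0.05,
                seed: int | None = None) -> SurrogateVariables:
    """Estimate surrogate variables from residual expression structure.

    The expression matrix is residualized against the primary model
    (intercept, intrinsic phenotype, covariates); singular components of the
    residual matrix are retained while their variance share exceeds the
    (1 - alpha) quantile of shares obtained from ``n_perm`` independent
    row-wise permutations of the residuals.  k = 0 is a valid outcome.
    """
    rng = np.random.default_rng(seed)
    samples = _shared_samples(expr, primary)
    Y = expr.values[samples].to_numpy(dtype=float)
    g = primary.values.loc[samples].to_numpy()
    M, _ = _design(samples, g, covariates, None)
    H = M @ np.linalg.inv(M.T @ M) @ M.T
    R = Y - Y @ H                                  # genes x samples residuals
    svals = np.linalg.svd(R, compute_uv=False)
    shares = svals**2 / max(np.sum(svals**2), 1e-300)
    n_comp = len(shares)

    perm_shares = np.empty((n_perm, n_comp))
    for b in range(n_perm):
        # re-residualize after permuting so the null spectrum lives in the
        # same rank-reduced subspace as the observed residuals
        Rp = rng.permuted(R, axis=1)
        Rp = Rp - Rp @ H
        sp = np.linalg.svd(Rp, compute_uv=False)
        perm_shares[b] = sp**2 / max(np.sum(sp**2), 1e-300)
    # conservative (ceil-rank) quantile so the keep decision errs toward k=0
    thresholds = np.quantile(perm_shares, 1.0 - alpha, axis=0, method="higher")

    k = 0
    while k < n_comp and shares[k] > thresholds[k]:
        k += 1
    _, _, Vt = np.linalg.svd(R, full_matrices=False)
    matrix = pd.DataFrame(
        Vt[:k].T, index=pd.Index(samples, name="sample_id"),
        columns=[f"sv{j + 1}" for j in range(k)],
    )
    trace = pd.DataFrame({
        "component": np.arange(1, n_comp + 1),
        "observed_share": shares,
        "permutation_threshold": thresholds,
    })
    return SurrogateVariables(matrix=matrix, k=k, trace=trace)


def permutation_null(expr: ExpressionMatrix, igrowth: IntrinsicPhenotype,
                     covariates: pd.DataFrame | None = None,
                     n_perm: int = 200, genes_per_perm: int = 1,
                     seed: int | None = None) -> pd.DataFrame:
    """Null association p-values obtained by permuting the phenotype.

    The intrinsic values are shuffled across samples while covariates stay
    with their samples, so the no-association null holds by construction; for
    each permutation ``genes_per_perm`` randomly sampled genes are tested.
    Returns a DataFrame with permutation index, gene id, and p.
    """
    samples = _shared_samples(expr, igrowth)
    Y = expr.values[samples].to_numpy(dtype=float)
    g = igrowth.values.loc[samples].to_numpy()
    rng = np.random.default_rng(seed)
    gene_ids = np.asarray(expr.gene_ids)
    rows = []
    for b in range(n_perm):
        gp = rng.permutation(g)
        gene_idx = rng.choice(len(gene_ids), size=genes_per_perm, replace=False)
        M, _ = _design(samples, gp, covariates, None)
        _, _, _, p, _ = _ols_many(Y[gene_idx], M)
        for gi, pv in zip(gene_idx, p):
            rows.append((b, gene_ids[gi], float(pv)))
    return pd.DataFrame(rows, columns=["perm", "gene_id", "p"])


def compare_power(expr: ExpressionMatrix, igrowth: IntrinsicPhenotype,
                  raw_by_condition: dict[str, pd.Series],
                  covariates: pd.DataFrame | None = None,
                  sv: SurrogateVariables | None = None) -> dict:
    """Association p-values per phenotype source: intrinsic vs each raw condition.

    ``raw_by_condition`` maps a condition label to a per-line phenotype
    Series (e.g. the raw within-condition mean).  Each source is analysed on
    the samples it shares with the expression matrix; when surrogate
    variables are supplied they adjust every source's model, so chance
    correlation between a phenotype source and expression heterogeneity does
    not distort the comparison.  Returns the per-gene p table plus sorted
    -log10 p columns for QQ comparison.
    """
    p_cols = {"igrowth": associate(expr, igrowth, covariates, sv=sv)["p"]}
    for cond, series in raw_by_condition.items():
        pheno = IntrinsicPhenotype(values=series.dropna(), provenance={"source": cond})
        res = associate(expr, pheno, covariates, sv=sv)
        p_cols[str(cond)] = res["p"]
    p_table = pd.DataFrame(p_cols)
    qq = {
        col: np.sort(-np.log10(np.maximum(p_table[col].to_numpy(), 1e-300)))[::-1]
        for col in p_table.columns
    }
    return {"p": p_table, "qq": qq}


def write_association(unadjusted: pd.DataFrame, adjusted: pd.DataFrame | None,
                      path) -> None:
    """TSV with unadjusted and (optionally) heterogeneity-adjusted columns."""
    out = unadjusted.rename(columns={"p": "p_unadjusted", "q": "q_unadjusted"})
    out = out[["beta", "se", "t", "p_unadjusted", "q_unadjusted"]]
    if adjusted is not None:
        out["p_sva"] = adjusted["p"]
        out["q_sva"] = adjusted["q"]
    out.to_csv(path, sep="\t", index_label="gene_id")
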