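"""Per-SNP linear association scan of the intrinsic phenotype on additive dosage.

Each SNP is tested with OLS of the phenotype on [intercept, dosage,
covariates]; the reported p-value is the two-sided t-test on the dosage
coefficient.  Missing dosages are mean-imputed per SNP inside the scan only;
SNPs below the minor-allele-frequency floor or without dosage variance are
skipped and logged.  Computation uses the Frisch-Waugh decomposition: the
phenotype and every dosage row are residualized against the covariate
design once, after which each SNP reduces to a simple regression, letting
the whole scan run as a few matrix products.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import GenotypeMatrix
from .mem import IntrinsicPhenotype

log = logging.getLogger(__name__)

MIN_SHARED_SAMPLES = 20


def _prepare(geno: GenotypeMatrix, igrowth: IntrinsicPhenotype,
             covariates: pd.DataFrame | None):
    shared = [s for s in geno.sample_ids if s in igrowth.values.index]
    if len(shared) == 0:
        raise ValidationError("no samples shared between genotypes and phenotype")
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValidationError(
            f"only {len(shared)} shared samples; need at least {MIN_SHARED_SAMPLES}"
        )
    G = geno.dosages[shared].to_numpy(dtype=float)
    y = igrowth.values.loc[shared].to_numpy()
    from .expression import _covariate_design
    C = _covariate_design(shared, covariates)
    M = np.column_stack([np.ones(len(shared)), C])
    return shared, G, y, M


def _impute_and_filter(G: np.ndarray, snp_ids: list[str], maf_min: float):
    """Mean-impute missing dosages; compute folded MAF; mark skipped SNPs."""
    n_used = np.sum(~np.isnan(G), axis=1)
    with np.errstate(invalid="ignore"):
        snp_mean = np.nanmean(G, axis=1)
    G_imp = np.where(np.isnan(G), snp_mean[:, None], G)
    af = snp_mean / 2.0
    maf = np.minimum(af, 1.0 - af)
    variance = G_imp.var(axis=1)
    keep = (maf >= maf_min) & (variance > 0)
    skipped = [snp_ids[i] for i in np.flatnonzero(~keep)]
    if skipped:
        log.info("skipped %d SNP(s) (maf < %g or monomorphic)", len(skipped), maf_min)
    return G_imp, maf, n_used, keep, skipped


def _scan_core(G_res: np.ndarray, y_res: np.ndarray, dof: int):
    """Simple-regression statistics of residualized phenotype on residualized dosage."""
    gg = np.einsum("ij,ij->i", G_res, G_res)
    gy = G_res @ y_res
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / gg, 0.0)
    rss = float(y_res @ y_res) - beta * gy
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / np.where(gg > 0, gg, np.nan))
        t = beta / se
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p


def scan(geno: GenotypeMatrix, igrowth: IntrinsicPhenotype,
         covariates: pd.DataFrame | None = None,
         maf_min: float = 0.05) -> pd.DataFrame:
    """Additive-dosage association scan; returns one row per tested SNP.

    Columns: beta, se, t, p, n_used, maf.  Skipped SNPs (monomorphic or
    maf < ``maf_min``) are recorded in the DataFrame ``attrs["skipped"]``.
    """
    shared, G, y, M = _prepare(geno, igrowth, covariates)
    snp_ids = geno.snp_ids
    G_imp, maf, n_used, keep, skipped = _impute_and_filter(G, snp_ids, maf_min)

    H = M @ np.linalg.inv(M.T @ M) @ M.T
    y_res = y - H @ y
    G_res = G_imp[keep] - G_imp[keep] @ H
    dof = len(shared) - M.shape[1] - 1
    beta, se, t, p = _scan_core(G_res, y_res, dof)

    idx = np.flatnonzero(keep)
    out = pd.DataFrame({
        "beta": beta, "se": se, "t": t, "p": p,
        "n_used": n_used[idx], "maf": maf[idx],
    }, index=pd.Index([snp_ids[i] for i in idx], name="snp_id"))
    out.attrs["skipped"] = skipped
    out.attrs["n_samples"] = len(shared)
    return out


def top_snps(results: pd.DataFrame, p_thresh: float) -> set[str]:
    """SNPs with association p below the threshold."""
    if not 0 < p_thresh <= 1:
        raise ValidationError(f"p_thresh must lie in (0, 1]; got {p_thresh}")
    return set(results.index[results["p"] < p_thresh])


def write_scan(results: pd.DataFrame, path) -> None:
    results[["beta", "se", "p", "n_used", "maf"]].to_csv(path, sep="\t", index_label="snp_id")
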