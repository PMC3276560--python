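"""Enrichment of growth-associated genes among eQTL targets of top SNPs.

Three procedures of increasing rigor:

1. ``fisher_overlap`` — one-sided hypergeometric (Fisher) test of the overlap
   between the target-gene set and the growth-gene set.  Exact, but assumes
   genes are independent.
2. ``enrich_method2`` — permutes the phenotype, reruns the SNP scan -> top
   SNPs -> eQTL-target pipeline each time against the *fixed* observed
   growth-gene set, and reports the proportion of permutation Fisher
   p-values at or below the observed one.  This respects the correlation
   structure among target genes.
3. ``enrich_method3`` — additionally recomputes the growth-gene set from the
   *same* permuted phenotype (unadjusted expression association at an FDR
   cut), accounting for the fact that the same individuals enter both the
   SNP and the expression associations.

``signature_overlap`` draws random gene sets of the signature's size from
the universe and counts how often they contain at least as many growth
genes as the signature does.

Empirical p-values are reported as the raw proportion (which can be zero);
the ``(r + 1) / (n + 1)`` corrected version is carried alongside.  Ties
(permutation p exactly equal to the observed p) count as at-least-as-extreme.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .gwas import _impute_and_filter, _prepare, _scan_core
from .io import EqtlMap, ExpressionMatrix, GeneSet, GenotypeMatrix
from .mem import IntrinsicPhenotype

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapTable:
    """2x2 overlap summary: universe m, |A| targets, |B| growth genes, overlap x."""

    m: int
    n_a: int
    n_b: int
    overlap: int

    def __post_init__(self) -> None:
        if self.overlap > min(self.n_a, self.n_b) or max(self.n_a, self.n_b) > self.m:
            raise ValidationError(f"inconsistent overlap table: {self}")


@dataclass
class EnrichmentResult:
    """Observed overlap plus Fisher and (optionally) permutation evidence."""

    observed: OverlapTable
    fisher_p: float
    empirical_p: float | None
    empirical_p_corrected: float | None
    n_perm: int
    trace: np.ndarray           # permutation fisher_p values, length n_perm
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "observed": vars(self.observed),
            "fisher_p": self.fisher_p,
            "empirical_p": self.empirical_p,
            "empirical_p_corrected": self.empirical_p_corrected,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def write_trace(self, path: str | Path) -> None:
        pd.DataFrame({"perm": np.arange(self.n_perm), "fisher_p": self.trace}) \
            .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# method 1: hypergeometric overlap
# ---------------------------------------------------------------------------

def fisher_overlap(universe: GeneSet, set_a: GeneSet, set_b: GeneSet) -> dict:
    """One-sided (enrichment) hypergeometric tail for the overlap of A and B.

    p = P(X >= x) for X ~ Hypergeom(m, |A|, |B|), where x is the observed
    overlap.  Both sets must be subsets of the universe.
    """
    for label, s in (("set_a", set_a), ("set_b", set_b)):
        stray = sorted(s.gene_ids - universe.gene_ids)
        if stray:
            raise ValidationError(f"{label} has gene(s) outside the universe: {stray[:10]}")
    m = len(universe)
    x = len(set_a.gene_ids & set_b.gene_ids)
    table = OverlapTable(m=m, n_a=len(set_a), n_b=len(set_b), overlap=x)
    p = float(stats.hypergeom.sf(x - 1, m, len(set_a), len(set_b)))
    return {"table": table, "p": p}


def _overlap_p(m: int, targets: set[str], growth: set[str]) -> float:
    x = len(targets & growth)
    return float(stats.hypergeom.sf(x - 1, m, len(targets), len(growth)))


# ---------------------------------------------------------------------------
# shared pipeline pieces
# ---------------------------------------------------------------------------

def _target_pipeline(G_res: np.ndarray, y_res: np.ndarray, dof: int,
                     kept_snps: np.ndarray, p_thresh: float,
                     eqtl: EqtlMap, universe_set: frozenset[str]) -> set[str]:
    """Scan -> top SNPs -> union of eQTL targets restricted to the universe."""
    _, _, _, p = _scan_core(G_res, y_res, dof)
    top = kept_snps[p < p_thresh]
    return eqtl.targets_of(top) & universe_set


def _restrict_growth(growth_genes: GeneSet, universe: GeneSet) -> set[str]:
    inside = growth_genes.gene_ids & universe.gene_ids
    dropped = len(growth_genes) - len(inside)
    if dropped:
        log.info("dropped %d growth gene(s) outside the universe", dropped)
    return set(inside)


def _finish(obs_p: float, trace: np.ndarray, table: OverlapTable,
            n_perm: int, seed, params: dict) -> EnrichmentResult:
    if n_perm > 0:
        r = int(np.sum(trace <= obs_p))
        empirical = r / n_perm
        corrected = (r + 1) / (n_perm + 1)
    else:
        empirical = corrected = None
    return EnrichmentResult(
        observed=table, fisher_p=obs_p, empirical_p=empirical,
        empirical_p_corrected=corrected, n_perm=n_perm, trace=trace,
        seed=seed, params=params,
    )


# ---------------------------------------------------------------------------
# method 2: phenotype permutation, fixed growth-gene set
# ---------------------------------------------------------------------------

def enrich_method2(geno: GenotypeMatrix, igrowth: IntrinsicPhenotype,
                   covariates: pd.DataFrame | None, eqtl: EqtlMap,
                   growth_genes: GeneSet, universe: GeneSet,
                   p_thresh: float, n_perm: int = 1000,
                   maf_min: float = 0.05, seed: int | None = None) -> EnrichmentResult:
    """Permutation enrichment with the observed growth-gene set held fixed.

    Each permutation shuffles the phenotype across samples, reruns the
    scan -> top-SNP -> eQTL-target pipeline, and records the Fisher p of the
    permuted target set against the fixed growth genes.  The empirical p is
    the proportion of permutation Fisher p-values <= the observed one.
    A permutation with an empty target set records Fisher p = 1.
    """
    rng = np.random.default_rng(seed)
    shared, G, y, M = _prepare(geno, igrowth, covariates)
    G_imp, _, _, keep, _ = _impute_and_filter(G, geno.snp_ids, maf_min)
    kept_snps = np.asarray(geno.snp_ids)[keep]
    H = M @ np.linalg.inv(M.T @ M) @ M.T
    G_res = G_imp[keep] - G_imp[keep] @ H
    dof = len(shared) - M.shape[1] - 1

    uni = universe.gene_ids
    growth = _restrict_growth(growth_genes, universe)
    m = len(universe)

    targets_obs = _target_pipeline(G_res, y - H @ y, dof, kept_snps, p_thresh, eqtl, uni)
    obs_p = _overlap_p(m, targets_obs, growth)
    table = OverlapTable(m=m, n_a=len(targets_obs), n_b=len(growth),
                         overlap=len(targets_obs & growth))

    trace = np.empty(n_perm)
    n_empty = 0
    for b in range(n_perm):
        yp = rng.permutation(y)
        targets = _target_pipeline(G_res, yp - H @ yp, dof, kept_snps, p_thresh, eqtl, uni)
        if not targets:
            n_empty += 1
        trace[b] = _overlap_p(m, targets, growth)
    if n_empty:
        log.info("method 2: %d/%d permutation(s) had an empty target set (fisher_p = 1)",
                 n_empty, n_perm)
    params = {"p_thresh": p_thresh, "maf_min": maf_min, "method": 2,
              "n_empty_target_perms": n_empty}
    return _finish(obs_p, trace, table, n_perm, seed, params)


# ---------------------------------------------------------------------------
# method 3: shared permutation drives both target and growth-gene sets
# ---------------------------------------------------------------------------

def enrich_method3(geno: GenotypeMatrix, expr: ExpressionMatrix,
                   igrowth: IntrinsicPhenotype, covariates: pd.DataFrame | None,
                   eqtl: EqtlMap, universe: GeneSet,
                   p_thresh: float, fdr_thresh: float, n_perm: int = 1000,
                   maf_min: float = 0.05, qvalue_lambda: float = 0.5,
                   seed: int | None = None) -> EnrichmentResult:
    """Permutation enrichment where one permuted phenotype drives both sets.

    The observed growth-gene set is recomputed here from the *unadjusted*
    expression association at ``q < fdr_thresh``; each permutation reuses a
    single permuted phenotype for both the SNP-target pipeline and the
    growth-gene recomputation, so the double use of the same individuals is
    reflected in the null.
    """
    from .expression import _ols_many, qvalues

    rng = np.random.default_rng(seed)
    shared_geno = set(geno.sample_ids) & set(igrowth.values.index)
    shared = [s for s in expr.sample_ids if s in shared_geno]
    if len(shared) < 20:
        raise ValidationError(
            f"only {len(shared)} samples shared among genotypes, expression, phenotype"
        )
    sub_geno = GenotypeMatrix(geno.dosages[shared])
    sub_pheno = IntrinsicPhenotype(values=igrowth.values.loc[shared],
                                   provenance=igrowth.provenance)
    _, G, y, M = _prepare(sub_geno, sub_pheno, covariates)
    G_imp, _, _, keep, _ = _impute_and_filter(G, sub_geno.snp_ids, maf_min)
    kept_snps = np.asarray(sub_geno.snp_ids)[keep]
    H = M @ np.linalg.inv(M.T @ M) @ M.T
    G_res = G_imp[keep] - G_imp[keep] @ H
    dof = len(shared) - M.shape[1] - 1

    Y = expr.values[shared].to_numpy(dtype=float)
    gene_ids = np.asarray(expr.gene_ids)
    in_universe = np.isin(gene_ids, sorted(universe.gene_ids))
    uni = universe.gene_ids
    m = len(universe)
    Cpart = M[:, 1:]  # covariate columns without intercept

    def growth_set(pheno_vec: np.ndarray) -> set[str]:
        D = np.column_stack([np.ones(len(shared)), pheno_vec, Cpart])
        _, _, _, p, _ = _ols_many(Y, D)
        q = qvalues(p, lam=qvalue_lambda)["q"]
        return set(gene_ids[(q < fdr_thresh) & in_universe])

    targets_obs = _target_pipeline(G_res, y - H @ y, dof, kept_snps, p_thresh, eqtl, uni)
    growth_obs = growth_set(y)
    obs_p = _overlap_p(m, targets_obs, growth_obs)
    table = OverlapTable(m=m, n_a=len(targets_obs), n_b=len(growth_obs),
                         overlap=len(targets_obs & growth_obs))

    trace = np.empty(n_perm)
    n_empty = 0
    for b in range(n_perm):
        yp = rng.permutation(y)
        targets = _target_pipeline(G_res, yp - H @ yp, dof, kept_snps, p_thresh, eqtl, uni)
        if not targets:
            n_empty += 1
        trace[b] = _overlap_p(m, targets, growth_set(yp))
    if n_empty:
        log.info("method 3: %d/%d permutation(s) had an empty target set (fisher_p = 1)",
                 n_empty, n_perm)
    params = {"p_thresh": p_thresh, "fdr_thresh": fdr_thresh, "maf_min": maf_min,
              "method": 3, "n_empty_target_perms": n_empty}
    return _finish(obs_p, trace, table, n_perm, seed, params)


# ---------------------------------------------------------------------------
# signature overlap by random sampling
# ---------------------------------------------------------------------------

def signature_overlap(universe: GeneSet, growth_genes: GeneSet, signature: GeneSet,
                      n_sim: int = 10000, seed: int | None = None) -> dict:
    """Random-sampling test of growth-gene content in an external signature.

    ``n_sim`` random gene sets of the signature's size are drawn uniformly
    without replacement from the universe; the empirical p is the proportion
    of draws containing at least as many growth genes as the signature.
    """
    stray = sorted(signature.gene_ids - universe.gene_ids)
    if stray:
        raise ValidationError(f"signature gene(s) outside the universe: {stray[:10]}")
    if len(signature) > len(universe):
        raise ValidationError("signature larger than the universe")
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(universe.gene_ids))
    is_growth = np.isin(genes, sorted(growth_genes.gene_ids & universe.gene_ids))
    k = len(signature)
    null_counts = np.empty(n_sim, dtype=int)
    for b in range(n_sim):
        idx = rng.choice(len(genes), size=k, replace=False)
        null_counts[b] = int(is_growth[idx].sum())
    observed = len(signature.gene_ids & growth_genes.gene_ids)
    empirical_p = float(np.mean(null_counts >= observed))
    return {"observed": observed, "null_counts": null_counts,
            "empirical_p": empirical_p, "n_sim": n_sim, "seed": seed}
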