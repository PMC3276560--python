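"""Synthetic cohort generator matching the statistical structure the mixed
model assumes, with full ground truth for every downstream module.

The generator emulates a replicated cell-line growth study: several hundred
lines from a few population groups with gender labels, measured under ~10
crossed experimental conditions ("technicians") with unbalanced coverage.
Phenotype values follow

    y_ijk = grand_mean * (1 + gender/population fractional effects)
            + u_i + v_j + e_ijk

with Gaussian line, condition, and residual components.  The expression
matrix is log-scale: a configured fraction of genes depends linearly on the
standardized true intrinsic value, all genes carry latent-heterogeneity
factor contributions and Gaussian noise, and eQTL SNPs add an additive
dosage term to their target gene.  Genotypes are Hardy-Weinberg binomial
dosages.  Optional knobs add a shared confounder that loads simultaneously
on the phenotype, allele frequencies, and expression (for stress-testing
the enrichment null) and SNP effects on the intrinsic phenotype itself
(for planted-signal power studies).

All randomness flows from a single ``numpy.random.default_rng(seed)``
stream with a fixed draw order (lines, conditions, genotypes, gene effects,
eQTL assignment, phenotype noise, expression), so one seed reproduces the
whole cohort byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    EqtlMap, ExpressionMatrix, GeneSet, GenotypeMatrix, PhenotypeTable,
    write_eqtl_map, write_expression, write_genotypes, write_phenotypes,
)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults describe the replicated LCL growth study."""

    # cohort
    n_lines: int = 500
    population_frequencies: dict = field(default_factory=lambda: {
        "ASN": 1 / 6, "ASW": 1 / 6, "CEU": 1 / 3, "YRI": 1 / 3,
    })
    gender_frequencies: dict = field(default_factory=lambda: {"female": 0.5, "male": 0.5})
    # phenotype model (assay units; grand mean on the raw alamar-number scale)
    grand_mean: float = 75_000.0
    gender_effect: float = -0.07          # fractional effect of female vs male
    population_effects: dict = field(default_factory=lambda: {
        "ASN": 0.020, "ASW": 0.057, "CEU": -0.044, "YRI": 0.026,
    })
    sigma_line: float = 12_000.0
    sigma_cond: float = 8_000.0
    sigma_resid: float = 16_000.0
    n_conditions: int = 10
    condition_coverage: float = 0.7       # P(line measured under a condition)
    replicates: int = 1                   # replicates per observed line x condition
    # expression model (log2 scale)
    n_genes: int = 10_748
    frac_growth_genes: float = 0.276
    expr_base_mean: float = 8.0
    expr_base_sd: float = 1.5
    growth_effect_mean: float = 0.2       # per SD of true intrinsic value
    growth_effect_sd: float = 0.3
    expr_noise_sd: float = 1.0
    n_latent_factors: int = 10
    latent_loading_sd: float = 0.3
    latent_pheno_loading: float = 0.0     # corr of factor 1 with the intrinsic value
    # genotypes and eQTLs
    n_snps: int = 5000
    maf_range: tuple = (0.05, 0.5)
    n_eqtls: int = 300
    eqtl_effect: float = 0.8              # log2 expression per alt allele
    frac_eqtls_targeting_growth_genes: float = 0.5
    snp_growth_effect: float = 0.0        # assay units per alt allele (growth-gene eQTLs)
    # shared-confounder knobs (ancestry-like factor touching everything)
    confounder_pheno_effect: float = 0.0  # assay units per SD of the confounder
    confounder_geno_loading: float = 0.0  # fractional MAF modulation per SD
    confounder_expr_loading_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 2 or self.n_conditions < 1 or self.replicates < 1:
            raise ConfigurationError("need >= 2 lines, >= 1 condition, >= 1 replicate")
        for name, freqs in (("population", self.population_frequencies),
                            ("gender", self.gender_frequencies)):
            total = sum(freqs.values())
            if not np.isclose(total, 1.0):
                raise ConfigurationError(f"{name} frequencies sum to {total}, not 1")
        if min(self.sigma_line, self.sigma_cond, self.sigma_resid) < 0:
            raise ConfigurationError("sigmas must be non-negative")
        if not 0 < self.condition_coverage <= 1:
            raise ConfigurationError("condition_coverage must lie in (0, 1]")
        for frac in (self.frac_growth_genes, self.frac_eqtls_targeting_growth_genes):
            if not 0 <= frac <= 1:
                raise ConfigurationError("fractions must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_eqtls > self.n_snps:
            raise ConfigurationError("n_eqtls cannot exceed n_snps")
        extra = set(self.population_effects) - set(self.population_frequencies)
        if extra:
            raise ConfigurationError(f"population_effects for unknown group(s): {sorted(extra)}")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    lines: pd.DataFrame            # index line_id: population, gender, u, genetic,
                                   # confounder, true_intrinsic
    condition_effects: pd.Series   # index condition_id
    genes: pd.DataFrame            # index gene_id: is_growth, effect
    snps: pd.Series                # index snp_id: drawn MAF
    factor_scores: pd.DataFrame    # lines x latent factors
    eqtls: pd.DataFrame            # snp_id, gene_id, effect, targets_growth_gene
    config: SimConfig

    @property
    def growth_genes(self) -> GeneSet:
        genes = self.genes.index[self.genes["is_growth"]]
        return GeneSet.from_iterable("true_growth_genes", genes)


@dataclass
class SimData:
    phenotypes: PhenotypeTable
    expression: ExpressionMatrix
    genotypes: GenotypeMatrix
    eqtl: EqtlMap
    truth: SimTruth


def simulate(config: SimConfig) -> SimData:
    """Generate a full synthetic cohort from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, J = config.n_lines, config.n_conditions

    # --- lines -------------------------------------------------------------
    line_ids = [f"L{i:04d}" for i in range(n)]
    pops = sorted(config.population_frequencies)
    pop_p = np.array([config.population_frequencies[p] for p in pops])
    population = rng.choice(pops, size=n, p=pop_p)
    genders = sorted(config.gender_frequencies)
    gen_p = np.array([config.gender_frequencies[g] for g in genders])
    gender = rng.choice(genders, size=n, p=gen_p)

    u = rng.normal(0.0, config.sigma_line, size=n)
    confounder = rng.normal(0.0, 1.0, size=n)

    # --- conditions --------------------------------------------------------
    cond_ids = [f"C{j:02d}" for j in range(J)]
    v = rng.normal(0.0, config.sigma_cond, size=J)

    # --- genotypes ---------------------------------------------------------
    snp_ids = [f"S{s:05d}" for s in range(config.n_snps)]
    maf = rng.uniform(*config.maf_range, size=config.n_snps)
    if config.confounder_geno_loading:
        per_line_af = np.clip(
            maf[:, None] * (1.0 + config.confounder_geno_loading * confounder[None, :]),
            0.01, 0.99,
        )
    else:
        per_line_af = np.broadcast_to(maf[:, None], (config.n_snps, n))
    dosages = rng.binomial(2, per_line_af).astype(float)

    # --- gene effects ------------------------------------------------------
    gene_ids = [f"G{g:05d}" for g in range(config.n_genes)]
    n_growth = int(round(config.frac_growth_genes * config.n_genes))
    growth_idx = rng.choice(config.n_genes, size=n_growth, replace=False)
    is_growth = np.zeros(config.n_genes, dtype=bool)
    is_growth[growth_idx] = True
    gene_effect = np.zeros(config.n_genes)
    gene_effect[growth_idx] = rng.normal(
        config.growth_effect_mean, config.growth_effect_sd, size=n_growth
    )

    # --- eQTL assignment ---------------------------------------------------
    eqtl_snp_idx = rng.choice(config.n_snps, size=config.n_eqtls, replace=False)
    n_to_growth = int(round(config.frac_eqtls_targeting_growth_genes * config.n_eqtls))
    n_to_growth = min(n_to_growth, n_growth)
    growth_pool = growth_idx
    other_pool = np.flatnonzero(~is_growth)
    tg = rng.choice(growth_pool, size=n_to_growth, replace=False) if n_to_growth else \
        np.empty(0, dtype=int)
    n_other = config.n_eqtls - n_to_growth
    to = rng.choice(other_pool, size=min(n_other, len(other_pool)), replace=False) \
        if n_other and len(other_pool) else np.empty(0, dtype=int)
    target_idx = np.concatenate([tg, to]).astype(int)
    eqtl_snp_idx = eqtl_snp_idx[: len(target_idx)]
    eqtl_df = pd.DataFrame({
        "snp_id": [snp_ids[s] for s in eqtl_snp_idx],
        "gene_id": [gene_ids[g] for g in target_idx],
        "effect": config.eqtl_effect,
        "targets_growth_gene": is_growth[target_idx],
    })

    # --- true intrinsic phenotype ------------------------------------------
    fixed = config.grand_mean * (
        1.0
        + np.array([config.population_effects.get(p, 0.0) for p in population])
        + np.where(gender == "female", config.gender_effect, 0.0)
    )
    snp_pos = {s: i for i, s in enumerate(snp_ids)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    genetic = np.zeros(n)
    if config.snp_growth_effect:
        causal = eqtl_df.index[eqtl_df["targets_growth_gene"]]
        for row in eqtl_df.loc[causal].itertuples():
            s = snp_pos[row.snp_id]
            genetic += config.snp_growth_effect * (dosages[s] - 2.0 * maf[s])
    pheno_conf = config.confounder_pheno_effect * confounder
    true_intrinsic = fixed + u + genetic + pheno_conf

    # --- phenotype records -------------------------------------------------
    include = rng.random((n, J)) < config.condition_coverage
    empty_rows = np.flatnonzero(~include.any(axis=1))
    for i in empty_rows:  # every line keeps at least one observation
        include[i, rng.integers(J)] = True
    pairs = np.argwhere(include)  # row-major (line, condition) order
    n_obs = len(pairs) * config.replicates
    eps = rng.normal(0.0, config.sigma_resid, size=n_obs)
    rows = []
    pos = 0
    for i, j in pairs:
        for k in range(config.replicates):
            rows.append((
                line_ids[i], population[i], gender[i], cond_ids[j], f"r{k + 1}",
                true_intrinsic[i] + v[j] + eps[pos],
            ))
            pos += 1
    pheno = PhenotypeTable(pd.DataFrame(
        rows, columns=["line_id", "population", "gender", "condition_id",
                       "replicate_id", "value"],
    ))

    # --- expression --------------------------------------------------------
    z = (true_intrinsic - true_intrinsic.mean()) / max(true_intrinsic.std(), 1e-12)
    base = rng.normal(config.expr_base_mean, config.expr_base_sd, size=config.n_genes)
    K = config.n_latent_factors
    factors = rng.normal(0.0, 1.0, size=(n, K)) if K else np.empty((n, 0))
    if K and config.latent_pheno_loading:
        lam = config.latent_pheno_loading
        factors[:, 0] = lam * z + np.sqrt(max(1.0 - lam**2, 0.0)) * factors[:, 0]
    loadings = rng.normal(0.0, config.latent_loading_sd, size=(config.n_genes, K)) \
        if K else np.empty((config.n_genes, 0))
    conf_loadings = rng.normal(0.0, config.confounder_expr_loading_sd,
                               size=config.n_genes) if config.confounder_expr_loading_sd \
        else np.zeros(config.n_genes)
    noise = rng.normal(0.0, config.expr_noise_sd, size=(config.n_genes, n))

    E = base[:, None] + np.outer(gene_effect, z) + loadings @ factors.T \
        + np.outer(conf_loadings, confounder) + noise
    for row in eqtl_df.itertuples():
        s, g = snp_pos[row.snp_id], gene_pos[row.gene_id]
        E[g] += config.eqtl_effect * (dosages[s] - dosages[s].mean())

    expr = ExpressionMatrix(pd.DataFrame(E, index=gene_ids, columns=line_ids))
    geno = GenotypeMatrix(pd.DataFrame(dosages, index=snp_ids, columns=line_ids))
    eqtl_map = EqtlMap({
        snp: frozenset(sub["gene_id"])
        for snp, sub in eqtl_df.groupby("snp_id", sort=False)
    }) if len(eqtl_df) else EqtlMap({})

    truth = SimTruth(
        lines=pd.DataFrame({
            "population": population, "gender": gender, "u": u,
            "genetic": genetic, "confounder": confounder,
            "true_intrinsic": true_intrinsic,
        }, index=pd.Index(line_ids, name="line_id")),
        condition_effects=pd.Series(v, index=pd.Index(cond_ids, name="condition_id"),
                                    name="effect"),
        genes=pd.DataFrame({"is_growth": is_growth, "effect": gene_effect},
                           index=pd.Index(gene_ids, name="gene_id")),
        snps=pd.Series(maf, index=pd.Index(snp_ids, name="snp_id"), name="maf"),
        factor_scores=pd.DataFrame(
            factors, index=pd.Index(line_ids, name="line_id"),
            columns=[f"factor{k + 1}" for k in range(K)],
        ),
        eqtls=eqtl_df,
        config=config,
    )
    return SimData(phenotypes=pheno, expression=expr, genotypes=geno,
                   eqtl=eqtl_map, truth=truth)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def scenario(name: str, seed: int = 0) -> SimConfig:
    """Named presets: null, planted_growth, confounded, paper_like."""
    presets = {
        "paper_like": SimConfig(seed=seed),
        "null": SimConfig(
            n_lines=180, n_conditions=6, condition_coverage=0.8,
            gender_effect=0.0,
            population_effects={"ASN": 0.0, "ASW": 0.0, "CEU": 0.0, "YRI": 0.0},
            n_genes=2000, frac_growth_genes=0.0,
            n_latent_factors=3,
            n_snps=500, n_eqtls=250, eqtl_effect=0.8,
            frac_eqtls_targeting_growth_genes=0.0,
            snp_growth_effect=0.0, seed=seed,
        ),
        "planted_growth": SimConfig(
            n_lines=200, n_conditions=6, condition_coverage=0.8,
            n_genes=2000, frac_growth_genes=0.3,
            growth_effect_mean=0.3, growth_effect_sd=0.25,
            n_latent_factors=5, sigma_resid=30_000.0,
            n_snps=300, n_eqtls=30, eqtl_effect=0.9,
            frac_eqtls_targeting_growth_genes=0.2,
            snp_growth_effect=12_000.0, seed=seed,
        ),
        "confounded": SimConfig(
            n_lines=200, n_conditions=6, condition_coverage=0.8,
            n_genes=1000, frac_growth_genes=0.0,
            n_latent_factors=3, latent_loading_sd=0.3,
            expr_noise_sd=0.5,
            n_snps=300, n_eqtls=300, eqtl_effect=2.0,
            frac_eqtls_targeting_growth_genes=0.0,
            snp_growth_effect=0.0,
            confounder_pheno_effect=0.0,
            confounder_geno_loading=0.3,
            confounder_expr_loading_sd=0.4,
            seed=seed,
        ),
    }
    if name not in presets:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(presets)}"
        )
    return presets[name]


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_all(sim: SimData, outdir: str | Path) -> dict[str, Path]:
    """Write every generated table plus the ground truth to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.tsv",
        "expression": outdir / "expression.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "eqtl": outdir / "eqtl_map.tsv",
        "truth_lines": outdir / "truth_lines.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_config": outdir / "truth_config.json",
    }
    write_phenotypes(sim.phenotypes, paths["phenotypes"])
    write_expression(sim.expression, paths["expression"])
    write_genotypes(sim.genotypes, paths["genotypes"])
    write_eqtl_map(sim.eqtl, paths["eqtl"])
    sim.truth.lines.to_csv(paths["truth_lines"], sep="\t")
    sim.truth.genes.to_csv(paths["truth_genes"], sep="\t")
    cfg = asdict(sim.truth.config)
    cfg["maf_range"] = list(cfg["maf_range"])
    paths["truth_config"].write_text(json.dumps(cfg, indent=2))
    return paths
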