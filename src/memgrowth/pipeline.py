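"""End-to-end pipeline: phenotype pooling -> intrinsic value -> association
and enrichment, with a checksummed artifact manifest.

The single top-level seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so each stochastic stage is
independently reproducible; the derived seeds are recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as ex
from . import gwas, io, mem
from .errors import ConfigurationError, MemgrowthError

log = logging.getLogger(__name__)

_STAGES = ("fit", "lrt", "expression", "sva", "scan", "enrichment", "signature")


@dataclass
class PipelineConfig:
    phenotype_path: str
    expression_path: str
    genotype_path: str
    eqtl_path: str
    out_dir: str
    genotype_format: str = "tsv"
    signature_path: str | None = None
    p_thresh: float = 1e-4
    fdr_thresh: float = 0.05
    maf_min: float = 0.05
    n_perm: int = 1000
    run_sva: bool = True
    seed: int = 0
    mem_spec: mem.MemSpec = field(default_factory=mem.MemSpec)

    def validate(self) -> None:
        for name in ("phenotype_path", "expression_path", "genotype_path", "eqtl_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} does not exist: {p}")
        if self.signature_path is not None and not Path(self.signature_path).exists():
            raise ConfigurationError(f"signature_path does not exist: {self.signature_path}")
        if not 0 < self.p_thresh < 1:
            raise ConfigurationError(f"p_thresh must lie in (0, 1); got {self.p_thresh}")
        if not 0 < self.fdr_thresh < 1:
            raise ConfigurationError(f"fdr_thresh must lie in (0, 1); got {self.fdr_thresh}")
        if not 0 <= self.maf_min < 0.5:
            raise ConfigurationError(f"maf_min must lie in [0, 0.5); got {self.maf_min}")
        if self.n_perm < 0:
            raise ConfigurationError("n_perm must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        spec = data.pop("mem_spec", None)
        cfg = cls(**data)
        if spec:
            cfg.mem_spec = mem.MemSpec(
                fixed_effects=tuple(spec.get("fixed_effects", ("gender", "population"))),
                random_effects=tuple(spec.get("random_effects", ("line_id", "condition_id"))),
                reml=bool(spec.get("reml", True)),
            )
        return cfg


def _stage_seeds(seed: int, n: int = len(_STAGES)) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the artifact manifest (also written to disk).

    Any stage failure aborts with a stage-named error; partial outputs are
    retained next to a FAILED marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log.info("stage seeds: %s", seeds)
    files: dict[str, Path] = {}
    stage = "load"
    try:
        table = io.read_phenotypes(config.phenotype_path)
        expr = io.read_expression(config.expression_path)
        geno = io.read_genotypes(config.genotype_path, format=config.genotype_format)
        eqtl = io.read_eqtl_map(config.eqtl_path)

        stage = "fit"
        fit = mem.fit_mem(table, config.mem_spec)
        igrowth = mem.intrinsic_phenotype(fit, table)
        files["igrowth"] = out / "igrowth.tsv"
        files["fit"] = out / "fit.json"
        mem.write_intrinsic(igrowth, fit, table, files["igrowth"], files["fit"])

        stage = "lrt"
        lrt = {
            effect: mem.lrt_fixed_effect(table, config.mem_spec, effect)
            for effect in config.mem_spec.fixed_effects
            if table.data[effect].nunique() > 1
        }
        files["lrt"] = out / "lrt_fixed_effects.json"
        files["lrt"].write_text(json.dumps(lrt, indent=2))

        stage = "expression"
        covariates = table.line_covariates()
        unadj = ex.associate(expr, igrowth, covariates)

        stage = "sva"
        adj = None
        if config.run_sva:
            sv = ex.estimate_sv(expr, igrowth, covariates, seed=seeds["sva"])
            adj = ex.associate(expr, igrowth, covariates, sv=sv)
        files["association"] = out / "expression_association.tsv"
        ex.write_association(unadj, adj, files["association"])

        null_p = ex.permutation_null(expr, igrowth, covariates,
                                     n_perm=min(config.n_perm, 200),
                                     seed=seeds["expression"])
        files["permutation_null"] = out / "permutation_null.tsv"
        null_p.to_csv(files["permutation_null"], sep="\t", index=False)

        stage = "scan"
        results = gwas.scan(geno, igrowth, covariates, maf_min=config.maf_min)
        files["scan"] = out / "gwas_scan.tsv"
        gwas.write_scan(results, files["scan"])

        stage = "enrichment"
        universe = io.GeneSet.from_iterable("universe", expr.gene_ids)
        growth_genes = io.GeneSet.from_iterable(
            "growth_genes", unadj.index[unadj["q"] < config.fdr_thresh]
        )
        targets = eqtl.targets_of(gwas.top_snps(results, config.p_thresh)) \
            & universe.gene_ids
        target_set = io.GeneSet.from_iterable("targets", targets)
        m1 = enr.fisher_overlap(universe, target_set, growth_genes)
        m2 = enr.enrich_method2(geno, igrowth, covariates, eqtl, growth_genes,
                                universe, config.p_thresh, n_perm=config.n_perm,
                                maf_min=config.maf_min, seed=seeds["enrichment"])
        m3 = enr.enrich_method3(geno, expr, igrowth, covariates, eqtl, universe,
                                config.p_thresh, config.fdr_thresh,
                                n_perm=config.n_perm, maf_min=config.maf_min,
                                seed=seeds["enrichment"])
        files["enrichment_m2"] = out / "enrichment_method2.json"
        files["enrichment_m3"] = out / "enrichment_method3.json"
        m2.to_json(files["enrichment_m2"])
        m3.to_json(files["enrichment_m3"])
        files["enrichment_m2_trace"] = out / "enrichment_method2_trace.tsv"
        files["enrichment_m3_trace"] = out / "enrichment_method3_trace.tsv"
        m2.write_trace(files["enrichment_m2_trace"])
        m3.write_trace(files["enrichment_m3_trace"])
        enrichment_summary = {
            "fisher": {"p": m1["p"], "table": vars(m1["table"])},
            "method2_empirical_p": m2.empirical_p,
            "method3_empirical_p": m3.empirical_p,
        }
        files["enrichment"] = out / "enrichment_summary.json"
        files["enrichment"].write_text(
            json.dumps(enrichment_summary, indent=2, default=float))

        if config.signature_path is not None:
            stage = "signature"
            signature = io.read_gene_set(config.signature_path)
            sig = enr.signature_overlap(universe, growth_genes, signature,
                                        seed=seeds["signature"])
            files["signature"] = out / "signature_overlap.json"
            files["signature"].write_text(json.dumps(
                {k: v for k, v in sig.items() if k != "null_counts"}, indent=2))
            files["signature_null"] = out / "signature_null_counts.tsv"
            pd.DataFrame({"count": sig["null_counts"]}).to_csv(
                files["signature_null"], sep="\t", index=False)
    except MemgrowthError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        log.error("pipeline failed at stage %r", stage)
        raise

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "params": {
            "p_thresh": config.p_thresh, "fdr_thresh": config.fdr_thresh,
            "maf_min": config.maf_min, "n_perm": config.n_perm,
            "run_sva": config.run_sva,
        },
        "files": {
            name: {"path": str(p), "md5": _md5(p)} for name, p in files.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
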