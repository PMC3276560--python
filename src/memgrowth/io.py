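"""Domain containers and readers/writers for phenotype, expression, genotype,
eQTL-map, and gene-list files.

All tabular formats are plain TSV with a header row.  Genotypes may also be
supplied as VCF 4.x, in which case the additive dosage is the count of
alternate alleles in the GT field (missing GT -> missing dosage).  Sample
matching across files is by exact ``line_id`` string; unmatched samples are
dropped by downstream operations, never imputed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

log = logging.getLogger(__name__)

#: default column-name mapping for long-format phenotype files
DEFAULT_DIALECT: dict[str, str] = {
    "line_id": "line_id",
    "population": "population",
    "gender": "gender",
    "condition_id": "condition",
    "replicate_id": "replicate",
    "value": "value",
}

PHENOTYPE_COLUMNS = ("line_id", "population", "gender", "condition_id", "replicate_id", "value")


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeRecord:
    """One replicated growth measurement of one cell line in one experiment."""

    line_id: str
    population: str
    gender: str
    condition_id: str
    replicate_id: str
    value: float


@dataclass
class PhenotypeTable:
    """Long-format replicated phenotype measurements.

    Invariants (enforced by :meth:`validate`): values finite;
    (line, condition, replicate) triples unique; every line carries exactly
    one population and one gender label across all of its records.
    """

    data: pd.DataFrame  # columns: PHENOTYPE_COLUMNS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"phenotype table missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("phenotype table is empty")
        if df["line_id"].nunique() < 2:
            raise ValidationError("phenotype table needs at least 2 distinct lines")
        bad = ~np.isfinite(df["value"].to_numpy(dtype=float))
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            raise ValidationError(f"non-finite phenotype values at rows {rows}")
        dup = df.duplicated(subset=["line_id", "condition_id", "replicate_id"])
        if dup.any():
            rows = df.index[dup].tolist()[:10]
            raise ValidationError(
                f"duplicate (line, condition, replicate) triples at rows {rows}"
            )
        for col in ("population", "gender"):
            per_line = df.groupby("line_id", sort=False)[col].nunique()
            incons = per_line[per_line > 1].index.tolist()
            if incons:
                raise ValidationError(
                    f"inconsistent {col} labels for line(s): {incons[:10]}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def line_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["line_id"]))

    @property
    def condition_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition_id"]))

    def line_covariates(self) -> pd.DataFrame:
        """Per-line population/gender table, indexed by line_id."""
        return (
            self.data.groupby("line_id", sort=False)[["population", "gender"]]
            .first()
        )

    def per_condition_means(self) -> dict[str, pd.Series]:
        """Per-condition raw phenotype: mean value per line within each condition."""
        out = {}
        for cond, sub in self.data.groupby("condition_id", sort=False):
            out[cond] = sub.groupby("line_id")["value"].mean()
        return out

    def records(self) -> Iterable[PhenotypeRecord]:
        for row in self.data.itertuples(index=False):
            yield PhenotypeRecord(
                row.line_id, row.population, row.gender,
                row.condition_id, row.replicate_id, float(row.value),
            )

    def __len__(self) -> int:
        return len(self.data)


def read_phenotypes(path: str | Path, dialect: Mapping[str, str] | None = None) -> PhenotypeTable:
    """Read a long-format phenotype TSV/CSV.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`)
    to the column names actually present in the file.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in dialect.values() if v not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) {missing} not found; available: {list(df.columns)}"
        )
    out = pd.DataFrame({canon: df[src] for canon, src in dialect.items()})
    try:
        out["value"] = out["value"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric phenotype value ({exc})") from exc
    out = out.reset_index(drop=True)
    return PhenotypeTable(out)


def write_phenotypes(table: PhenotypeTable, path: str | Path,
                     dialect: Mapping[str, str] | None = None) -> None:
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = table.data.rename(columns=dialect)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of (log-scale) expression values."""

    values: pd.DataFrame  # index: gene_ids, columns: sample_ids

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.values
        df.index.name = "gene_id"
        df.columns.name = None
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()[:10]
            raise ValidationError(f"duplicate gene ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()[:10]
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression(path: str | Path, log2_transform: bool = False) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene id, header = sample ids).

    With ``log2_transform`` the raw values are log2-transformed; non-positive
    entries are rejected because the logarithm is undefined there.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression cell ({exc})") from exc
    if log2_transform:
        if (arr <= 0).any():
            i, j = np.argwhere(arr <= 0)[0]
            raise ValidationError(
                f"{path}: non-positive value at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}; log2 transform undefined"
            )
        df = pd.DataFrame(np.log2(arr), index=df.index, columns=df.columns)
    else:
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """SNP x sample additive dosage matrix; entries in [0, 2] or NaN (missing)."""

    dosages: pd.DataFrame  # index: snp_ids, columns: sample_ids

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.dosages
        df.index.name = "snp_id"
        df.columns.name = None
        if df.index.duplicated().any():
            raise ValidationError("duplicate SNP ids")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        arr = df.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 2)
        if np.nansum(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage outside [0, 2] at SNP {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def missing_fraction(self) -> pd.Series:
        """Per-SNP fraction of missing dosages."""
        return self.dosages.isna().mean(axis=1)


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from a TSV dosage matrix or a VCF.

    VCF: dosage = alternate-allele count from GT; ``./.`` -> missing;
    multi-allelic sites are dropped (a count is logged).
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ConfigurationError(f"unknown genotype format {format!r} (expected tsv or vcf)")


def _read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric dosage ({exc})") from exc
    return GenotypeMatrix(df)


def _read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError("cyvcf2 is required to read VCF genotypes") from exc
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF ({exc})") from exc
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) > 1:
            n_multiallelic += 1
            continue
        dos = np.empty(len(samples))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) < 2:
                dos[i] = np.nan
            else:
                dos[i] = float(sum(1 for a in alleles if a == 1))
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        rows.append(dos)
    if n_multiallelic:
        log.info("dropped %d multi-allelic VCF site(s)", n_multiallelic)
    df = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(samples))),
                      index=snp_ids, columns=samples)
    return GenotypeMatrix(df)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as TSV (missing encoded as NA)."""
    geno.dosages.to_csv(path, sep="\t", index_label="snp_id", na_rep="NA")


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal synthetic VCF (GT-only, one biallelic SNP per row).

    Intended for generated cohorts and fixtures; dosage 0/1/2 becomes GT
    0/0, 0/1, 1/1 and missing becomes ``./.``.
    """
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for pos, (snp, row) in enumerate(geno.dosages.iterrows(), start=1):
            calls = []
            for v in row.to_numpy(dtype=float):
                calls.append("./." if np.isnan(v) else gt_code[int(round(v))])
            fh.write(f"1\t{pos}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# eQTL map and gene sets
# ---------------------------------------------------------------------------

@dataclass
class EqtlMap:
    """Mapping snp_id -> set of target gene ids."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        empty = [s for s, g in self.targets.items() if not g]
        if empty:
            raise ValidationError(f"eQTL map has SNP(s) with empty target sets: {empty[:10]}")

    def targets_of(self, snp_ids: Iterable[str]) -> set[str]:
        """Union of target genes over the given SNPs (unknown SNPs contribute nothing)."""
        out: set[str] = set()
        for s in snp_ids:
            out |= self.targets.get(s, frozenset())
        return out

    def __len__(self) -> int:
        return len(self.targets)


def read_eqtl_map(path: str | Path) -> EqtlMap:
    """Read a two-column TSV (snp_id, gene_id; one row per pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "gene_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: eQTL map missing column(s) {missing}")
    mapping = {
        snp: frozenset(sub["gene_id"])
        for snp, sub in df.groupby("snp_id", sort=False)
    }
    return EqtlMap(mapping)


def write_eqtl_map(eqtl: EqtlMap, path: str | Path) -> None:
    rows = [(s, g) for s in eqtl.targets for g in sorted(eqtl.targets[s])]
    pd.DataFrame(rows, columns=["snp_id", "gene_id"]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers."""

    name: str
    gene_ids: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneSet":
        genes = list(genes)
        if len(genes) != len(set(genes)):
            raise ValidationError(f"gene set {name!r} contains duplicates")
        return cls(name, frozenset(genes))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list, one gene per line; blank lines ignored."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(genes) != len(set(genes)):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ValidationError(f"{path}: duplicate gene(s) in list: {dups[:10]}")
    return GeneSet(name or path.stem, frozenset(genes))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.gene_ids)) + "\n")
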