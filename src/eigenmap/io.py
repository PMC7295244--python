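"""Readers and writers for the external formats the pipeline touches.

Expression, covariate and module-assignment tables are plain TSV; genotypes
are VCF v4.2 (read through cyvcf2); gene sets are GMT; the phenotype-locus
network is GraphML. All tabular data is held in pandas containers; genotypes
in a small dataclass around a dense dosage matrix.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

DIAGNOSES = ("CASE", "CONTROL", "OTHER")


class FormatError(ValueError):
    """Malformed or invariant-violating input file."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages, samples x variants.

    ``dosages`` holds alt-allele counts in [0, 2]; missing calls have been
    mean-imputed per variant (EMMAX convention), with ``variants['imputed']``
    flagging variants that required imputation.
    """

    dosages: np.ndarray  # (n_samples, n_variants), float
    variants: pd.DataFrame  # columns: chrom, pos, ref, alt, id, imputed
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise FormatError("dosage matrix shape does not match ids")


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and the random seed.

    Defaults follow the published analysis: soft-threshold power 6, minimum
    eigengene connectivity 0.6, minimum submodule size 100 (overridable at
    desk scale), suggestive/significant GWAS cutoffs 1e-5 / 5e-8, replication
    p 0.05, DE thresholds FDR 0.05 and |logFC| 0.5, MAF floor 0.05, 1 Mb
    positional clump window.
    """

    soft_power: float = 6.0
    kme_min: float = 0.6
    min_module_size: int = 100
    k_min: int = 2
    k_max: int = 6
    suggestive_p: float = 1e-5
    significant_p: float = 5e-8
    replication_p: float = 0.05
    de_fdr: float = 0.05
    de_lfc: float = 0.5
    maf_min: float = 0.05
    missing_cap: float = 0.1
    clump_window_bp: int = 1_000_000
    network_signed: bool = False
    kinship_method: str = "ibs"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("suggestive_p", "significant_p", "replication_p", "de_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.kme_min < 1:
            raise ValueError("kme_min must be in (0,1)")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# expression / covariates / module assignment (TSV)
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV into a float DataFrame (genes as index).

    Raises :class:`FormatError` on duplicate gene or sample ids, and a parse
    error naming the offending cell on non-numeric values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise FormatError(f"duplicate gene ids: {dup_genes}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise FormatError(f"duplicate sample ids: {dup_samples}")
    try:
        values = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric value {v!r} at gene {df.index[i]!r} "
                        f"(row {i + 1}), sample {col!r} (column {j + 1})"
                    ) from None
        raise
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)].tolist()
        raise FormatError(f"missing values in genes: {bad}")
    values.index.name = "gene_id"
    return values


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the per-sample covariate/diagnosis table, indexed by sample_id."""
    cov = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in cov.columns:
        raise FormatError("covariate table must have a sample_id column")
    if cov["sample_id"].duplicated().any():
        dups = cov.loc[cov["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in covariates: {dups}")
    cov = cov.set_index("sample_id")
    if "diagnosis" in cov.columns:
        bad = set(cov["diagnosis"].unique()) - set(DIAGNOSES)
        if bad:
            raise FormatError(f"unknown diagnosis codes: {sorted(bad)}")
    return cov


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample_id")


def read_module_assignment(path: str | Path) -> pd.Series:
    """Read gene -> coarse module label mapping (two-column TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("module table needs gene_id and module columns")
    genes, modules = df.iloc[:, 0], df.iloc[:, 1]
    if genes.duplicated().any():
        raise FormatError(
            f"genes assigned to multiple modules: {genes[genes.duplicated()].tolist()}"
        )
    if (modules.isna() | (modules.str.len() == 0)).any():
        raise FormatError("empty module labels")
    return pd.Series(modules.values, index=genes.values, name="module")


def write_module_assignment(modules: pd.Series, path: str | Path) -> None:
    modules.rename_axis("gene_id").rename("module").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path, maf_min: float = 0.05, missing_cap: float = 0.1
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF v4.2 into a dosage matrix.

    Multi-allelic records are skipped (count logged). Variants failing the
    MAF floor (computed on non-missing calls) or the per-variant missing
    fraction cap are dropped. Remaining missing calls are mean-imputed per
    variant and the variant flagged ``imputed``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError("VCF contains no samples")
    rows, meta = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        miss = np.isnan(dos)
        miss_frac = miss.mean()
        if miss_frac > missing_cap or miss.all():
            continue
        p = np.nanmean(dos) / 2.0
        maf = min(p, 1.0 - p)
        if maf < maf_min:
            continue
        imputed = bool(miss.any())
        if imputed:
            dos[miss] = np.nanmean(dos)
        rows.append(dos)
        vid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0], vid, imputed))
    if n_multi:
        log.info("skipped %d multi-allelic records", n_multi)
    if not rows:
        raise FormatError("no variants survived MAF/missingness filters")
    variants = pd.DataFrame(
        meta, columns=["chrom", "pos", "ref", "alt", "id", "imputed"]
    )
    return GenotypeMatrix(
        dosages=np.asarray(rows).T, variants=variants, sample_ids=samples
    )


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call dosages as a minimal VCF v4.2 with GT fields.

    Non-integral (imputed) dosages cannot be represented as genotype calls
    and raise; write before imputation or keep calls integral.
    """
    dos = geno.dosages
    if not np.all(np.isnan(dos) | (dos == np.round(dos))):
        raise ValueError("non-integral dosages cannot be written as GT calls")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        for j, row in geno.variants.iterrows():
            calls = [
                "./." if np.isnan(d) else gt_map[int(d)] for d in dos[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# phenotype -> locus network (GraphML)
# ---------------------------------------------------------------------------

PHENOTYPE_CLASSES = ("diagnostic", "module", "submodule", "subtype")
# edge colour scheme of the published figure
ASSOCIATION_COLORS = {
    "diagnostic": "red",
    "subtype": "blue",
    "module": "yellow",
    "submodule": "green",
}


def write_network(network: nx.DiGraph, path: str | Path) -> None:
    """Write the directed phenotype->locus graph as GraphML.

    Every node must carry ``role`` (phenotype|locus) and phenotype nodes a
    ``phenotype_class``; edges carry ``association_class``.
    """
    for u, v in network.edges():
        for node in (u, v):
            if node not in network.nodes:
                raise FormatError(f"edge references unknown node {node!r}")
        if network.nodes[u].get("role") != "phenotype":
            raise FormatError(f"edge source {u!r} is not a phenotype node")
        if network.nodes[v].get("role") != "locus":
            raise FormatError(f"edge target {v!r} is not a locus node")
    nx.write_graphml(network, str(path))


def read_network(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(str(path))
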