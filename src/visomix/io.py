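"""Readers and writers for the interchange formats.

Canonical on-disk forms: TSV/CSV matrices (first column = sample id, header
row = feature ids), CSV annotation tables (1-based positions; BED-like
0-based half-open tables are converted on read), GMT pathway membership, a
two-column child/parent TSV for the hierarchy, and JSON for manifests and
metrics. The method assumes complete data, so missing values are an error,
never imputed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .annot_masks import AnnotationSet, CpGSite, GeneRegion, PathwayHierarchy
from .dataset import OmicsDataset
from .synthdata import GroundTruth

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_cpg_table",
    "read_gene_table",
    "read_gmt",
    "write_gmt",
    "read_hierarchy",
    "write_hierarchy",
    "read_phenotype_table",
    "align_samples",
    "write_fixture",
    "read_fixture",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_matrix(path, orientation: str = "samples_by_features") -> pd.DataFrame:
    """Numeric matrix with sample index and feature columns.

    ``orientation='features_by_samples'`` transposes on read. Duplicate ids
    or missing values abort with a message naming the offenders.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(path))[1:]
    dup_cols = {h for h in header if header.count(h) > 1}
    if dup_cols:
        raise ValueError(f"duplicate column ids in {path}: {sorted(dup_cols)[:5]}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation == "features_by_samples":
        df = df.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    for axis, ids in (("sample", df.index), ("feature", df.columns)):
        dup = ids[ids.duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate {axis} ids in {path}: {dup[:5]}")
    df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        rows, cols = np.where(df.isna())
        cells = [(str(df.index[r]), str(df.columns[c])) for r, c in zip(rows[:5], cols[:5])]
        raise ValueError(f"missing values in {path} at (sample, feature): {cells}")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path), index_label="sample_id", float_format="%.10g")


def read_cpg_table(path) -> list[CpGSite]:
    """CpG positions from a CSV/TSV with columns cpg_id, chrom, pos (1-based)."""
    df = pd.read_csv(path, sep=_sep(path))
    required = {"cpg_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"CpG table needs columns {sorted(required)}, got {list(df.columns)}")
    sites = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            sites.append(CpGSite(str(row.cpg_id), str(row.chrom), int(row.pos)))
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path} row {i + 2}: {e}") from None
    return sites


def read_gene_table(path, bed_like: bool = False) -> list[GeneRegion]:
    """Gene regions from CSV/TSV with gene_id, chrom, tss, strand.

    With ``bed_like=True`` the table is read as 0-based half-open
    (gene_id, chrom, start, strand) and converted to 1-based TSS on read.
    """
    df = pd.read_csv(path, sep=_sep(path))
    pos_col = "start" if bed_like else "tss"
    required = {"gene_id", "chrom", pos_col}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}, got {list(df.columns)}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            tss = int(getattr(row, pos_col)) + (1 if bed_like else 0)
            strand = str(getattr(row, "strand", "+"))
            genes.append(GeneRegion(str(row.gene_id), str(row.chrom), tss, strand))
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path} row {i + 2}: {e}") from None
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def read_gmt(path) -> dict[str, set[str]]:
    """Pathway membership from GMT: name <tab> description <tab> genes...

    Lines with an empty gene list are dropped with a warning. Returns
    gene_id -> set of pathway names (the orientation the mask builder uses).
    """
    membership: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                warnings.warn(f"{path} line {lineno}: pathway with no genes dropped",
                              stacklevel=2)
                continue
            name = parts[0]
            for g in parts[2:]:
                if g.strip():
                    membership.setdefault(g.strip(), set()).add(name)
    return membership


def write_gmt(membership: dict[str, set[str]], path, description: str = "na") -> None:
    by_pathway: dict[str, list[str]] = {}
    for g, ps in membership.items():
        for p in ps:
            by_pathway.setdefault(p, []).append(g)
    with open(path, "w") as fh:
        for p in sorted(by_pathway):
            genes = "\t".join(sorted(by_pathway[p]))
            fh.write(f"{p}\t{description}\t{genes}\n")


def read_hierarchy(gmt_path, parent_path) -> PathwayHierarchy:
    """Hierarchy = GMT membership + two-column (child, parent) TSV."""
    membership = read_gmt(gmt_path)
    parent_df = pd.read_csv(parent_path, sep="\t", header=None, names=["child", "parent"])
    parent = {str(r.child): str(r.parent) for r in parent_df.itertuples(index=False)}
    return PathwayHierarchy(membership=membership, parent=parent)


def write_hierarchy(h: PathwayHierarchy, gmt_path, parent_path) -> None:
    write_gmt(h.membership, gmt_path)
    with open(parent_path, "w") as fh:
        for child in sorted(h.parent):
            fh.write(f"{child}\t{h.parent[child]}\n")


def read_phenotype_table(path, phenotype: str, cohort_col: str = "cohort",
                         covariate_cols: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    needed = [phenotype, cohort_col, *(covariate_cols or [])]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table {path} lacks columns {missing}")
    if df[needed].isna().any().any():
        raise ValueError(f"phenotype table {path} has missing values in {needed}")
    return df


def align_samples(
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
    phenotype: str,
    cohort_col: str = "cohort",
    covariate_cols: list[str] | None = None,
) -> OmicsDataset:
    """Inner-join the omics matrices and phenotype table on sample id.

    Only samples present in all three sources are kept (complete multi-omics
    cases); per-source drop counts are recorded in ``dataset`` attrs-style
    metadata via a log message, and a fully disjoint overlap is an error.
    """
    shared = methylation.index.intersection(expression.index).intersection(phenotypes.index)
    if len(shared) == 0:
        raise ValueError("no sample ids shared between methylation, expression and phenotypes")
    dropped = {
        "methylation": int(len(methylation.index.difference(shared))),
        "expression": int(len(expression.index.difference(shared))),
        "phenotypes": int(len(phenotypes.index.difference(shared))),
    }
    ds = OmicsDataset(
        methylation=methylation.loc[shared],
        expression=expression.loc[shared],
        phenotype=phenotypes.loc[shared, phenotype].astype(float),
        cohort=phenotypes.loc[shared, cohort_col].astype(str),
        covariates=phenotypes.loc[shared, covariate_cols or []].astype(float),
    )
    ds.dropped_counts = dropped  # type: ignore[attr-defined]
    return ds


# ---------------------------------------------------------------------------
# fixture bundles (the exact files the readers consume)

_FILES = {
    "methylation": "methylation.tsv",
    "expression": "expression.tsv",
    "phenotype": "phenotype.csv",
    "cpgs": "cpgs.csv",
    "genes": "genes.csv",
    "truth": "ground_truth.json",
}


def write_fixture(outdir, dataset: OmicsDataset, annot: AnnotationSet,
                  truth: GroundTruth | None = None) -> dict[str, str]:
    """Emit a simulated dataset as the on-disk formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.methylation, outdir / _FILES["methylation"])
    write_matrix(dataset.expression, outdir / _FILES["expression"])
    pheno = pd.DataFrame(
        {"phenotype": dataset.phenotype, "cohort": dataset.cohort}
    ).join(dataset.covariates)
    pheno.to_csv(outdir / _FILES["phenotype"], index_label="sample_id")
    pd.DataFrame(
        [(c.cpg_id, c.chrom, c.position) for c in annot.cpgs],
        columns=["cpg_id", "chrom", "pos"],
    ).to_csv(outdir / _FILES["cpgs"], index=False)
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in annot.genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(outdir / _FILES["genes"], index=False)
    if truth is not None:
        manifest = {
            "causal_genes": {g: list(c) for g, c in truth.causal_genes.items()},
            "sex_genes": truth.sex_genes,
            "cpg_gene_map": truth.cpg_gene_map,
            "formula": truth.formula,
            "extras": truth.extras,
        }
        (outdir / _FILES["truth"]).write_text(json.dumps(manifest, indent=1))
    return {k: str(outdir / v) for k, v in _FILES.items()}


def read_fixture(indir, covariate_cols: list[str] = ("sex",)) -> tuple[OmicsDataset, AnnotationSet]:
    indir = Path(indir)
    me = read_matrix(indir / _FILES["methylation"])
    ge = read_matrix(indir / _FILES["expression"])
    pheno = read_phenotype_table(
        indir / _FILES["phenotype"], "phenotype", covariate_cols=list(covariate_cols)
    )
    ds = align_samples(me, ge, pheno, "phenotype", covariate_cols=list(covariate_cols))
    annot = AnnotationSet(
        cpgs=read_cpg_table(indir / _FILES["cpgs"]),
        genes=read_gene_table(indir / _FILES["genes"]),
    )
    return ds, annot
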