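"""Core data model and I/O for gene x cell expression matrices.

The pipeline operates on FPKM-like expression matrices with per-cell
metadata describing study of origin, embryonic day, developmental stage
and (possibly unknown) lineage label.  Matrices are stored as pandas
DataFrames (genes as rows, cells as columns) wrapped in a thin
:class:`ExpressionMatrix` that carries the unit tag and enforces basic
validity (unique identifiers, non-negativity on linear scales).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "UNITS",
    "STAGES",
    "STAGE_ORDER",
    "EMBRYONIC_DAYS",
    "COLLECTIONS",
    "SOURCE_STUDIES",
    "ExpressionMatrix",
    "MarkerPanel",
    "default_marker_panel",
    "make_annotation",
    "validate_annotation",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_annotation",
    "log_transform",
    "inverse_log_transform",
    "merge_studies",
]

UNITS = ("FPKM", "count", "log2FPKM")

#: all recognised developmental stages / cell states
STAGES = (
    "zygote", "4cell", "8cell", "morula", "earlyICM",
    "EPI", "PrE", "TE", "intermediate", "PSC", "unknown",
)

#: the ordered pre-implantation time course used for stage profiles
STAGE_ORDER = ("zygote", "4cell", "8cell", "morula", "earlyICM", "EPI", "PrE")

EMBRYONIC_DAYS = ("E3", "E4", "E5", "E6", "E7", "culture", "unknown")
COLLECTIONS = ("whole_embryo", "immunosurgery", "culture", "unknown")

ANNOTATION_COLUMNS = (
    "cell_id", "study", "embryonic_day", "stage", "collection", "lineage_label",
)

#: the three single-cell embryo profiling studies whose structure the
#: synthetic generator emulates (name, ENA accession, number of
#: single-cell transcriptomes contributed)
SOURCE_STUDIES = (
    ("Yan", "SRP011546", 124),
    ("Blakeley", "SRP055810", 30),
    ("Petropoulos", "ERP012552", 1529),
)


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed in the expected dialect."""


@dataclass
class ExpressionMatrix:
    """Gene x cell expression matrix with a unit tag.

    Parameters
    ----------
    data:
        DataFrame with gene identifiers as index and cell identifiers as
        columns.  Values must be non-negative for linear units.
    unit:
        One of ``"FPKM"``, ``"count"``, ``"log2FPKM"``.
    """

    data: pd.DataFrame
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell identifiers: {dupes[:5]}")
        if self.unit in ("FPKM", "count") and (self.data.values < 0).any():
            raise ValidationError(f"negative values not allowed for unit {self.unit}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], self.unit)

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(cells)], self.unit)


@dataclass
class MarkerPanel:
    """Ordered gene -> lineage map used for post-hoc classification.

    The default panel carries 12 high-confidence blastocyst markers,
    four per lineage (EPI, PrE, TE), and is user-replaceable.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lineages = {lin for _, lin in self.entries}
        bad = lineages - {"EPI", "PrE", "TE"}
        if bad:
            raise ValidationError(f"marker lineage must be EPI/PrE/TE, got {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def genes_for(self, lineage: str) -> list[str]:
        return [g for g, lin in self.entries if lin == lineage]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_id", "lineage"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerPanel":
        return cls(list(zip(df["gene_id"], df["lineage"])))


def default_marker_panel() -> MarkerPanel:
    """The 12-gene high-confidence blastocyst marker panel (4 per lineage)."""
    panel = MarkerPanel(
        [
            ("NANOG", "EPI"), ("SOX2", "EPI"), ("KLF17", "EPI"), ("TDGF1", "EPI"),
            ("GATA6", "PrE"), ("SOX17", "PrE"), ("GATA4", "PrE"), ("PDGFRA", "PrE"),
            ("GATA2", "TE"), ("GATA3", "TE"), ("KRT8", "TE"), ("CDX2", "TE"),
        ]
    )
    assert len(panel.entries) == 12
    return panel


# ---------------------------------------------------------------------------
# annotation handling (kept as a plain DataFrame with a fixed schema)
# ---------------------------------------------------------------------------

def make_annotation(cell_ids, study="unknown", embryonic_day="unknown",
                    stage="unknown", collection="unknown",
                    lineage_label="unknown") -> pd.DataFrame:
    """Build a per-cell annotation table; scalar arguments are broadcast."""
    n = len(cell_ids)

    def _col(v):
        if np.isscalar(v) or isinstance(v, str):
            return [v] * n
        v = list(v)
        if len(v) != n:
            raise ValidationError("annotation column length mismatch")
        return v

    df = pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "study": _col(study),
            "embryonic_day": _col(embryonic_day),
            "stage": _col(stage),
            "collection": _col(collection),
            "lineage_label": _col(lineage_label),
        }
    )
    validate_annotation(df)
    return df


def validate_annotation(ann: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> None:
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    if ann["cell_id"].duplicated().any():
        raise ValidationError("every cell_id must appear in exactly one annotation row")
    bad = set(ann["stage"]) - set(STAGES)
    if bad:
        raise ValidationError(f"unknown stages: {sorted(bad)}")
    if matrix is not None:
        extra = set(ann["cell_id"]) - set(matrix.cell_ids)
        if extra:
            raise ValidationError(f"annotation cells absent from matrix: {sorted(extra)[:5]}")


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _meta_path(path: str) -> str:
    return str(path) + ".meta.yaml"


def read_matrix(path: str, format: str = "TSV", unit: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV or MatrixMarket files.

    TSV dialect: UTF-8, tab-delimited, first column ``gene_id``, header
    row of cell identifiers.  MTX: coordinate real general with 1-based
    indices, accompanied by ``genes.tsv`` / ``cells.tsv`` sidecars (one
    identifier per line) in the same directory.  The unit is read from a
    ``<path>.meta.yaml`` sidecar when present unless ``unit`` is given.
    """
    fmt = format.upper()
    if fmt not in ("TSV", "MTX"):
        raise ValueError(f"unknown format {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if unit is None:
        meta = _meta_path(path)
        if os.path.exists(meta):
            with open(meta) as fh:
                unit = (yaml.safe_load(fh) or {}).get("unit", "FPKM")
        else:
            unit = "FPKM"
    if fmt == "TSV":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        if df.index.name != "gene_id":
            raise ParseError(f"first column of {path} must be named 'gene_id', got {df.index.name!r}")
        return ExpressionMatrix(df, unit)
    mat = scipy.io.mmread(path)
    d = os.path.dirname(os.path.abspath(path))
    genes_file = os.path.join(d, "genes.tsv")
    cells_file = os.path.join(d, "cells.tsv")
    for f in (genes_file, cells_file):
        if not os.path.exists(f):
            raise ParseError(f"MTX sidecar missing: {f}")
    genes = [l.strip() for l in open(genes_file) if l.strip()]
    cells = [l.strip() for l in open(cells_file) if l.strip()]
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(cells)):
        raise ParseError(
            f"MTX shape {dense.shape} does not match sidecars ({len(genes)} genes, {len(cells)} cells)"
        )
    return ExpressionMatrix(pd.DataFrame(dense, index=genes, columns=cells), unit)


def write_matrix(m: ExpressionMatrix, path: str, format: str = "TSV") -> None:
    """Write a matrix in the TSV or MTX dialect of :func:`read_matrix`."""
    fmt = format.upper()
    if fmt == "TSV":
        m.data.rename_axis("gene_id").to_csv(path, sep="\t", lineterminator="\n")
    elif fmt == "MTX":
        d = os.path.dirname(os.path.abspath(path))
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values))
        with open(os.path.join(d, "genes.tsv"), "w") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with open(os.path.join(d, "cells.tsv"), "w") as fh:
            fh.write("\n".join(m.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    with open(_meta_path(path), "w") as fh:
        yaml.safe_dump({"unit": m.unit}, fh)


def read_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    validate_annotation(ann)
    return ann


def write_annotation(ann: pd.DataFrame, path: str) -> None:
    ann.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# transforms and merging
# ---------------------------------------------------------------------------

def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1) transform (pseudocount 1; zero-preserving, monotone)."""
    if m.unit != "FPKM":
        raise ValidationError(f"log_transform expects FPKM input, got {m.unit}")
    return ExpressionMatrix(np.log2(m.data + 1.0), "log2FPKM")


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`log_transform`: 2**x - 1 back to the FPKM scale."""
    if m.unit != "log2FPKM":
        raise ValidationError(f"inverse_log_transform expects log2FPKM input, got {m.unit}")
    return ExpressionMatrix(np.maximum(2.0 ** m.data - 1.0, 0.0), "FPKM")


def merge_studies(matrices, annotations) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Merge per-study matrices on the intersection of their gene sets.

    Gene order in the result is lexicographic; column order is the
    concatenation of the inputs in the given order.  Cross-study
    comparability motivates intersection rather than union: only
    features quantified in every study are retained.
    """
    matrices = list(matrices)
    annotations = list(annotations)
    if len(matrices) != len(annotations):
        raise ValidationError("need one annotation table per matrix")
    units = {m.unit for m in matrices}
    if len(units) != 1:
        raise ValidationError(f"all matrices must share a unit, got {sorted(units)}")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValidationError("empty gene intersection across studies")
    genes = sorted(common)
    all_cells: list[str] = []
    for m in matrices:
        all_cells.extend(m.cell_ids)
    if len(set(all_cells)) != len(all_cells):
        raise ValidationError(
            "cell identifiers collide across studies; prefix them with the study name first"
        )
    merged = pd.concat([m.data.loc[genes] for m in matrices], axis=1)
    ann = pd.concat(annotations, ignore_index=True)
    validate_annotation(ann)
    out = ExpressionMatrix(merged, matrices[0].unit)
    validate_annotation(ann, out)
    return out, ann
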