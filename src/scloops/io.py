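"""Readers and writers for the standard formats the pipeline touches.

Supported formats: CellRanger-style MatrixMarket triplet (matrix.mtx +
genes.tsv + barcodes.tsv), dense TSV/CSV with genes as rows, GMT for all
gene sets, and TSV for cell annotations.  MatrixMarket coordinates are
1-based on disk per the standard; everything in memory is 0-based — the
conversion happens only here, inside scipy's MTX codec.

Gene symbols are matched exactly and case-sensitively throughout; no alias
resolution is attempted (silent symbol mapping is a reproducibility hazard).
Expression is assumed to be log-normalized already; pass ``raw_counts=True``
to apply a one-off library-size + log1p normalization at load.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    ANNOTATION_OPTIONAL_FIELDS,
    CellAnnotation,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "normalize_counts",
]

logger = logging.getLogger(__name__)

_SEP = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"mtx", "tsv", "csv"}:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def _read_id_column(path: Path) -> list[str]:
    # CellRanger genes.tsv carries "ensembl_id TAB symbol"; the first column
    # is the identifier either way.
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def normalize_counts(counts: np.ndarray) -> np.ndarray:
    """Library-size normalize raw counts to the median depth, then log1p."""
    counts = np.asarray(counts, dtype=float)
    depth = counts.sum(axis=0)
    if np.any(depth <= 0):
        bad = int(np.flatnonzero(depth <= 0)[0])
        raise ValueError(f"cell at column {bad} has zero total counts")
    scale = depth / np.median(depth)
    return np.log1p(counts / scale)


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    format: str | None = None,
    raw_counts: bool = False,
) -> ExpressionMatrix:
    """Load a gene x cell matrix from MTX triplet or dense TSV/CSV.

    For ``mtx`` the companion ``genes_path``/``cells_path`` are mandatory.
    Dense files carry gene ids in the first column and cell ids in the
    header.  Validation failures name the offending identifier.
    """
    matrix_path = Path(matrix_path)
    fmt = format or _infer_format(matrix_path)
    if fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx format requires genes_path and cells_path")
        try:
            mat = scipy.io.mmread(matrix_path)
        except Exception as exc:  # malformed header or body
            raise ValueError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
        genes = _read_id_column(Path(genes_path))
        cells = _read_id_column(Path(cells_path))
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix is {mat.shape[0]} x {mat.shape[1]} but id files list "
                f"{len(genes)} genes and {len(cells)} cells"
            )
        values = np.asarray(sp.coo_matrix(mat).todense(), dtype=float)
    elif fmt in _SEP:
        df = pd.read_csv(matrix_path, sep=_SEP[fmt], index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown expression format: {fmt!r}")
    if raw_counts:
        values = normalize_counts(values)
    return ExpressionMatrix(gene_ids=genes, cell_ids=cells, values=values)


def write_expression(
    expr: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    format: str | None = None,
) -> None:
    """Write a matrix as MTX triplet or dense TSV/CSV (genes as rows)."""
    matrix_path = Path(matrix_path)
    fmt = format or _infer_format(matrix_path)
    if fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("mtx format requires genes_path and cells_path")
        scipy.io.mmwrite(matrix_path, sp.coo_matrix(expr.values))
        Path(genes_path).write_text("".join(f"{g}\n" for g in expr.gene_ids))
        Path(cells_path).write_text("".join(f"{c}\n" for c in expr.cell_ids))
    elif fmt in _SEP:
        pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids).to_csv(
            matrix_path, sep=_SEP[fmt]
        )
    else:
        raise ValueError(f"unknown expression format: {fmt!r}")


def read_gmt(path: str | Path, kind: str) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene TAB gene ...).

    Every line yields one :class:`GeneSet` stamped with ``kind``.  Duplicate
    genes within a line collapse to set semantics with a warning; a line with
    fewer than three fields is an error reported with its line number.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description and at least one gene"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s: line %d (%s) lists duplicate genes; collapsed to %d unique",
                    path, lineno, name, len(unique),
                )
            coll.add(GeneSet(name=name, kind=kind, genes=unique))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path, description: str = "NA") -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


def read_annotation(path: str | Path) -> CellAnnotation:
    """Load a cell annotation TSV with at least cell_id and cell_type.

    Optional condition/region/donor columns default to a single
    ``"unspecified"`` level.  Leading/trailing whitespace in values is
    trimmed (the only silent repair any reader performs), with a log note.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in CellAnnotation.MANDATORY:
        if col not in df.columns:
            raise ValueError(f"annotation file {path} is missing column {col!r}")
    trimmed = False
    for col in df.columns:
        stripped = df[col].str.strip()
        if not stripped.equals(df[col]):
            trimmed = True
        df[col] = stripped
    if trimmed:
        logger.warning("%s: trimmed leading/trailing whitespace in annotation values", path)
    return CellAnnotation(df)


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    cols = ["cell_id", "cell_type", *ANNOTATION_OPTIONAL_FIELDS]
    ann.df[cols].to_csv(path, sep="\t", index=False)
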