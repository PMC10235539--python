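"""Cell expression specificity of genes (CESG) and novel-marker calling.

For gene *i* and cell type *j*, let m be the number of type-*j* cells
detecting the gene, M the number of type-*j* cells, K the number of
detecting cells outside the type and N the total cell count.  Then

    pct.1 = m / M,     pct.2 = K / (N - M),     CESG = pct.1 / pct.2.

CESG is infinite when a gene is detected exclusively inside one cell type
(pct.2 = 0 with pct.1 > 0) and zero for an undetected gene.  A gene is a
*novel marker candidate* for a type when it is strongly over-expressed there
(avg_log2FC > 1, adjusted p < 0.05 in a type-vs-rest test), is not already a
known marker, and its CESG strictly exceeds the reference CESG of the type's
known markers (the maximum over the known set — the conservative reading).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .datatypes import CellAnnotation, ExpressionMatrix, GeneSetCollection

__all__ = [
    "MarkerScore",
    "ExpressionFractions",
    "expression_fractions",
    "compute_cesg",
    "cesg_table",
    "identify_novel_markers",
]

logger = logging.getLogger(__name__)


class ExpressionFractions(NamedTuple):
    pct1: float
    pct2: float
    m: int
    M: int
    K: int
    N: int


@dataclass
class MarkerScore:
    """Specificity record for one (gene, cell type) candidate."""

    gene: str
    cell_type: str
    pct1: float
    pct2: float
    cesg: float
    avg_log2FC: float
    p_adj: float
    is_novel_candidate: bool
    note: str = ""


def expression_fractions(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    gene: str,
    cell_type: str,
    threshold: float = 0.0,
) -> ExpressionFractions:
    """Detection counts and fractions of ``gene`` inside vs outside ``cell_type``.

    A cell "expresses" the gene when its value is strictly above
    ``threshold`` (default 0 on the normalized matrix).
    """
    gi = expr.gene_index(gene)
    labels = ann.labels_for(expr.cell_ids)
    if cell_type not in set(labels):
        raise KeyError(f"unknown cell type: {cell_type!r}")
    in_type = labels == cell_type
    N = expr.n_cells
    M = int(in_type.sum())
    if N - M == 0:
        raise ValueError(
            f"cell type {cell_type!r} covers all {N} cells; pct.2 is undefined "
            "for a single-type partition"
        )
    det = expr.values[gi] > threshold
    m = int(np.sum(det & in_type))
    K = int(np.sum(det & ~in_type))
    return ExpressionFractions(m / M, K / (N - M), m, M, K, N)


def compute_cesg(pct1: float, pct2: float) -> float:
    """CESG = pct.1 / pct.2 with the exclusive-expression conventions.

    Returns ``inf`` when pct.2 = 0 and pct.1 > 0 (the gene is detected only
    inside the focal type) and 0 when pct.1 = 0; a fully undetected gene
    (both fractions zero) scores 0 with a warning.
    """
    if not (0 <= pct1 <= 1 and 0 <= pct2 <= 1):
        raise ValueError("pct.1 and pct.2 must lie in [0, 1]")
    if pct1 == 0:
        if pct2 == 0:
            logger.warning("gene unexpressed everywhere; CESG defined as 0")
        return 0.0
    if pct2 == 0:
        return math.inf
    return pct1 / pct2


def cesg_table(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """CESG with its fractions for every gene x cell type, long format.

    Columns: gene, cell_type, pct1, pct2, m, cesg.  Vectorized over the
    whole matrix; equivalent to :func:`expression_fractions` +
    :func:`compute_cesg` per pair.
    """
    labels = ann.labels_for(expr.cell_ids)
    types = [t for t in ann.levels("cell_type") if t in set(labels)]
    if len(types) < 2:
        raise ValueError("CESG needs at least two cell types in the matrix")
    det = expr.values > threshold  # genes x cells
    total = det.sum(axis=1)
    frames = []
    for t in types:
        in_type = labels == t
        M = int(in_type.sum())
        m = det[:, in_type].sum(axis=1)
        K = total - m
        pct1 = m / M
        pct2 = K / (expr.n_cells - M)
        with np.errstate(divide="ignore", invalid="ignore"):
            cesg = np.where(
                pct1 == 0, 0.0, np.where(pct2 == 0, np.inf, pct1 / np.maximum(pct2, 1e-300))
            )
        frames.append(
            pd.DataFrame(
                {
                    "gene": expr.gene_ids,
                    "cell_type": t,
                    "pct1": pct1,
                    "pct2": pct2,
                    "m": m,
                    "cesg": cesg,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _reference_cesg(
    table_t: pd.DataFrame, known_genes: frozenset[str]
) -> tuple[float, float]:
    """Max CESG among a type's known markers, with the max pct.1 among the
    infinite ones as the secondary reference for infinite ties."""
    rows = table_t[table_t["gene"].isin(known_genes)]
    if rows.empty:
        return math.nan, math.nan
    ref = float(rows["cesg"].max())
    ref_pct1 = float(rows.loc[np.isinf(rows["cesg"]), "pct1"].max()) if math.isinf(ref) else math.nan
    return ref, ref_pct1


def identify_novel_markers(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    known_markers: GeneSetCollection,
    deg_by_type: Mapping[str, pd.DataFrame],
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    threshold: float = 0.0,
) -> list[MarkerScore]:
    """Score and call novel cell-marker candidates per cell type.

    ``deg_by_type`` maps each cell type to its type-vs-rest differential
    expression table (columns gene, avg_log2FC, p_adj) as produced by
    :func:`scloops.diffexpr.de_by_type`.  ``known_markers`` carries one set
    per cell type, named after the type.

    A candidate must clear avg_log2FC > ``lfc_min`` (strict), p_adj <
    ``alpha``, not be a known marker, and have CESG strictly above the
    type's reference (see module docstring).  When the reference itself is
    infinite, only an infinite candidate with a larger pct.1 is called.
    Types without a known-marker set yield candidates flagged
    ``no_reference`` and never called novel — they await manual curation, as
    does the literature check that is outside this package's scope.

    Returns scores sorted by CESG descending, ties broken by avg_log2FC
    descending then gene id.
    """
    table = cesg_table(expr, ann, threshold=threshold)
    out: list[MarkerScore] = []
    for cell_type, de in deg_by_type.items():
        table_t = table[table["cell_type"] == cell_type].set_index("gene")
        known = known_markers[cell_type].genes if cell_type in known_markers else None
        if known is None:
            logger.warning("no known-marker set for %r; candidates flagged", cell_type)
            ref, ref_pct1 = math.nan, math.nan
        else:
            ref, ref_pct1 = _reference_cesg(table_t.reset_index(), known)
        passing = de[(de["avg_log2FC"] > lfc_min) & (de["p_adj"] < alpha)]
        for row in passing.itertuples():
            gene = row.gene
            if known is not None and gene in known:
                continue  # exclusion rule: known markers are never "novel"
            if gene not in table_t.index:
                continue
            cesg = float(table_t.at[gene, "cesg"])
            pct1 = float(table_t.at[gene, "pct1"])
            pct2 = float(table_t.at[gene, "pct2"])
            if known is None or math.isnan(ref):
                novel, note = False, "no_reference"
            elif math.isinf(ref):
                novel = math.isinf(cesg) and pct1 > ref_pct1
                note = "infinite_reference"
            else:
                novel, note = cesg > ref, ""
            out.append(
                MarkerScore(
                    gene=gene,
                    cell_type=cell_type,
                    pct1=pct1,
                    pct2=pct2,
                    cesg=cesg,
                    avg_log2FC=float(row.avg_log2FC),
                    p_adj=float(row.p_adj),
                    is_novel_candidate=bool(novel),
                    note=note,
                )
            )
    out.sort(key=lambda s: (-s.cesg, -s.avg_log2FC, s.gene))
    return out


def marker_scores_to_frame(scores: list[MarkerScore]) -> pd.DataFrame:
    """Flatten marker scores for TSV export."""
    return pd.DataFrame([s.__dict__ for s in scores])
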