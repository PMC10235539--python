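"""Non-negative gene-expression patterns and their cell-type predictive power.

The expression matrix V (genes x cells) is factorized as V ~ A @ P with
non-negative amplitude A (genes x k, gene weights) and pattern P
(k x cells, per-cell sample weights) matrices, by multiplicative updates on
the Frobenius objective from a seeded random start.  The objective is
non-increasing at every update, and a fixed seed gives bitwise-identical
factors.

A pattern's *predictive power* for a cell type is the AUROC of its sample
weights for discriminating that type from all other cells, computed by the
midrank Mann-Whitney construction U / (n_c * n_other).  Patterns with power
>= 0.7 (boundary inclusive) are treated as cell-associated; each pattern is
turned into a gene set by taking the top genes of its amplitude column
(default 50 — the membership rule is a declared choice, configurable to a
weight quantile).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import CellAnnotation, ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "PatternDecomposition",
    "nmf_decompose",
    "predictive_power",
    "auc_score",
    "select_patterns",
    "pattern_gene_sets",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class PatternDecomposition:
    """Result of the seeded NMF: A (genes x k), P (k x cells)."""

    amplitude: pd.DataFrame
    pattern: pd.DataFrame
    k: int
    seed: int
    reconstruction_error: float  # relative Frobenius error ||V - AP|| / ||V||
    error_history: np.ndarray  # relative error after each full update

    @property
    def pattern_names(self) -> list[str]:
        return list(self.amplitude.columns)


def nmf_decompose(
    expr: ExpressionMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> PatternDecomposition:
    """Multiplicative-update NMF of the expression matrix at rank ``k``.

    Stops when the relative Frobenius error decreases by less than ``tol``
    between iterations, or after ``max_iter`` full updates.
    """
    V = expr.values
    G, S = V.shape
    if not (1 <= k < min(G, S)):
        raise ValueError(f"k must satisfy 1 <= k < min(genes, cells) = {min(G, S)}; got {k}")
    v_norm = float(np.linalg.norm(V))
    if v_norm == 0:
        raise ValueError("cannot factorize an all-zero matrix")
    rng = np.random.default_rng(seed)
    scale = math.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(G, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, S)) * scale

    history = []
    prev = np.inf
    for _ in range(max_iter):
        # H update, then W update; each is non-increasing in the objective
        WtV = W.T @ V
        H *= WtV / (W.T @ W @ H + _EPS)
        VHt = V @ H.T
        W *= VHt / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(V - W @ H)) / v_norm
        history.append(err)
        if prev - err < tol * max(prev, _EPS):
            break
        prev = err

    names = [f"pattern_{i + 1}" for i in range(k)]
    return PatternDecomposition(
        amplitude=pd.DataFrame(W, index=expr.gene_ids, columns=names),
        pattern=pd.DataFrame(H, index=names, columns=expr.cell_ids),
        k=k,
        seed=seed,
        reconstruction_error=history[-1],
        error_history=np.array(history),
    )


def auc_score(weights: np.ndarray, positive: np.ndarray) -> float:
    """AUROC of ``weights`` for the boolean ``positive`` mask (midranks)."""
    n1 = int(positive.sum())
    n0 = len(weights) - n1
    if n1 == 0 or n0 == 0:
        return math.nan
    r = rankdata(weights)
    u = r[positive].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def predictive_power(
    decomp: PatternDecomposition,
    ann: CellAnnotation,
    stratify_by_condition: bool = False,
) -> pd.DataFrame:
    """AUROC of each pattern's sample weights per cell type.

    Rows are patterns; columns are cell types, or (condition, cell type)
    pairs when ``stratify_by_condition`` is set.  Entries for types with
    fewer than 2 cells (in the stratum) are reported missing (NaN).
    """
    cells = list(decomp.pattern.columns)
    labels = ann.labels_for(cells)
    types = [t for t in ann.levels("cell_type") if t in set(labels)]
    H = decomp.pattern.to_numpy()

    def _block(mask_cells: np.ndarray) -> pd.DataFrame:
        sub_labels = labels[mask_cells]
        sub_H = H[:, mask_cells]
        cols = {}
        for t in types:
            pos = sub_labels == t
            if pos.sum() < 2 or (~pos).sum() < 1:
                logger.warning("cell type %r has < 2 cells in stratum; AUC undefined", t)
                cols[t] = [math.nan] * decomp.k
                continue
            cols[t] = [auc_score(sub_H[p], pos) for p in range(decomp.k)]
        return pd.DataFrame(cols, index=decomp.pattern_names)

    if not stratify_by_condition:
        return _block(np.ones(len(cells), dtype=bool))
    cond = ann.labels_for(cells, "condition")
    blocks = {
        lvl: _block(cond == lvl)
        for lvl in ann.levels("condition")
        if (cond == lvl).any()
    }
    return pd.concat(blocks, axis=1)


def select_patterns(
    table: pd.DataFrame, threshold: float = 0.7
) -> dict[str, list[str]]:
    """Per cell type, the patterns with predictive power >= threshold.

    Returned lists are sorted by power descending (ties by pattern name).
    """
    out: dict[str, list[str]] = {}
    for t in table.columns:
        col = table[t].dropna()
        hits = col[col >= threshold]
        out[t] = list(hits.sort_values(ascending=False, kind="stable").index)
    return out


def pattern_gene_sets(
    decomp: PatternDecomposition,
    top_n: int | None = 50,
    quantile: float | None = None,
    kind: str = "pattern_top_genes",
) -> GeneSetCollection:
    """One gene set per pattern from its amplitude column.

    Membership rule: the ``top_n`` genes by amplitude weight (ties broken by
    gene id for determinism), or — when ``quantile`` is given — the top
    (1 - quantile) fraction of genes.  ``top_n`` above the gene count is
    capped with a warning.
    """
    G = decomp.amplitude.shape[0]
    if quantile is not None:
        n = max(1, int(round((1.0 - quantile) * G)))
    else:
        if top_n is None:
            raise ValueError("pass top_n or quantile")
        n = top_n
        if n > G:
            logger.warning("top_n=%d exceeds %d genes; capped", n, G)
            n = G
    coll = GeneSetCollection(universe=frozenset(decomp.amplitude.index))
    for name in decomp.pattern_names:
        col = decomp.amplitude[name]
        order = sorted(zip(-col.to_numpy(), col.index))  # weight desc, gene asc
        genes = frozenset(g for _, g in order[:n])
        coll.add(GeneSet(name=name, kind=kind, genes=genes))
    return coll
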