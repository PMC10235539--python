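"""Per-cell-type differential expression by Wilcoxon rank-sum.

Two contrast kinds are supported: each type against all remaining cells
(``vs_rest``, used to rank marker candidates) and disease against control
within one type (``condition_within_type``).  Per gene, a two-sided rank-sum
p-value is computed from the tie- and continuity-corrected normal
approximation, or from exact enumeration of all group assignments when the
pooled size is at most ``EXACT_MAX_N`` cells.  The fold change is the conventional

    avg_log2FC = log2((mean(expm1 x_a) + 1) / (mean(expm1 x_b) + 1))

i.e. group means on the de-logged (natural) expression scale with a
pseudocount of 1, which keeps it finite.  Adjusted p-values use Bonferroni
over the tested genes (the convention the thresholds were calibrated
against); pass ``adjust="bh"`` for Benjamini-Hochberg instead.  DEG calling
keeps |avg_log2FC| >= 0.25 (boundary inclusive) and p_adj < 0.05 (strict).

All genes detected in at least one cell of either group are tested; a
``min_pct`` prefilter is available for speed but off by default.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .datatypes import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)

__all__ = [
    "wilcoxon_de",
    "filter_degs",
    "de_by_type",
    "deg_sets_by_type",
    "EXACT_MAX_N",
]

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # pooled size at or below which the exact branch runs

CONTRAST_KINDS = ("vs_rest", "condition_within_type")


def _exact_two_sided_p(xa: np.ndarray, xb: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group-A assignments.

    Ties are handled by enumerating the actual pooled values with midranks,
    so the null distribution conditions on the observed ties.  Two-sided p
    is 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    pooled = np.concatenate([xa, xb])
    n, na = len(pooled), len(xa)
    ranks = rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(n), na)]
    ) - na * (na + 1) / 2
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _tie_term(row: np.ndarray) -> float:
    _, counts = np.unique(row, return_counts=True)
    return float(np.sum(counts**3 - counts))


def wilcoxon_de(
    expr: ExpressionMatrix,
    cells_a: list[str] | np.ndarray,
    cells_b: list[str] | np.ndarray,
    contrast: str = "",
    min_pct: float = 0.0,
    adjust: str = "bonferroni",
    exact_max_n: int = EXACT_MAX_N,
) -> pd.DataFrame:
    """Rank-sum differential expression of group A versus group B.

    Returns a DataFrame with columns gene, contrast, avg_log2FC, p_value,
    p_adj, pct1, pct2, covering every gene detected in either group (and
    above ``min_pct`` detection in at least one, when set).  Swapping the
    groups negates avg_log2FC and leaves p unchanged.
    """
    ia = expr.cell_indices(cells_a)
    ib = expr.cell_indices(cells_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            f"each group needs at least 2 cells (got {len(ia)} and {len(ib)})"
        )
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")
    A = expr.values[:, ia]
    B = expr.values[:, ib]
    pct1 = (A > 0).mean(axis=1)
    pct2 = (B > 0).mean(axis=1)
    tested = (pct1 > 0) | (pct2 > 0)
    if min_pct > 0:
        tested &= (pct1 >= min_pct) | (pct2 >= min_pct)
    idx = np.flatnonzero(tested)

    na, nb = len(ia), len(ib)
    n = na + nb
    X = np.hstack([A[idx], B[idx]])
    if n <= exact_max_n:
        p = np.array([_exact_two_sided_p(X[g, :na], X[g, na:]) for g in range(len(idx))])
    else:
        ranks = rankdata(X, axis=1)
        ra = ranks[:, :na].sum(axis=1)
        u = ra - na * (na + 1) / 2
        mu = na * nb / 2
        tie = np.array([_tie_term(X[g]) for g in range(len(idx))])
        var = na * nb / 12 * ((n + 1) - tie / (n * (n - 1)))
        # continuity-corrected normal approximation (wilcox.test convention)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.maximum(np.abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
        p = np.where(var <= 0, 1.0, 2 * norm.sf(np.nan_to_num(z)))
        p = np.minimum(p, 1.0)

    lfc = np.log2(
        (np.expm1(A[idx]).mean(axis=1) + 1) / (np.expm1(B[idx]).mean(axis=1) + 1)
    )
    # constant genes carry no signal by construction
    constant = np.array([np.all(X[g] == X[g, 0]) for g in range(len(idx))])
    p[constant] = 1.0
    lfc[constant] = 0.0

    if adjust == "bonferroni":
        p_adj = np.minimum(p * len(idx), 1.0)
    elif adjust == "bh":
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        p_adj = np.minimum(adj, 1.0)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return pd.DataFrame(
        {
            "gene": [expr.gene_ids[i] for i in idx],
            "contrast": contrast,
            "avg_log2FC": lfc,
            "p_value": p,
            "p_adj": p_adj,
            "pct1": pct1[idx],
            "pct2": pct2[idx],
        }
    )


def filter_degs(
    records: pd.DataFrame, lfc_min: float = 0.25, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep records with |avg_log2FC| >= lfc_min and p_adj < alpha.

    The fold-change gate is two-sided and boundary inclusive; the
    significance gate is strict.
    """
    keep = (records["avg_log2FC"].abs() >= lfc_min) & (records["p_adj"] < alpha)
    return records[keep].reset_index(drop=True)


def de_by_type(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    contrast_kind: str = "vs_rest",
    condition_a: str | None = None,
    condition_b: str | None = None,
    min_cells: int = 3,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run the per-type contrast and return one DE table per cell type.

    ``vs_rest`` contrasts each type against all other cells;
    ``condition_within_type`` contrasts ``condition_a`` vs ``condition_b``
    (default: the first two condition levels) inside each type.  Types with
    fewer than ``min_cells`` cells on either side yield an empty table with
    a warning.
    """
    if contrast_kind not in CONTRAST_KINDS:
        raise ValueError(f"contrast_kind must be one of {CONTRAST_KINDS}")
    labels = ann.labels_for(expr.cell_ids)
    cond = ann.labels_for(expr.cell_ids, "condition")
    if contrast_kind == "condition_within_type":
        levels = ann.levels("condition")
        condition_a = condition_a or levels[0]
        condition_b = condition_b or levels[1]
    cell_ids = np.array(expr.cell_ids)
    out: dict[str, pd.DataFrame] = {}
    empty = pd.DataFrame(
        columns=["gene", "contrast", "avg_log2FC", "p_value", "p_adj", "pct1", "pct2"]
    )
    for t in dict.fromkeys(labels):
        in_type = labels == t
        if contrast_kind == "vs_rest":
            a = cell_ids[in_type]
            b = cell_ids[~in_type]
            name = f"{t}:vs_rest"
        else:
            a = cell_ids[in_type & (cond == condition_a)]
            b = cell_ids[in_type & (cond == condition_b)]
            name = f"{t}:{condition_a}_vs_{condition_b}"
        if len(a) < min_cells or len(b) < min_cells:
            logger.warning(
                "cell type %r too small for %s (%d vs %d cells); empty result",
                t, contrast_kind, len(a), len(b),
            )
            out[t] = empty.copy()
            continue
        out[t] = wilcoxon_de(expr, a, b, contrast=name, **kwargs)
    return out


def deg_sets_by_type(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    contrast_kind: str = "condition_within_type",
    lfc_min: float = 0.25,
    alpha: float = 0.05,
    de_tables: Mapping[str, pd.DataFrame] | None = None,
    **kwargs,
) -> GeneSetCollection:
    """Filtered DEG sets, one :class:`GeneSet` per cell type.

    ``de_tables`` may supply pre-computed results from :func:`de_by_type`;
    otherwise the contrast is run here.  Types whose contrast produced no
    records yield an empty set.
    """
    tables = de_tables if de_tables is not None else de_by_type(
        expr, ann, contrast_kind, **kwargs
    )
    coll = GeneSetCollection(universe=frozenset(expr.gene_ids))
    for t, table in tables.items():
        genes = frozenset(filter_degs(table, lfc_min, alpha)["gene"])
        coll.add(GeneSet(name=t, kind="deg_set", genes=genes))
    return coll
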