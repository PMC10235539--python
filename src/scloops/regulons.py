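"""Regulon activity (RAS), specificity (RSS) and the selection rules.

A regulon is a transcription factor with its putative target set; target
sets are inputs here (GMT), as inferring them (co-expression plus motif
pruning) is a separate, upstream problem.

*RAS* is the per-cell recovery-curve statistic: genes are ranked by
descending expression within the cell (ties broken by a fixed permutation
seeded from the cell index), and RAS is the area under the step curve of
regulon-target recovery within the top ``top_fraction`` of ranks,
normalized by the maximal achievable area, so RAS lies in [0, 1].

*RSS(R, C)* = 1 - JSD(P^R, P^C), where P^R is the regulon's RAS vector
normalized to sum 1 over cells, P^C the uniform indicator distribution of
cell type C, and JSD the Jensen-Shannon divergence with log base 2 (so
JSD, and hence RSS, lies in [0, 1]).

Selection: a regulon is *cell-type specific* for type c when RSS(r, c) >=
0.1 and its Z-score there is >= 2, where Z standardizes the regulon's mean
RAS per type across all types; it is *disease-associated* when the log2
ratio of its condition-wise RSS exceeds 1 in magnitude.  Condition-wise
fold changes are clipped to +/-10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .datatypes import CellAnnotation, ExpressionMatrix, GeneSetCollection

__all__ = [
    "RegulonActivity",
    "jsd",
    "compute_ras",
    "compute_rss",
    "ras_zscore",
    "rss_condition_fold_change",
    "select_regulons",
    "compute_regulon_activity",
]

logger = logging.getLogger(__name__)

FC_CLIP = 10.0


@dataclass
class RegulonActivity:
    """RAS/RSS bundle: activity per cell, specificity per type, Z-scores and
    optional condition-wise RSS log2 fold changes."""

    ras: pd.DataFrame  # regulons x cells
    rss: pd.DataFrame  # regulons x cell types
    zscore: pd.DataFrame  # regulons x cell types
    rss_log2fc: pd.DataFrame | None = None  # regulons x cell types


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with log base 2 (lies in [0, 1])."""
    return float(jensenshannon(p, q, base=2) ** 2)


def _recovery_auc(positions: np.ndarray, n_targets: int, threshold: int) -> float:
    """Area of the step recovery curve over ranks 1..threshold, normalized.

    ``positions`` are the 1-based ranks of the targets found within the
    threshold.  The maximal area corresponds to the targets occupying the
    top ranks.
    """
    area = float(np.sum(threshold - positions + 1))
    g = min(n_targets, threshold)
    max_area = g * (g + 1) / 2 + (threshold - g) * g
    return area / max_area


def compute_ras(
    expr: ExpressionMatrix,
    regulons: GeneSetCollection,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Regulon activity score per (regulon, cell); values in [0, 1].

    A regulon with no targets present in the matrix yields a missing row
    with a warning.
    """
    if not (0 < top_fraction < 1):
        raise ValueError(f"top_fraction must lie in (0, 1); got {top_fraction}")
    G = expr.n_genes
    threshold = math.ceil(top_fraction * G)
    target_idx: dict[str, np.ndarray] = {}
    for gs in regulons:
        idx = [expr._gene_index[g] for g in gs.genes if g in expr._gene_index]
        if not idx:
            logger.warning("regulon %r shares no genes with the matrix; RAS missing", gs.name)
        target_idx[gs.name] = np.array(sorted(idx), dtype=int)

    ras = np.full((len(target_idx), expr.n_cells), np.nan)
    names = list(target_idx)
    pos = np.empty(G, dtype=int)
    for c in range(expr.n_cells):
        perm = np.random.default_rng(c).permutation(G)
        order = np.lexsort((perm, -expr.values[:, c]))
        pos[order] = np.arange(1, G + 1)
        for r, name in enumerate(names):
            idx = target_idx[name]
            if len(idx) == 0:
                continue
            p = pos[idx]
            ras[r, c] = _recovery_auc(p[p <= threshold], len(idx), threshold)
    return pd.DataFrame(ras, index=names, columns=expr.cell_ids)


def compute_rss(ras: pd.DataFrame, ann: CellAnnotation) -> pd.DataFrame:
    """RSS(R, C) = 1 - JSD(P^R, P^C) per regulon and cell type.

    Regulons whose RAS row is all zero (or missing) get a missing RSS row
    with a warning.
    """
    cells = list(ras.columns)
    labels = ann.labels_for(cells)
    types = [t for t in ann.levels("cell_type") if t in set(labels)]
    out = pd.DataFrame(np.nan, index=ras.index, columns=types)
    indicators = {}
    for t in types:
        ind = (labels == t).astype(float)
        indicators[t] = ind / ind.sum()
    for name, row in ras.iterrows():
        v = row.to_numpy(dtype=float)
        total = np.nansum(v)
        if not np.isfinite(v).all() or total <= 0:
            logger.warning("regulon %r has zero/missing RAS; RSS undefined", name)
            continue
        p_r = v / total
        for t in types:
            div = jsd(p_r, indicators[t])
            out.at[name, t] = 1.0 - div
    return out


def ras_zscore(ras: pd.DataFrame, ann: CellAnnotation) -> pd.DataFrame:
    """Standardized per-type mean RAS, per regulon across cell types.

    Population standard deviation; a regulon flat across types scores 0
    everywhere.
    """
    cells = list(ras.columns)
    labels = ann.labels_for(cells)
    types = [t for t in ann.levels("cell_type") if t in set(labels)]
    means = pd.DataFrame(
        {t: ras.loc[:, np.array(labels) == t].mean(axis=1) for t in types}
    )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = means.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def rss_condition_fold_change(
    expr: ExpressionMatrix,
    regulons: GeneSetCollection,
    ann: CellAnnotation,
    level_a: str | None = None,
    level_b: str | None = None,
    top_fraction: float = 0.05,
    clip: float = FC_CLIP,
) -> pd.DataFrame:
    """log2(RSS in condition A / RSS in condition B) per (regulon, type).

    RAS and RSS are recomputed separately on each condition's cells.  Values
    are clipped to +/-``clip``; a zero denominator (or numerator) produces
    the +/-``clip`` sentinel, and a regulon silent in both conditions scores
    0 for that type.
    """
    levels = ann.levels("condition")
    if len(levels) < 2:
        raise ValueError("condition fold change needs two condition levels")
    level_a = level_a or levels[0]
    level_b = level_b or levels[1]

    def _rss_for(level: str) -> pd.DataFrame:
        mask = ann.mask("condition", level, expr.cell_ids)
        sub = expr.subset_cells(mask)
        sub_ann = ann.subset(sub.cell_ids)
        return compute_rss(compute_ras(sub, regulons, top_fraction), sub_ann)

    rss_a = _rss_for(level_a)
    rss_b = _rss_for(level_b)
    types = [t for t in rss_a.columns if t in rss_b.columns]
    out = pd.DataFrame(np.nan, index=rss_a.index, columns=types)
    for name in rss_a.index:
        for t in types:
            a = rss_a.at[name, t]
            b = rss_b.at[name, t]
            if np.isnan(a) or np.isnan(b):
                continue
            if a <= 0 and b <= 0:
                out.at[name, t] = 0.0
            elif b <= 0:
                out.at[name, t] = clip
            elif a <= 0:
                out.at[name, t] = -clip
            else:
                out.at[name, t] = float(np.clip(np.log2(a / b), -clip, clip))
    return out


def select_regulons(
    activity: RegulonActivity,
    mode: str = "cell_specific",
    rss_min: float = 0.1,
    z_min: float = 2.0,
    lfc_min: float = 1.0,
) -> dict[str, list[str]]:
    """Assign regulons to cell types by the selection rules.

    ``cell_specific``: RSS(r, c) >= rss_min and Z(r, c) >= z_min (the
    Z-score evaluated across all cell types; at least 3 types required).
    ``disease``: |log2 fold change of condition-wise RSS| > lfc_min.
    """
    if mode == "cell_specific":
        if activity.rss.shape[1] < 3:
            raise ValueError("cell-specific selection needs at least 3 cell types")
        hit = (activity.rss >= rss_min) & (activity.zscore >= z_min)
    elif mode == "disease":
        if activity.rss_log2fc is None:
            raise ValueError("disease mode needs rss_log2fc (run rss_condition_fold_change)")
        hit = activity.rss_log2fc.abs() > lfc_min
    else:
        raise ValueError(f"mode must be cell_specific or disease, got {mode!r}")
    return {
        t: sorted(hit.index[hit[t].fillna(False)])
        for t in hit.columns
    }


def compute_regulon_activity(
    expr: ExpressionMatrix,
    regulons: GeneSetCollection,
    ann: CellAnnotation,
    top_fraction: float = 0.05,
    with_condition_fc: bool = False,
) -> RegulonActivity:
    """Convenience: RAS, RSS, Z-scores and (optionally) condition fold change."""
    ras = compute_ras(expr, regulons, top_fraction)
    ok = ras.dropna(how="all").index
    ras = ras.loc[ok]
    rss = compute_rss(ras, ann)
    z = ras_zscore(ras, ann)
    fc = (
        rss_condition_fold_change(expr, regulons, ann, top_fraction=top_fraction).loc[ok]
        if with_condition_fc
        else None
    )
    return RegulonActivity(ras=ras, rss=rss, zscore=z, rss_log2fc=fc)
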