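"""Recovery metrics scoring a pipeline run against planted ground truth."""

from __future__ import annotations

import numpy as np

from .loops import hypergeom_ploop
from .pipeline import PipelineResult

__all__ = [
    "marker_top_rank_rate",
    "deg_recall",
    "pattern_power_by_type",
    "regulon_assignment_accuracy",
    "loop_recovery",
    "null_edge_rejection_rate",
]


def marker_top_rank_rate(result: PipelineResult) -> float:
    """Fraction of planted exclusive markers that rank first by CESG among
    their type's candidates and are called novel."""
    truth = result.dataset.truth.planted_markers
    if not truth:
        return float("nan")
    by_type: dict[str, list] = {}
    for s in result.marker_scores:  # already sorted by CESG desc
        by_type.setdefault(s.cell_type, []).append(s)
    hits = 0
    for gene, t in truth.items():
        scores = by_type.get(t, [])
        if scores and scores[0].gene == gene and scores[0].is_novel_candidate:
            hits += 1
    return hits / len(truth)


def deg_recall(result: PipelineResult) -> float:
    """Fraction of planted condition-DEGs present in their type's DEG set."""
    truth = result.dataset.truth.planted_degs
    if not truth:
        return float("nan")
    hits = sum(
        1
        for (gene, t) in truth
        if t in result.deg_sets and gene in result.deg_sets[t].genes
    )
    return hits / len(truth)


def pattern_power_by_type(result: PipelineResult) -> dict[str, tuple[str, float, float]]:
    """Per planted type: (best-matching factor, its AUC for the type, its
    maximal AUC over the other types)."""
    out: dict[str, tuple[str, float, float]] = {}
    power = result.power
    for _, (t, _genes) in result.dataset.truth.planted_patterns.items():
        col = power[t].dropna()
        best = col.idxmax()
        others = power.loc[best].drop(t).max()
        out[t] = (best, float(col.loc[best]), float(others))
    return out


def regulon_assignment_accuracy(result: PipelineResult) -> float:
    """Fraction of planted cell-specific regulons selected for exactly their
    planted type and no other."""
    truth = result.dataset.truth.planted_regulons
    cell_specific = {
        name: v
        for name, v in truth.items()
        if set(v["active_conditions"]) == set(result.dataset.config.conditions)
    }
    if not cell_specific:
        return float("nan")
    hits = 0
    for name, v in cell_specific.items():
        assigned = {t for t, regs in result.selected_regulons.items() if name in regs}
        if assigned == set(v["active_types"]):
            hits += 1
    return hits / len(cell_specific)


def loop_recovery(result: PipelineResult) -> float:
    """Fraction of planted ternary loops recovered: a loop for the planted
    cell type whose regulon node is the planted regulon."""
    truth = result.dataset.truth.planted_loops
    if not truth:
        return float("nan")
    found = {(lo.cell_type, lo.regulon) for lo in result.loop_graph.loops}
    hits = sum(1 for (_p, reg, _d, t) in truth if (t, reg) in found)
    return hits / len(truth)


def null_edge_rejection_rate(
    rng: np.random.Generator,
    n_pairs: int = 1000,
    universe_size: int = 2000,
    size_1: int = 50,
    size_2: int = 20,
    alpha: float = 0.05,
) -> float:
    """Empirical P_loop rejection rate for independent random set pairs.

    Under independent draws the rate must not exceed alpha (the discrete
    tail makes the test conservative)."""
    rejections = 0
    for _ in range(n_pairs):
        a = rng.choice(universe_size, size=size_1, replace=False)
        b = rng.choice(universe_size, size=size_2, replace=False)
        k = len(set(a.tolist()) & set(b.tolist()))
        if hypergeom_ploop(k, size_1, size_2, universe_size) < alpha:
            rejections += 1
    return rejections / n_pairs
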