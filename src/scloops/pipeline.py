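"""End-to-end orchestration of the mining pipeline on one dataset.

Runs, in order: type-vs-rest and condition-within-type differential
expression, CESG-based novel-marker calling, ACT abundance, NMF patterns
with predictive power, regulon activity/specificity with both selection
modes, and cell-specific ternary-loop construction.  The result object
keeps every intermediate so callers (tests, the CLI, acceptance scripts)
can score any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .abundance import ACTTable, compute_act
from .datatypes import GeneSet, GeneSetCollection
from .diffexpr import de_by_type, deg_sets_by_type
from .loops import LoopGraph, build_loops
from .markers import MarkerScore, identify_novel_markers
from .patterns import (
    PatternDecomposition,
    nmf_decompose,
    pattern_gene_sets,
    predictive_power,
    select_patterns,
)
from .regulons import RegulonActivity, compute_regulon_activity, select_regulons
from .simulate import SimulatedDataset, SimulationConfig, generate

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    de_vs_rest: dict[str, pd.DataFrame]
    deg_sets: GeneSetCollection  # condition-within-type, filtered
    marker_scores: list[MarkerScore]
    act_condition: ACTTable
    decomposition: PatternDecomposition
    power: pd.DataFrame
    selected_patterns: dict[str, list[str]]
    pattern_sets: GeneSetCollection
    activity: RegulonActivity
    selected_regulons: dict[str, list[str]]  # cell-specific mode
    selected_regulons_disease: dict[str, list[str]]
    loop_graph: LoopGraph


def run_pipeline(
    config: SimulationConfig | None = None,
    dataset: SimulatedDataset | None = None,
    nmf_k: int = 10,
    nmf_seed: int | None = None,
    nmf_max_iter: int = 100,
    pattern_top_n: int = 50,
    top_fraction: float = 0.05,
    lfc_min: float = 0.25,
    alpha: float = 0.05,
    loop_alpha: float = 0.05,
    power_threshold: float = 0.7,
) -> PipelineResult:
    """Run every stage on a generated (or supplied) dataset.

    ``nmf_seed`` defaults to the dataset's simulation seed so the whole run
    is a function of one integer.
    """
    if dataset is None:
        if config is None:
            config = SimulationConfig()
        dataset = generate(config)
    expr, ann = dataset.expr, dataset.ann
    if nmf_seed is None:
        nmf_seed = dataset.config.seed

    de_rest = de_by_type(expr, ann, "vs_rest")
    deg_sets = deg_sets_by_type(
        expr, ann, "condition_within_type", lfc_min=lfc_min, alpha=alpha
    )
    markers = identify_novel_markers(expr, ann, dataset.known_markers, de_rest)
    act = compute_act(ann, "condition")

    decomp = nmf_decompose(expr, k=nmf_k, seed=nmf_seed, max_iter=nmf_max_iter)
    power = predictive_power(decomp, ann)
    sel_patterns = select_patterns(power, threshold=power_threshold)
    pattern_sets = pattern_gene_sets(decomp, top_n=pattern_top_n)

    activity = compute_regulon_activity(
        expr, dataset.regulons, ann, top_fraction=top_fraction, with_condition_fc=True
    )
    sel_regulons = select_regulons(activity, mode="cell_specific")
    sel_regulons_disease = select_regulons(activity, mode="disease")

    patterns_by_type = {
        t: [pattern_sets[p] for p in ps] for t, ps in sel_patterns.items()
    }
    regulons_by_type = {
        t: [dataset.regulons[r] for r in rs] for t, rs in sel_regulons.items()
    }
    deg_by_type = {gs.name: gs for gs in deg_sets}
    loop_graph = build_loops(
        patterns_by_type,
        regulons_by_type,
        deg_by_type,
        universe=frozenset(expr.gene_ids),
        alpha=loop_alpha,
    )
    return PipelineResult(
        dataset=dataset,
        de_vs_rest=de_rest,
        deg_sets=deg_sets,
        marker_scores=markers,
        act_condition=act,
        decomposition=decomp,
        power=power,
        selected_patterns=sel_patterns,
        pattern_sets=pattern_sets,
        activity=activity,
        selected_regulons=sel_regulons,
        selected_regulons_disease=sel_regulons_disease,
        loop_graph=loop_graph,
    )
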