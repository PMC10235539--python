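"""Synthetic single-cell datasets with planted ground truth.

The generator emulates a small RPE/choroid-like dissociation: ~8 cell types
across a disease and a control condition and two tissue regions, with
negative-binomial counts (gene-specific log-normal baselines, common
dispersion) that are library-size normalized and log1p transformed — the
same convention the pipeline assumes for its input.

Planted structure, all recorded in :class:`GroundTruth`:

* one *exclusive novel marker* per type — detected only inside its type
  (infinite CESG) — plus a small known-marker set per type that is elevated
  in the type but detectable elsewhere (finite CESG), standing in for
  curated marker lists;
* condition DEGs per type — genes whose mean is multiplied by
  ``exp(deg_effect)`` in the disease cells of that type;
* one co-expression program (pattern) per planted type — a block of genes
  jointly elevated in the type's cells;
* regulon target sets jointly elevated in designated (type, condition)
  strata: cell-specific regulons are active in one type under both
  conditions, disease regulons only in the disease stratum of their type;
* ternary loops, built by seeding ``loop_overlap`` common genes into a
  pattern, its type's regulon targets, and the same type's condition-DEG
  set.

An effect of 0 disables the corresponding plant entirely (for the exclusive
markers, whose exclusivity is itself the effect, ``marker_effect = 0``
skips the plant); :meth:`SimulationConfig.null` zeroes every effect for
null simulations.  Everything is drawn from one seeded generator, so a
fixed seed reproduces the dataset bit for bit.

What this emulates — and what it does not: real dissociation data carry
doublets, ambient RNA, batch and donor effects, and continuous cell states;
none of those are modelled, so passing recovery tests demonstrates the
correctness of the scoring machinery, not robustness to such artefacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)
from . import io as scio

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "DEFAULT_CELL_TYPES",
    "generate",
    "write_fixture",
]

DEFAULT_CELL_TYPES = (
    "RPE",
    "endothelial",
    "fibroblast",
    "melanocyte",
    "Schwann",
    "macrophage",
    "mast_cell",
    "T_NK",
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults define the standard study conditions.

    Effects are on the natural-log scale: a planted gene's negative-binomial
    mean is multiplied by ``exp(effect)`` in the stratum it is planted in.
    """

    n_cell_types: int = 8
    cells_per_type_per_condition: int | Mapping[str, int] = 100
    n_genes: int = 2000
    conditions: tuple[str, str] = ("disease", "control")
    regions: tuple[str, str] = ("macula", "periphery")
    n_donors_per_condition: int = 2
    marker_effect: float = 2.0
    deg_effect: float = 1.4
    pattern_effect: float = 1.5
    regulon_effect: float = 2.0
    n_patterns: int = 8
    pattern_gene_size: int = 50
    n_regulons: int = 8
    regulon_size: int = 20
    n_disease_regulons: int = 2
    n_deg_genes: int = 20
    n_known_markers_per_type: int = 2
    loop_overlap: int = 15
    noise_dispersion: float = 2.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.6
    region_bias: Mapping[str, float] | None = None  # cell_type -> odds macula:periphery
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_cell_types": self.n_cell_types,
            "n_genes": self.n_genes,
            "pattern_gene_size": self.pattern_gene_size,
            "regulon_size": self.regulon_size,
            "n_deg_genes": self.n_deg_genes,
            "noise_dispersion": self.noise_dispersion,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive; got {v}")
        if self.loop_overlap > min(self.pattern_gene_size, self.regulon_size, self.n_deg_genes):
            raise ValueError(
                "loop_overlap exceeds min(pattern_gene_size, regulon_size, n_deg_genes)"
            )
        if self.n_patterns > self.n_cell_types or self.n_regulons > self.n_cell_types:
            raise ValueError("n_patterns and n_regulons cannot exceed n_cell_types")

    def cells_for(self, cell_type: str) -> int:
        if isinstance(self.cells_per_type_per_condition, Mapping):
            return int(self.cells_per_type_per_condition[cell_type])
        return int(self.cells_per_type_per_condition)

    def cell_type_names(self) -> list[str]:
        if self.n_cell_types <= len(DEFAULT_CELL_TYPES):
            return list(DEFAULT_CELL_TYPES[: self.n_cell_types])
        return [f"type_{i}" for i in range(self.n_cell_types)]

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """Configuration with every planted effect switched off."""
        base = dict(marker_effect=0.0, deg_effect=0.0, pattern_effect=0.0, regulon_effect=0.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery scoring."""

    planted_markers: dict[str, str]  # novel exclusive marker gene -> cell type
    known_markers: dict[str, list[str]]  # cell type -> marker genes
    planted_degs: dict[tuple[str, str], str]  # (gene, cell type) -> direction
    planted_patterns: dict[str, tuple[str, list[str]]]  # pattern -> (type, genes)
    planted_regulons: dict[str, dict]  # regulon -> {targets, active_types, active_conditions}
    planted_loops: list[tuple[str, str, str, str]]  # (pattern, regulon, deg_set, type)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_markers": self.planted_markers,
            "known_markers": self.known_markers,
            "planted_degs": [
                [g, t, d] for (g, t), d in sorted(self.planted_degs.items())
            ],
            "planted_patterns": {
                k: [t, sorted(gs)] for k, (t, gs) in self.planted_patterns.items()
            },
            "planted_regulons": {
                k: {
                    "targets": sorted(v["targets"]),
                    "active_types": v["active_types"],
                    "active_conditions": v["active_conditions"],
                }
                for k, v in self.planted_regulons.items()
            },
            "planted_loops": [list(t) for t in self.planted_loops],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class SimulatedDataset:
    expr: ExpressionMatrix
    ann: CellAnnotation
    known_markers: GeneSetCollection
    regulons: GeneSetCollection
    truth: GroundTruth
    config: SimulationConfig


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw: var = mu + mu^2 / dispersion; mean 0 stays 0."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(float)


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under ``config``; deterministic under its seed."""
    rng = np.random.default_rng(config.seed)
    types = config.cell_type_names()
    G = config.n_genes

    # -- gene bookkeeping: plants are carved from a disjoint leading block,
    #    except the deliberate loop overlaps
    needed_per_type = (
        1  # novel exclusive marker
        + config.n_known_markers_per_type
        + config.pattern_gene_size
        + (config.regulon_size - config.loop_overlap)
        + (config.n_deg_genes - config.loop_overlap)
    )
    needed = needed_per_type * config.n_cell_types + (
        config.n_disease_regulons * config.regulon_size
    )
    if needed > G:
        raise ValueError(
            f"planted structure needs {needed} genes but n_genes = {G}; "
            "reduce plant sizes or raise n_genes"
        )
    genes = [f"G{i:05d}" for i in range(G)]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor : cursor + n]
        cursor += n
        return block

    base_mean = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=G)
    n_cond = len(config.conditions)
    # multiplier per gene x type x condition, on top of the baseline mean
    mult = np.ones((G, config.n_cell_types, n_cond))
    gidx = {g: i for i, g in enumerate(genes)}

    truth_markers: dict[str, str] = {}
    known_markers: dict[str, list[str]] = {}
    truth_degs: dict[tuple[str, str], str] = {}
    truth_patterns: dict[str, tuple[str, list[str]]] = {}
    truth_regulons: dict[str, dict] = {}
    truth_loops: list[tuple[str, str, str, str]] = []
    exclusive_rows: list[tuple[int, int]] = []  # (gene row, owning type)

    for ti, t in enumerate(types):
        # exclusive novel marker (skipped entirely at zero effect)
        novel = take(1)[0]
        if config.marker_effect > 0:
            truth_markers[novel] = t
            mult[gidx[novel], ti, :] = np.exp(config.marker_effect) / base_mean[gidx[novel]]
            exclusive_rows.append((gidx[novel], ti))
        km = take(config.n_known_markers_per_type)
        known_markers[t] = km
        if config.marker_effect > 0:
            for g in km:
                mult[gidx[g], ti, :] *= np.exp(config.marker_effect)

        pattern_genes = take(config.pattern_gene_size)
        overlap = pattern_genes[: config.loop_overlap]
        regulon_genes = overlap + take(config.regulon_size - config.loop_overlap)
        deg_genes = overlap + take(config.n_deg_genes - config.loop_overlap)

        if ti < config.n_patterns and config.pattern_effect > 0:
            pname = f"program_{t}"
            truth_patterns[pname] = (t, list(pattern_genes))
            for g in pattern_genes:
                mult[gidx[g], ti, :] *= np.exp(config.pattern_effect)
        if ti < config.n_regulons and config.regulon_effect > 0:
            rname = f"TF_{t}"
            truth_regulons[rname] = {
                "targets": list(regulon_genes),
                "active_types": [t],
                "active_conditions": list(config.conditions),
            }
            for g in regulon_genes:
                mult[gidx[g], ti, :] *= np.exp(config.regulon_effect)
        if config.deg_effect > 0:
            for g in deg_genes:
                truth_degs[(g, t)] = "up"
                mult[gidx[g], ti, 0] *= np.exp(config.deg_effect)  # condition 0 = disease
        if (
            ti < min(config.n_patterns, config.n_regulons)
            and config.pattern_effect > 0
            and config.regulon_effect > 0
            and config.deg_effect > 0
        ):
            truth_loops.append((f"program_{t}", f"TF_{t}", t, t))

    # disease-only regulons: active solely in the disease stratum of a type
    for d in range(config.n_disease_regulons):
        ti = d % config.n_cell_types
        targets = take(config.regulon_size)
        rname = f"TF_disease_{types[ti]}_{d}"
        truth_regulons[rname] = {
            "targets": list(targets),
            "active_types": [types[ti]],
            "active_conditions": [config.conditions[0]],
        }
        if config.regulon_effect > 0:
            for g in targets:
                mult[gidx[g], ti, 0] *= np.exp(config.regulon_effect)

    # -- sample counts stratum by stratum
    columns: list[np.ndarray] = []
    rows: list[dict] = []
    for ti, t in enumerate(types):
        n_per = config.cells_for(t)
        for ci, cond in enumerate(config.conditions):
            mu = base_mean * mult[:, ti, ci]
            for ge, owner in exclusive_rows:
                if owner != ti:
                    mu[ge] = 0.0
            counts = np.column_stack(
                [_nb_counts(rng, mu, config.noise_dispersion) for _ in range(n_per)]
            )
            columns.append(counts)
            odds = (config.region_bias or {}).get(t)
            p_macula = 0.5 if odds is None else odds / (1.0 + odds)
            region_draw = rng.random(n_per) < p_macula
            donor_draw = rng.integers(config.n_donors_per_condition, size=n_per)
            for j in range(n_per):
                rows.append(
                    {
                        "cell_type": t,
                        "condition": cond,
                        "region": config.regions[0] if region_draw[j] else config.regions[1],
                        "donor": f"donor_{cond}_{donor_draw[j] + 1}",
                    }
                )
    counts = np.hstack(columns)
    cell_ids = [f"cell_{i:05d}" for i in range(counts.shape[1])]
    values = scio.normalize_counts(counts)
    expr = ExpressionMatrix(gene_ids=genes, cell_ids=cell_ids, values=values)
    ann = CellAnnotation(pd.DataFrame([{"cell_id": c, **r} for c, r in zip(cell_ids, rows)]))

    km_coll = GeneSetCollection(universe=frozenset(genes))
    for t, km in known_markers.items():
        km_coll.add(GeneSet(name=t, kind="known_marker", genes=frozenset(km)))
    reg_coll = GeneSetCollection(universe=frozenset(genes))
    for rname, spec_ in truth_regulons.items():
        reg_coll.add(
            GeneSet(name=rname, kind="regulon_targets", genes=frozenset(spec_["targets"]))
        )

    truth = GroundTruth(
        planted_markers=truth_markers,
        known_markers=known_markers,
        planted_degs=truth_degs,
        planted_patterns=truth_patterns,
        planted_regulons=truth_regulons,
        planted_loops=truth_loops,
    )
    return SimulatedDataset(
        expr=expr, ann=ann, known_markers=km_coll, regulons=reg_coll, truth=truth,
        config=config,
    )


def write_fixture(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Write the dataset as an MTX triplet, annotation TSV, GMTs and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scio.write_expression(
        ds.expr,
        out / "matrix.mtx",
        out / "genes.tsv",
        out / "barcodes.tsv",
        format="mtx",
    )
    scio.write_annotation(ds.ann, out / "annotations.tsv")
    scio.write_gmt(ds.known_markers, out / "known_markers.gmt")
    scio.write_gmt(ds.regulons, out / "regulons.gmt")
    ds.truth.to_json(out / "truth.json")
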