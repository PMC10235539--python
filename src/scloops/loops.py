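"""Cell-specific TF regulatory loops from pairwise gene-set enrichment.

Within each cell type, three families of gene sets — the selected
expression patterns (predictive power >= 0.7), the selected regulons and
the filtered DEG set — are tested pairwise across families for overlap
enrichment against the gene universe of the analyzed matrix.  The overlap
statistic is the hypergeometric upper tail

    P_loop = P(X >= k),   X ~ Hypergeometric(N, M, n)

with k the observed intersection, M and n the two set sizes and N the
universe size; the point mass C(M,k) C(N-M,n-k) / C(N,n) is exposed
separately as :func:`hypergeom_pmf`.  Edges are kept at P_loop < alpha
(strict, no multiple-testing correction by default — a BH option exists),
and a *ternary loop* is a (pattern, regulon, DEG set) triple of the same
cell type whose three pairwise edges are all kept.  Within-family pairs are
never tested.

Loop nodes can be annotated post hoc with user-supplied pathway gene sets
(e.g. ligand-receptor pathway memberships exported from a communication
analysis); the annotation is pure set membership.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .datatypes import GeneSet, GeneSetCollection

__all__ = [
    "LoopEdge",
    "TernaryLoop",
    "LoopGraph",
    "hypergeom_ploop",
    "hypergeom_pmf",
    "build_loops",
    "annotate_pathways",
    "export_graph",
    "read_edge_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoopEdge:
    """Pairwise overlap-enrichment edge between two gene-set nodes."""

    node_1: str
    node_2: str
    kind_1: str
    kind_2: str
    k_overlap: int
    p_loop: float
    universe_size: int


@dataclass(frozen=True)
class TernaryLoop:
    """A pattern, regulon and DEG set of one cell type, pairwise enriched."""

    pattern: str
    regulon: str
    deg_set: str
    cell_type: str
    disease_flag: bool
    edges: tuple[LoopEdge, LoopEdge, LoopEdge]


@dataclass
class LoopGraph:
    """Typed enrichment graph plus the extracted ternary loops."""

    graph: nx.Graph
    loops: list[TernaryLoop]
    alpha: float
    universe_size: int
    node_sets: dict[str, GeneSet] = field(default_factory=dict)
    pathway_fraction: float | None = None


def _check_params(k: int, M: int, n: int, N: int) -> None:
    if N < 0 or M < 0 or n < 0 or k < 0:
        raise ValueError("hypergeometric parameters must be non-negative")
    if M > N:
        raise ValueError(f"set size M={M} exceeds universe N={N}")
    if n > N:
        raise ValueError(f"set size n={n} exceeds universe N={N}")
    if k > min(M, n):
        raise ValueError(f"overlap k={k} exceeds min(M, n)={min(M, n)}")


def hypergeom_ploop(k: int, M: int, n: int, N: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeometric(N, M, n).

    Computed as a log-space sum of hypergeometric log point masses for
    numerical stability; returns exactly 1.0 at k = 0.  Symmetric in M and n.
    """
    _check_params(k, M, n, N)
    if k == 0:
        return 1.0
    ks = np.arange(k, min(M, n) + 1)
    if len(ks) == 0:
        return 1.0
    logp = hypergeom.logpmf(ks, N, M, n)
    return float(min(1.0, math.exp(logsumexp(logp))))


def hypergeom_pmf(k: int, M: int, n: int, N: int) -> float:
    """Exact hypergeometric point mass C(M,k) C(N-M,n-k) / C(N,n)."""
    _check_params(k, M, n, N)
    if n - k > N - M:
        return 0.0
    return math.comb(M, k) * math.comb(N - M, n - k) / math.comb(N, n)


def _node_id(gs: GeneSet) -> str:
    return f"{gs.kind}:{gs.name}"


def _edge_between(
    a: GeneSet, b: GeneSet, universe: frozenset[str], alpha: float
) -> LoopEdge | None:
    ga = a.genes & universe
    gb = b.genes & universe
    if not ga or not gb:
        return None
    k = len(ga & gb)
    p = hypergeom_ploop(k, len(ga), len(gb), len(universe))
    if p >= alpha:
        return None
    return LoopEdge(
        node_1=_node_id(a),
        node_2=_node_id(b),
        kind_1=a.kind,
        kind_2=b.kind,
        k_overlap=k,
        p_loop=p,
        universe_size=len(universe),
    )


def build_loops(
    patterns_by_type: Mapping[str, Sequence[GeneSet]],
    regulons_by_type: Mapping[str, Sequence[GeneSet]],
    deg_sets: Mapping[str, GeneSet],
    universe: frozenset[str] | set[str],
    alpha: float = 0.05,
    disease_flag: bool = False,
) -> LoopGraph:
    """Test all cross-family pairs within each cell type and extract loops.

    Inputs are the already-selected patterns and regulons per type and one
    filtered DEG set per type; ``universe`` is the gene universe of the
    analyzed matrix.  A type missing any family (or with an empty set)
    yields no loops, with a log note.  Edges with P_loop < alpha enter the
    graph; ternary loops require all three pairwise edges.
    """
    universe = frozenset(universe)
    graph = nx.Graph()
    loops: list[TernaryLoop] = []
    node_sets: dict[str, GeneSet] = {}
    types = sorted(set(patterns_by_type) | set(regulons_by_type) | set(deg_sets))
    for t in types:
        pats = [p for p in patterns_by_type.get(t, []) if len(p)]
        regs = [r for r in regulons_by_type.get(t, []) if len(r)]
        deg = deg_sets.get(t)
        degs = [deg] if deg is not None and len(deg) else []
        if not (pats and regs and degs):
            logger.info("cell type %r lacks a non-empty set family; no loops", t)
        pair_edges: dict[tuple[str, str], LoopEdge] = {}
        for fam_a, fam_b in (
            (pats, regs),
            (pats, degs),
            (regs, degs),
        ):
            for a, b in product(fam_a, fam_b):
                edge = _edge_between(a, b, universe, alpha)
                if edge is None:
                    continue
                pair_edges[(edge.node_1, edge.node_2)] = edge
                for gs in (a, b):
                    nid = _node_id(gs)
                    if nid not in node_sets:
                        node_sets[nid] = gs
                        graph.add_node(
                            nid, kind=gs.kind, name=gs.name, cell_type=t, size=len(gs)
                        )
                graph.add_edge(
                    edge.node_1,
                    edge.node_2,
                    k_overlap=edge.k_overlap,
                    p_loop=edge.p_loop,
                    cell_type=t,
                )
        for p, r, d in product(pats, regs, degs):
            e1 = pair_edges.get((_node_id(p), _node_id(r)))
            e2 = pair_edges.get((_node_id(p), _node_id(d)))
            e3 = pair_edges.get((_node_id(r), _node_id(d)))
            if e1 and e2 and e3:
                loops.append(
                    TernaryLoop(
                        pattern=p.name,
                        regulon=r.name,
                        deg_set=d.name,
                        cell_type=t,
                        disease_flag=disease_flag,
                        edges=(e1, e2, e3),
                    )
                )
    return LoopGraph(
        graph=graph,
        loops=loops,
        alpha=alpha,
        universe_size=len(universe),
        node_sets=node_sets,
    )


def annotate_pathways(
    loop_graph: LoopGraph,
    pathways: GeneSetCollection,
    min_overlap: int = 1,
) -> float:
    """Annotate loop nodes with the pathways they share genes with.

    Each node participating in a ternary loop gains a ``pathways`` attribute
    listing (semicolon-joined) every pathway sharing at least ``min_overlap``
    genes with it.  Returns — and records on the graph — the fraction of
    supplied pathways touched by any loop node.  An empty pathway collection
    is a no-op with a warning.
    """
    if len(pathways) == 0:
        logger.warning("empty pathway collection; nothing annotated")
        return 0.0
    loop_nodes = sorted(
        {f"pattern_top_genes:{lo.pattern}" for lo in loop_graph.loops}
        | {f"regulon_targets:{lo.regulon}" for lo in loop_graph.loops}
        | {f"deg_set:{lo.deg_set}" for lo in loop_graph.loops}
    )
    touched: set[str] = set()
    for nid in loop_nodes:
        gs = loop_graph.node_sets.get(nid)
        if gs is None:
            continue
        hits = sorted(
            pw.name for pw in pathways if len(pw.genes & gs.genes) >= min_overlap
        )
        touched.update(hits)
        if nid in loop_graph.graph:
            loop_graph.graph.nodes[nid]["pathways"] = ";".join(hits)
    fraction = len(touched) / len(pathways)
    loop_graph.pathway_fraction = fraction
    return fraction


def export_graph(loop_graph: LoopGraph, path: str | Path, format: str = "graphml") -> None:
    """Write the loop graph as GraphML or a TSV edge list.

    Node and edge ordering is deterministic (sorted node ids).
    """
    path = Path(path)
    g = loop_graph.graph
    ordered = nx.Graph()
    ordered.graph.update(g.graph)
    for n in sorted(g.nodes):
        ordered.add_node(n, **g.nodes[n])
    for u, v in sorted(tuple(sorted(e)) for e in g.edges):
        ordered.add_edge(u, v, **g.edges[u, v])
    if format == "graphml":
        nx.write_graphml(ordered, path)
    elif format == "edge_tsv":
        rows = [
            {
                "node_1": u,
                "node_2": v,
                "k_overlap": d["k_overlap"],
                "p_loop": d["p_loop"],
                "cell_type": d.get("cell_type", ""),
            }
            for u, v, d in ordered.edges(data=True)
        ]
        pd.DataFrame(
            rows, columns=["node_1", "node_2", "k_overlap", "p_loop", "cell_type"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"format must be graphml or edge_tsv, got {format!r}")


def read_edge_tsv(path: str | Path) -> pd.DataFrame:
    """Load an exported edge list (round-trip counterpart of export_graph)."""
    return pd.read_csv(path, sep="\t")


def loops_to_frame(loop_graph: LoopGraph) -> pd.DataFrame:
    """Ternary loops flattened for TSV export."""
    rows = []
    for lo in loop_graph.loops:
        rows.append(
            {
                "cell_type": lo.cell_type,
                "pattern": lo.pattern,
                "regulon": lo.regulon,
                "deg_set": lo.deg_set,
                "disease_flag": lo.disease_flag,
                "max_p_loop": max(e.p_loop for e in lo.edges),
                "min_k_overlap": min(e.k_overlap for e in lo.edges),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_type", "pattern", "regulon", "deg_set",
            "disease_flag", "max_p_loop", "min_k_overlap",
        ],
    )
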