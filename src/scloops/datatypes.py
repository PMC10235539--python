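"""Core containers shared by every stage of the pipeline.

The pipeline operates on a log-normalized gene-by-cell expression matrix, a
per-cell annotation table (cell type, disease condition, tissue region,
donor) and named gene sets (known markers, regulon target sets, pattern top
genes, DEG sets, pathways).  All containers validate their invariants at
construction time and fail naming the offending identifier; they never
repair silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "GeneSet",
    "GeneSetCollection",
    "GENE_SET_KINDS",
    "ANNOTATION_OPTIONAL_FIELDS",
]

GENE_SET_KINDS = frozenset(
    {"known_marker", "regulon_targets", "pattern_top_genes", "deg_set", "pathway"}
)

ANNOTATION_OPTIONAL_FIELDS = ("condition", "region", "donor")


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class ExpressionMatrix:
    """Log-normalized expression, genes as rows, cells as columns.

    ``values`` must be non-negative (log1p-normalized expression is); gene and
    cell identifiers must be unique.  Sparse input is densified at
    construction — every downstream score is rank- or fraction-based and
    dense arithmetic is the simpler substrate at the scales this package
    targets.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense(), dtype=float)
        else:
            self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene id: {dup!r}")
        dup = _first_duplicate(self.cell_ids)
        if dup is not None:
            raise ValueError(f"duplicate cell id: {dup!r}")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene: {gene!r}") from None

    def cell_index(self, cell: str) -> int:
        try:
            return self._cell_index[cell]
        except KeyError:
            raise KeyError(f"unknown cell: {cell!r}") from None

    def cell_indices(self, cells: Iterable[str]) -> np.ndarray:
        return np.array([self.cell_index(c) for c in cells], dtype=int)

    def subset_cells(self, cells: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to ``cells`` (a boolean mask or id list)."""
        arr = np.asarray(cells)
        if arr.dtype == bool:
            if arr.shape != (self.n_cells,):
                raise ValueError("boolean cell mask has wrong length")
            idx = np.flatnonzero(arr)
        else:
            idx = self.cell_indices(arr)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
        )

    def expressed(self, threshold: float = 0.0) -> np.ndarray:
        """Boolean genes x cells detection matrix (value strictly above threshold)."""
        return self.values > threshold

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class CellAnnotation:
    """Per-cell labels: cell type plus optional condition, region and donor.

    Backed by a DataFrame with one row per cell.  Missing optional columns
    collapse to a single ``"unspecified"`` level so stratified operations stay
    well defined.
    """

    df: pd.DataFrame

    MANDATORY = ("cell_id", "cell_type")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.MANDATORY:
            if col not in df.columns:
                raise ValueError(f"annotation is missing mandatory column {col!r}")
        for col in ANNOTATION_OPTIONAL_FIELDS:
            if col not in df.columns:
                df[col] = "unspecified"
        for col in ("cell_id", "cell_type", *ANNOTATION_OPTIONAL_FIELDS):
            df[col] = df[col].astype(str)
        dup = _first_duplicate(df["cell_id"].tolist())
        if dup is not None:
            raise ValueError(f"duplicate cell id in annotation: {dup!r}")
        if len(df) == 0:
            raise ValueError("annotation table is empty")
        self.df = df.reset_index(drop=True)
        self._row = {c: i for i, c in enumerate(self.df["cell_id"])}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> list[str]:
        return self.df["cell_id"].tolist()

    def levels(self, fld: str = "cell_type") -> list[str]:
        """Distinct values of ``fld`` in first-appearance order."""
        return list(dict.fromkeys(self.df[fld]))

    def labels_for(self, cell_ids: Sequence[str], fld: str = "cell_type") -> np.ndarray:
        """Label of ``fld`` for each cell id, in the given order."""
        out = []
        for c in cell_ids:
            try:
                out.append(self.df.at[self._row[c], fld])
            except KeyError:
                raise KeyError(f"cell {c!r} missing from annotation") from None
        return np.array(out, dtype=object)

    def subset(self, cell_ids: Sequence[str]) -> "CellAnnotation":
        rows = [self._row[c] if c in self._row else None for c in cell_ids]
        missing = [c for c, r in zip(cell_ids, rows) if r is None]
        if missing:
            raise KeyError(f"cell {missing[0]!r} missing from annotation")
        return CellAnnotation(self.df.iloc[[r for r in rows if r is not None]])

    def mask(self, fld: str, level: str, cell_ids: Sequence[str]) -> np.ndarray:
        return self.labels_for(cell_ids, fld) == level


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a role tag.

    ``kind`` records how the set entered the analysis (known marker list,
    regulon target set, pattern top genes, DEG set or pathway); the loop
    construction pairs sets across kinds, never within one.
    """

    name: str
    kind: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in GENE_SET_KINDS:
            raise ValueError(
                f"unknown gene-set kind {self.kind!r}; expected one of "
                f"{sorted(GENE_SET_KINDS)}"
            )
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def overlap(self, other: "GeneSet | frozenset[str] | set[str]") -> frozenset[str]:
        other_genes = other.genes if isinstance(other, GeneSet) else frozenset(other)
        return self.genes & other_genes


@dataclass
class GeneSetCollection:
    """Named map of gene sets with an optional explicit gene universe."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"set stored under {name!r} is named {gs.name!r}")
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate gene-set name: {gs.name!r}")
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        try:
            return self.sets[name]
        except KeyError:
            raise KeyError(f"unknown gene set: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def of_kind(self, kind: str) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: s for n, s in self.sets.items() if s.kind == kind}, self.universe
        )
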