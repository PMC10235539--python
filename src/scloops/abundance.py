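"""Cell-type abundance across conditions (ACT).

ACT is the observed/expected enrichment ratio of a cell type within a
condition level:

    ACT(c, k) = (n_{c,k} / n_k) / (n_c / n_total)

i.e. the proportion of type *c* among condition-*k* cells over its overall
proportion.  ACT > 1 (strict) means the type is enriched under that
condition.  The ratio satisfies a weighted-mean conservation: for every
type, sum_k ACT(c,k) * n_k / n_total = 1.

Raw pooled ratios are reported with the underlying contingency table so
users can judge small-count stability themselves; no shrinkage or
continuity correction is applied, and no significance test (stratify by
donor via ``condition_field="donor"`` to inspect per-donor behaviour).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CellAnnotation

__all__ = ["ACTTable", "compute_act", "act_ratio", "enrichment_calls"]

logger = logging.getLogger(__name__)


@dataclass
class ACTTable:
    """ACT ratios (cell types x condition levels) with their cell counts.

    ``counts`` may be None when the table was assembled from published ACT
    values rather than from an annotation; the conservation invariant is
    validated whenever counts are present.
    """

    act: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts is not None:
            n_k = self.counts.sum(axis=0)
            n_total = float(n_k.sum())
            recon = (self.act * n_k).sum(axis=1) / n_total
            if not np.allclose(recon, 1.0, atol=1e-12):
                raise ValueError("ACT table violates weighted-mean conservation")

    @property
    def cell_types(self) -> list[str]:
        return list(self.act.index)

    @property
    def levels(self) -> list[str]:
        return list(self.act.columns)


def compute_act(ann: CellAnnotation, condition_field: str = "condition") -> ACTTable:
    """ACT of every cell type across the levels of ``condition_field``.

    Requires at least two levels.  A type absent from some level gets
    ACT = 0 there (with a warning); levels are defined by presence in the
    annotation so no level can have zero cells.
    """
    if condition_field not in ("condition", "region", "donor"):
        raise ValueError(f"condition_field must be condition/region/donor, got {condition_field!r}")
    counts = pd.crosstab(ann.df["cell_type"], ann.df[condition_field])
    counts = counts.loc[ann.levels("cell_type"), ann.levels(condition_field)]
    if counts.shape[1] < 2:
        raise ValueError(
            f"ACT needs at least two levels of {condition_field!r}; found {counts.shape[1]}"
        )
    n_k = counts.sum(axis=0).astype(float)
    n_c = counts.sum(axis=1).astype(float)
    n_total = float(n_k.sum())
    act = (counts / n_k) / (n_c / n_total).to_numpy()[:, None]
    if (counts == 0).any().any():
        for c, k in zip(*np.where(counts.to_numpy() == 0)):
            logger.warning(
                "cell type %r absent from %s level %r; ACT = 0 there",
                counts.index[c], condition_field, counts.columns[k],
            )
    return ACTTable(act=act.astype(float), counts=counts)


def act_ratio(table: ACTTable, cell_type: str, level_a: str, level_b: str) -> float:
    """Fold difference ACT(c, a) / ACT(c, b) between two condition levels."""
    try:
        a = float(table.act.at[cell_type, level_a])
        b = float(table.act.at[cell_type, level_b])
    except KeyError as exc:
        raise KeyError(f"unknown cell type or level: {exc}") from None
    if b == 0:
        logger.warning("ACT(%s, %s) is zero; ratio reported as infinity", cell_type, level_b)
        return math.inf
    return a / b


def enrichment_calls(table: ACTTable) -> pd.DataFrame:
    """Boolean table: enriched iff ACT strictly exceeds 1."""
    return table.act > 1.0
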