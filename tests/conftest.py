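import numpy as np
import pandas as pd
import pytest

import scloops as sl
from scloops.simulate import SimulationConfig, generate


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced-scale study: 4 types x 2 conditions x 30 cells, 400 genes."""
    base = dict(
        n_cell_types=4,
        cells_per_type_per_condition=30,
        n_genes=400,
        n_patterns=4,
        n_regulons=4,
        pattern_gene_size=20,
        regulon_size=10,
        loop_overlap=6,
        n_deg_genes=10,
        n_disease_regulons=1,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config(seed=0))


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return sl.run_pipeline(dataset=small_dataset, nmf_k=6)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw at the generator's standard study conditions."""
    return generate(SimulationConfig(seed=1))


def make_expr(values, gene_ids=None, cell_ids=None) -> sl.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return sl.ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        cell_ids=cell_ids or [f"c{j}" for j in range(c)],
        values=values,
    )


def make_ann(cell_types, conditions=None, cell_ids=None) -> sl.CellAnnotation:
    n = len(cell_types)
    df = pd.DataFrame(
        {
            "cell_id": cell_ids or [f"c{j}" for j in range(n)],
            "cell_type": cell_types,
        }
    )
    if conditions is not None:
        df["condition"] = conditions
    return sl.CellAnnotation(df)
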