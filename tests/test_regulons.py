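import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scloops as sl
from scloops.regulons import (
    RegulonActivity,
    compute_ras,
    compute_rss,
    jsd,
    ras_zscore,
    rss_condition_fold_change,
    select_regulons,
)

from conftest import make_ann, make_expr


def _regulon(name, genes):
    coll = sl.GeneSetCollection()
    coll.add(sl.GeneSet(name=name, kind="regulon_targets", genes=frozenset(genes)))
    return coll


def _ranked_cell_expr(n_genes):
    """One cell whose gene ranking is exactly g0 > g1 > ... (no ties)."""
    vals = np.arange(n_genes, 0, -1, dtype=float).reshape(-1, 1)
    return make_expr(vals)


class TestRAS:
    def test_targets_at_top_give_one(self):
        expr = _ranked_cell_expr(100)  # threshold = 5
        ras = compute_ras(expr, _regulon("r", [f"g{i}" for i in range(5)]))
        assert ras.iloc[0, 0] == 1.0

    def test_targets_below_threshold_give_zero(self):
        expr = _ranked_cell_expr(100)
        ras = compute_ras(expr, _regulon("r", [f"g{i}" for i in range(50, 55)]))
        assert ras.iloc[0, 0] == 0.0

    def test_interleaved_targets_step_area(self):
        # targets at ranks 2,4,6,8,10; threshold 10 of 200 genes
        expr = _ranked_cell_expr(200)
        ras = compute_ras(expr, _regulon("r", ["g1", "g3", "g5", "g7", "g9"]))
        assert ras.iloc[0, 0] == pytest.approx(25 / 40)

    def test_matches_brute_force_recovery_curve(self):
        """Independent oracle: walk the ranking, accumulate the step curve."""
        rng = np.random.default_rng(0)
        values = rng.poisson(1.5, size=(200, 8)).astype(float)
        expr = make_expr(values)
        targets = [f"g{i}" for i in rng.choice(200, size=12, replace=False)]
        ras = compute_ras(expr, _regulon("r", targets), top_fraction=0.05)
        threshold = 10  # ceil(0.05 * 200)
        tset = set(targets)
        for c in range(8):
            perm = np.random.default_rng(c).permutation(200)
            order = sorted(range(200), key=lambda g: (-values[g, c], perm[g]))
            hits, area = 0, 0
            for r in range(threshold):
                if expr.gene_ids[order[r]] in tset:
                    hits += 1
                area += hits
            gmax = min(len(targets), threshold)
            max_area = sum(min(r + 1, gmax) for r in range(threshold))
            assert ras.iloc[0, c] == pytest.approx(area / max_area)

    def test_regulon_absent_from_matrix_is_missing(self, caplog):
        expr = _ranked_cell_expr(20)
        with caplog.at_level("WARNING"):
            ras = compute_ras(expr, _regulon("r", ["nope"]))
        assert ras.isna().all().all()
        assert "no genes" in caplog.text

    def test_bad_top_fraction(self):
        expr = _ranked_cell_expr(20)
        with pytest.raises(ValueError, match="top_fraction"):
            compute_ras(expr, _regulon("r", ["g0"]), top_fraction=1.5)


class TestRSS:
    def test_identical_distributions_score_one(self):
        ras = pd.DataFrame([[0.25, 0.25, 0.25, 0.25, 0, 0, 0, 0]],
                           index=["r"], columns=[f"c{i}" for i in range(8)])
        ann = make_ann(["A"] * 4 + ["B"] * 4)
        rss = compute_rss(ras, ann)
        assert rss.at["r", "A"] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_vs_half_support_closed_form(self):
        ras = pd.DataFrame([[1 / 8] * 8], index=["r"], columns=[f"c{i}" for i in range(8)])
        ann = make_ann(["A"] * 4 + ["B"] * 4)
        rss = compute_rss(ras, ann)
        assert rss.at["r", "A"] == pytest.approx(1 - 0.31128, abs=1e-4)

    def test_disjoint_support_scores_zero(self):
        ras = pd.DataFrame([[0, 0, 0, 0, 0.25, 0.25, 0.25, 0.25]],
                           index=["r"], columns=[f"c{i}" for i in range(8)])
        ann = make_ann(["A"] * 4 + ["B"] * 4)
        rss = compute_rss(ras, ann)
        assert rss.at["r", "A"] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_row_undefined_with_warning(self, caplog):
        ras = pd.DataFrame([[0.0] * 4], index=["r"], columns=[f"c{i}" for i in range(4)])
        ann = make_ann(["A"] * 2 + ["B"] * 2)
        with caplog.at_level("WARNING"):
            rss = compute_rss(ras, ann)
        assert rss.loc["r"].isna().all()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=12))
    def test_jsd_symmetric_bounded(self, raw):
        p = np.array(raw)
        p /= p.sum()
        rng = np.random.default_rng(len(raw))
        q = rng.dirichlet(np.ones(len(raw)))
        assert jsd(p, q) == pytest.approx(jsd(q, p), abs=1e-12)
        assert 0.0 <= jsd(p, q) <= 1.0 + 1e-12


class TestSelection:
    def _activity(self, rss, z, fc=None):
        idx, cols = ["r"], ["A", "B", "C"]
        return RegulonActivity(
            ras=pd.DataFrame(np.zeros((1, 3)), index=idx, columns=["c0", "c1", "c2"]),
            rss=pd.DataFrame([rss], index=idx, columns=cols),
            zscore=pd.DataFrame([z], index=idx, columns=cols),
            rss_log2fc=pd.DataFrame([fc], index=idx, columns=cols) if fc else None,
        )

    def test_rss_gate_blocks_high_z(self):
        act = self._activity([0.09, 0.05, 0.02], [5.0, -1.0, -1.0])
        assert select_regulons(act, "cell_specific") == {"A": [], "B": [], "C": []}

    def test_joint_gate_selects(self):
        act = self._activity([0.45, 0.05, 0.02], [2.3, -1.0, -1.0])
        assert select_regulons(act, "cell_specific")["A"] == ["r"]

    def test_disease_mode_log2fc_gate(self):
        act = self._activity([0.4, 0.4, 0.4], [0.0, 0.0, 0.0], fc=[2.0, 0.5, -0.9])
        sel = select_regulons(act, "disease")
        assert sel == {"A": ["r"], "B": [], "C": []}

    def test_too_few_types_for_zscore(self):
        act = RegulonActivity(
            ras=pd.DataFrame(np.zeros((1, 2)), index=["r"], columns=["c0", "c1"]),
            rss=pd.DataFrame([[0.5, 0.5]], index=["r"], columns=["A", "B"]),
            zscore=pd.DataFrame([[0.0, 0.0]], index=["r"], columns=["A", "B"]),
        )
        with pytest.raises(ValueError, match="3 cell types"):
            select_regulons(act, "cell_specific")


class TestConditionFoldChange:
    def test_identical_conditions_score_zero(self):
        # same deterministic expression in both conditions
        vals = np.tile(np.arange(30, 0, -1, dtype=float).reshape(-1, 1), (1, 8))
        expr = make_expr(vals)
        ann = make_ann(["A", "B"] * 4, conditions=["x"] * 4 + ["y"] * 4)
        fc = rss_condition_fold_change(expr, _regulon("r", ["g0", "g1"]), ann)
        assert np.allclose(fc.to_numpy(dtype=float), 0.0)

    def test_zero_denominator_hits_sentinel(self):
        # targets (g0, g1) top-ranked in type-A cells under condition x, but
        # active only in type-B cells under y: RSS_y(A) = 0 -> +clip sentinel
        filler = np.arange(38, 0, -1, dtype=float) * 0.01
        on = np.concatenate([[10.0, 10.0], filler * 0])
        off = np.concatenate([[0.0, 0.0], filler])
        cols = [on] * 3 + [off] * 3 + [off] * 3 + [on] * 3
        expr = make_expr(np.column_stack(cols))
        ann = make_ann(["A", "A", "A", "B", "B", "B"] * 2,
                       conditions=["x"] * 6 + ["y"] * 6)
        fc = rss_condition_fold_change(expr, _regulon("r", ["g0", "g1"]), ann)
        assert fc.at["r", "A"] == 10.0
        assert fc.at["r", "B"] == -10.0

    def test_planted_disease_regulon_exceeds_gate(self, small_result):
        truth = small_result.dataset.truth.planted_regulons
        fc = small_result.activity.rss_log2fc
        for name, v in truth.items():
            if v["active_conditions"] == ["disease"]:
                t = v["active_types"][0]
                assert fc.at[name, t] > 1.0


def test_planted_regulons_peak_at_their_type(small_result):
    truth = small_result.dataset.truth.planted_regulons
    rss = small_result.activity.rss
    for name, v in truth.items():
        if set(v["active_conditions"]) == {"disease", "control"}:
            assert rss.loc[name].idxmax() == v["active_types"][0]


def test_zscore_flags_single_active_type():
    # one active type among 8: z = sqrt(7) against the population sd
    ras = pd.DataFrame(
        [[0.8, 0.8] + [0.05] * 14], index=["r"], columns=[f"c{i}" for i in range(16)]
    )
    ann = make_ann([t for t in "ABCDEFGH" for _ in range(2)])
    z = ras_zscore(ras, ann)
    assert z.at["r", "A"] == pytest.approx(np.sqrt(7), abs=1e-9)
    assert z.at["r", "A"] >= 2.0
    assert (z.loc["r"].drop("A") < 0).all()
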