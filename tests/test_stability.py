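"""Rank tensor machinery: rank conversion, aggregation, stability, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata

from pcspanel.models import gene_importance, tune_and_fit
from pcspanel.prediction_check import make_splits
from pcspanel.preprocess import default_pipeline_set
from pcspanel.stability import (
    GenePanel,
    NoStableGenesError,
    RankTensor,
    aggregate_ranks,
    build_rank_tensor,
    ranks_from_importance,
    select_panel,
    stability_summary,
)


def random_tensor(p=2, m=3, r=4, g=10, seed=0) -> RankTensor:
    rng = np.random.default_rng(seed)
    vals = np.empty((p, m, r, g))
    for idx in np.ndindex(p, m, r):
        vals[idx] = rng.permutation(g) + 1.0
    return RankTensor(vals, [f"pipe{i}" for i in range(p)],
                      [f"model{j}" for j in range(m)],
                      [f"G{k:02d}" for k in range(g)])


class TestRanksFromImportance:
    def test_descending_scores(self):
        imp = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0})
        assert ranks_from_importance(imp).tolist() == [1.0, 2.0, 3.0]

    def test_average_tie_convention(self):
        imp = pd.Series({"a": 5.0, "b": 5.0, "c": 1.0})
        assert ranks_from_importance(imp).tolist() == [1.5, 1.5, 3.0]

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=54))
    def test_rank_sum_conserved(self, scores):
        g = len(scores)
        ranks = ranks_from_importance(pd.Series(scores))
        assert ranks.sum() == pytest.approx(g * (g + 1) / 2)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ranks_from_importance(pd.Series(dtype=float))
        with pytest.raises(ValueError):
            ranks_from_importance(pd.Series([1.0, np.nan]))


class TestBuildTensor:
    def test_single_combination_equals_direct_ranking(self, tiny_cohort, cheap_specs):
        cohort, _ = tiny_cohort
        plan = make_splits(cohort.n_samples, cohort.outcome, n_repeats=1,
                           inner_folds=3, seed=0)
        pipe = default_pipeline_set()[0]
        spec = cheap_specs["ridge-logistic"]
        tensor = build_rank_tensor(cohort, [pipe], [spec], plan,
                                   tune_folds=3, seed=0)
        assert tensor.values.shape == (1, 1, 1, 12)

        dev = plan.splits[0][0]
        fitted_pipe = pipe.fit(cohort.ct.subset_rows(dev))
        expr = fitted_pipe.transform(cohort.ct.subset_rows(dev))
        clin = cohort.clinical.drop(columns=["prostate_volume"]).iloc[dev].astype(float)
        clin.index = expr.index
        X = pd.concat([expr, clin], axis=1)
        model = tune_and_fit(spec, X, cohort.outcome[dev], seed=0, cv_folds=3)
        imp = gene_importance(model, cohort.ct.candidate_genes)
        expected = ranks_from_importance(imp).to_numpy()
        np.testing.assert_allclose(tensor.values[0, 0, 0], expected)

    def test_every_combination_is_a_tied_permutation(self, tiny_cohort, cheap_specs):
        cohort, _ = tiny_cohort
        plan = make_splits(cohort.n_samples, cohort.outcome, n_repeats=2,
                           inner_folds=3, seed=1)
        tensor = build_rank_tensor(
            cohort, default_pipeline_set()[:2],
            [cheap_specs["ridge-logistic"], cheap_specs["lasso-logistic"]],
            plan, tune_folds=3, seed=1,
        )
        g = len(tensor.genes)
        sums = tensor.flat().sum(axis=1)
        np.testing.assert_allclose(sums, g * (g + 1) / 2)


class TestAggregate:
    def test_constant_tensor_all_modes_agree(self):
        g = 6
        ranking = np.arange(1.0, g + 1)
        vals = np.tile(ranking, (2, 3, 4, 1))
        t = RankTensor(vals, ["p0", "p1"], ["m0", "m1", "m2"],
                       [f"G{k}" for k in range(g)])
        np.testing.assert_allclose(aggregate_ranks(t, "pcs_ensembled"), ranking)
        me = aggregate_ranks(t, "model_ensembled")
        for col in me.columns:
            np.testing.assert_allclose(me[col], ranking)
        ms = aggregate_ranks(t, "model_specific")
        for col in ms.columns:
            np.testing.assert_allclose(ms[col], ranking)

    def test_two_gene_symmetry(self):
        vals = np.array([[[[1.0, 2.0]]], [[[2.0, 1.0]]]])  # two combos, flipped
        t = RankTensor(vals, ["p0", "p1"], ["m0"], ["A", "B"])
        agg = aggregate_ranks(t, "pcs_ensembled")
        assert agg.tolist() == [1.5, 1.5]

    def test_brute_force_oracle(self):
        t = random_tensor(p=3, m=2, r=5, g=8, seed=3)
        p, m, r, g = t.values.shape
        # explicit loops
        pcs = np.zeros(g)
        for i in range(p):
            for j in range(m):
                for k in range(r):
                    pcs += t.values[i, j, k]
        pcs /= p * m * r
        np.testing.assert_allclose(aggregate_ranks(t, "pcs_ensembled"), pcs)
        me = aggregate_ranks(t, "model_ensembled")
        for i in range(p):
            acc = np.zeros(g)
            for j in range(m):
                for k in range(r):
                    acc += t.values[i, j, k]
            np.testing.assert_allclose(me.iloc[:, i], acc / (m * r))

    def test_pcs_mean_is_combination_weighted_mean_of_model_ensembled(self):
        t = random_tensor(p=4, m=3, r=6, g=12, seed=4)
        pcs = aggregate_ranks(t, "pcs_ensembled")
        me = aggregate_ranks(t, "model_ensembled")
        np.testing.assert_allclose(pcs, me.mean(axis=1))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            aggregate_ranks(random_tensor(), "grand_ensembled")


class TestStabilitySummary:
    def test_constant_tensor_zero_sd(self):
        g = 5
        vals = np.tile(np.arange(1.0, g + 1), (2, 2, 3, 1))
        t = RankTensor(vals, ["p0", "p1"], ["m0", "m1"], [f"G{k}" for k in range(g)])
        s = stability_summary(t, top_m=(3,))
        assert (s["rank_sd"] == 0.0).all()

    def test_half_and_half_proportion(self):
        vals = np.empty((1, 1, 4, 12))
        a = np.arange(1.0, 13.0)
        b = a.copy()
        b[0], b[10] = 11.0, 1.0  # gene 0 ranked 1 twice and 11 twice
        vals[0, 0, 0] = vals[0, 0, 1] = a
        vals[0, 0, 2] = vals[0, 0, 3] = b
        t = RankTensor(vals, ["p"], ["m"], [f"G{k}" for k in range(12)])
        s = stability_summary(t, top_m=(10,))
        assert s.loc["G0", "prop_top10"] == 0.5

    def test_brute_force_oracle_54_genes(self):
        t = random_tensor(p=2, m=3, r=4, g=54, seed=5)
        s = stability_summary(t, top_m=(5, 10, 17))
        flat = t.values.reshape(-1, 54)
        for k, gene in enumerate(t.genes):
            col = flat[:, k]
            assert s.loc[gene, "mean_rank"] == pytest.approx(col.mean())
            assert s.loc[gene, "rank_sd"] == pytest.approx(col.std(ddof=0))
            for m in (5, 10, 17):
                assert s.loc[gene, f"prop_top{m}"] == pytest.approx(
                    (col <= m).mean()
                )


def summary_from(mean_rank, prop_top10):
    return pd.DataFrame(
        {"mean_rank": mean_rank, "rank_sd": 0.0, "prop_top10": prop_top10},
        index=[f"G{k:02d}" for k in range(len(mean_rank))],
    )


class TestSelectPanel:
    def test_six_stable_genes_give_seven_measured(self):
        s = summary_from(
            mean_rank=[2, 3, 4, 5, 6, 7] + [20] * 6,
            prop_top10=[0.95] * 6 + [0.1] * 6,
        )
        panel = select_panel(s, reference_gene="KLK3")
        assert len(panel.genes) == 6
        assert panel.measured_genes == 7
        assert panel.reference_gene == "KLK3"

    def test_deterministic_tensor_selects_top_genes_by_rank(self):
        g = 20
        vals = np.tile(np.arange(1.0, g + 1), (1, 1, 2, 1))
        t = RankTensor(vals, ["p"], ["m"], [f"G{k:02d}" for k in range(g)])
        s = stability_summary(t)
        panel = select_panel(s, reference_gene="KLK3", max_mean_rank=10)
        # strict inequality: ranks 1..9 qualify
        assert panel.genes == [f"G{k:02d}" for k in range(9)]

    def test_loosening_prop_threshold_never_removes_genes(self):
        rng = np.random.default_rng(6)
        s = summary_from(rng.uniform(1, 20, 15), rng.uniform(0, 1, 15))
        prev: set = set()
        for thresh in (0.9, 0.7, 0.5, 0.3, 0.0):
            try:
                panel = select_panel(s, "KLK3", min_prop_top10=thresh)
                got = set(panel.genes)
            except NoStableGenesError:
                got = set()
            assert prev <= got
            prev = got

    def test_empty_selection_signals(self):
        s = summary_from([30, 40], [0.0, 0.0])
        with pytest.raises(NoStableGenesError):
            select_panel(s, "KLK3")

    def test_borderline_gene_yields_extended_panel(self):
        s = summary_from([2, 3, 9.5, 25], [0.9, 0.85, 0.68, 0.05])
        panel = select_panel(s, "KLK3", borderline_slack=0.05)
        assert panel.genes == ["G00", "G01"]
        assert panel.extended == ["G00", "G01", "G02"]

    def test_reference_gene_cannot_be_selected(self):
        with pytest.raises(ValueError):
            GenePanel(genes=["KLK3", "G01"], reference_gene="KLK3")
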