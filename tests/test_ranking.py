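"""Assessment pipeline: the HasseRanking estimator, level summaries,
bivariate rank table, and the PCA overview."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from greenrank.data import ProcedureTable, VariableSpec
from greenrank.exceptions import ValidationError
from greenrank.ranking import (
    HasseRanking,
    PipelineStageError,
    bivariate_rank_table,
    level_summary,
    pca_overview,
    rank_procedures,
)
from greenrank.simulate import (
    GeneratorConfig,
    generate_correlated_table,
    plant_poset_table,
    random_poset,
)


@pytest.fixture(scope="module")
def synthetic_table():
    """A complete 26-procedure table with all 11 variables."""
    return generate_correlated_table(GeneratorConfig(n_procedures=26, seed=7))


class TestHasseRankingEstimator:
    def test_sklearn_params_round_trip(self):
        est = HasseRanking(role="metrological", n_samples=500, random_state=3)
        params = est.get_params()
        assert params["role"] == "metrological"
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_exposes_structural_attributes(self, synthetic_table):
        est = HasseRanking(role="environmental", random_state=1).fit(
            synthetic_table
        )
        assert est.height_ == max(est.summary_.levels.values())
        assert est.isolated_ <= est.maximal_ & est.minimal_
        assert len(est.average_ranks_) == synthetic_table.n_procedures
        assert est.height_ * est.width_ >= est.diagram_.n_objects

    def test_fit_predict_returns_ranks(self, synthetic_table):
        ranks = HasseRanking(role="metrological",
                             random_state=2).fit_predict(synthetic_table)
        n = len(ranks)
        assert ranks.sum() == pytest.approx(n * (n + 1) / 2)

    def test_identical_rows_collapse_to_one_level(self):
        df = pd.DataFrame(
            {"lod": [1.0] * 4, "precision": [5.0] * 4,
             "recovery": [95.0] * 4},
            index=range(1, 5),
        )
        schema = (
            VariableSpec("lod", role="metrological"),
            VariableSpec("precision", role="metrological"),
            VariableSpec("recovery", role="metrological",
                         orientation="target_100"),
        )
        est = HasseRanking(role="metrological").fit(
            ProcedureTable(df, schema)
        )
        assert est.diagram_.n_objects == 1
        assert est.height_ == 1
        assert set(est.levels_.index) == {1, 2, 3, 4}
        assert set(est.levels_) == {1}

    def test_stage_errors_are_labelled(self):
        df = pd.DataFrame({"lod": [1.0, np.nan]}, index=[1, 2])
        table = ProcedureTable(df, (VariableSpec("lod", role="metrological"),))
        est = HasseRanking(variables=["precision"])
        with pytest.raises(PipelineStageError, match="validate_completeness"):
            est.fit(table)

    def test_pipeline_is_deterministic(self, synthetic_table):
        r1 = rank_procedures(synthetic_table, role="environmental", seed=4)
        r2 = rank_procedures(synthetic_table, role="environmental", seed=4)
        pd.testing.assert_series_equal(r1.average_ranks, r2.average_ranks)
        assert r1.summary == r2.summary

    def test_include_scores_toggle_extends_basis(self, synthetic_table):
        with_scores = HasseRanking(role="environmental", include_scores=True,
                                   random_state=1).fit(synthetic_table)
        without = HasseRanking(role="environmental",
                               random_state=1).fit(synthetic_table)
        assert set(without.variable_set_) < set(with_scores.variable_set_)
        # adding variables can only remove comparabilities
        assert set(with_scores.diagram_.order) <= set(without.diagram_.order)

    def test_zero_noise_planted_order_is_recovered(self):
        planted = random_poset(8, 0.3, seed=41)
        table = plant_poset_table(planted, n_variables=6, noise_sd=0.0, seed=1)
        est = HasseRanking(variables=table.variable_names).fit(table)
        assert set(est.diagram_.covers) == set(planted.covers)


class TestLevelSummary:
    def test_level_means_and_isolated_group(self, synthetic_table):
        result = rank_procedures(synthetic_table, role="environmental", seed=4)
        scores = synthetic_table.values["eco_scale"]
        summary = level_summary(result, scores)
        iso = set(summary.isolated_members)
        for level, members in summary.members.items():
            assert iso.isdisjoint(members)
            expected = scores.loc[list(members)].mean()
            assert summary.per_level_mean_score[level] == pytest.approx(expected)
        if iso:
            assert summary.isolated_mean_score == pytest.approx(
                scores.loc[sorted(iso)].mean()
            )

    def test_level_means_recombine_to_overall_mean(self, synthetic_table):
        result = rank_procedures(synthetic_table, role="environmental", seed=4)
        scores = synthetic_table.values["eco_scale"]
        summary = level_summary(result, scores)
        weighted = sum(
            summary.per_level_mean_score[lv] * len(members)
            for lv, members in summary.members.items()
        )
        non_isolated = [
            pid for members in summary.members.values() for pid in members
        ]
        assert weighted / len(non_isolated) == pytest.approx(
            scores.loc[non_isolated].mean()
        )

    def test_single_level_mean_is_overall_mean(self):
        df = pd.DataFrame({"lod": [1.0, 1.0, 1.0]}, index=[1, 2, 3])
        table = ProcedureTable(df, (VariableSpec("lod"),))
        result = rank_procedures(table, variables=["lod"], seed=0)
        summary = level_summary(result, {1: 10.0, 2: 20.0, 3: 30.0})
        # a lone equivalence class is comparable to nothing, hence
        # isolated: the whole table is summarised as the isolated group,
        # whose mean is the overall mean
        assert summary.per_level_mean_score == {}
        assert summary.isolated_mean_score == pytest.approx(20.0)
        assert set(summary.isolated_members) == {1, 2, 3}

    def test_missing_scores_reported_not_imputed(self, synthetic_table):
        result = rank_procedures(synthetic_table, role="environmental", seed=4)
        scores = synthetic_table.values["eco_scale"].drop(index=[1, 2])
        summary = level_summary(result, scores)
        assert set(summary.missing_score_ids) == {1, 2}


class TestBivariateRankTable:
    def test_join_and_pareto_on_synthetic_table(self, synthetic_table):
        env = rank_procedures(synthetic_table, role="environmental", seed=4)
        met = rank_procedures(synthetic_table, role="metrological", seed=5)
        biv = bivariate_rank_table(env, met)
        assert len(biv) == synthetic_table.n_procedures
        assert biv["pareto"].any()
        front = biv[biv["pareto"]]
        rest = biv[~biv["pareto"]]
        for _, row in rest.iterrows():
            dominated = (
                (front["greenness_rank"] <= row["greenness_rank"])
                & (front["performance_rank"] <= row["performance_rank"])
            )
            assert dominated.any()

    def test_identical_rankings_single_pareto_point(self):
        df = pd.DataFrame(
            {"lod": [1.0, 2.0, 3.0], "sample_mass": [1.0, 2.0, 3.0]},
            index=[1, 2, 3],
        )
        schema = (VariableSpec("lod", role="metrological"),
                  VariableSpec("sample_mass", role="environmental"))
        table = ProcedureTable(df, schema)
        env = rank_procedures(table, variables=["sample_mass"], seed=0)
        met = rank_procedures(table, variables=["lod"], seed=0)
        biv = bivariate_rank_table(env, met)
        assert biv["pareto"].sum() == 1
        assert biv.index[biv["pareto"]].tolist() == [1]

    def test_disjoint_rankings_error(self):
        t1 = ProcedureTable(
            pd.DataFrame({"lod": [1.0, 2.0]}, index=[1, 2]),
            (VariableSpec("lod"),),
        )
        t2 = ProcedureTable(
            pd.DataFrame({"lod": [1.0, 2.0]}, index=[3, 4]),
            (VariableSpec("lod"),),
        )
        r1 = rank_procedures(t1, variables=["lod"], seed=0)
        r2 = rank_procedures(t2, variables=["lod"], seed=0)
        with pytest.raises(ValidationError):
            bivariate_rank_table(r1, r2)


class TestPcaOverview:
    def test_standardisation_and_variance_fractions(self, synthetic_table):
        variables = [s.name for s in synthetic_table.variables]
        scores, loadings, explained = pca_overview(synthetic_table, variables)
        assert explained.sum() == pytest.approx(1.0)
        assert (np.diff(explained) <= 1e-12).all()
        assert scores.to_numpy().mean(axis=0) == pytest.approx(
            np.zeros(scores.shape[1]), abs=1e-9
        )

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame(
            {"lod": [1.0, 2.0, 3.0], "precision": [5.0, 5.0, 5.0]},
            index=[1, 2, 3],
        )
        table = ProcedureTable(
            df, (VariableSpec("lod"), VariableSpec("precision")),
        )
        with pytest.raises(ValidationError, match="precision"):
            pca_overview(table, ["lod", "precision"])

    def test_planted_block_loads_on_one_component(self):
        cfg = GeneratorConfig(
            n_procedures=500,
            correlation_blocks=((("nemi", "eco_scale", "-sample_mass"), 0.9),),
            seed=21,
        )
        table = generate_correlated_table(cfg)
        variables = [s.name for s in table.variables]
        _, loadings, _ = pca_overview(table, variables)
        block = ["nemi", "eco_scale", "sample_mass"]
        sub = loadings.loc[block, ["PC1", "PC2", "PC3"]].to_numpy()
        # sample_mass is anti-correlated: flip its loading before comparing
        sub[2] = -sub[2]
        for i in range(3):
            for j in range(i + 1, 3):
                cos = np.dot(sub[i], sub[j]) / (
                    np.linalg.norm(sub[i]) * np.linalg.norm(sub[j])
                )
                assert cos > 0.8
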