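"""Linear models, ANOVA ranking, balanced classification and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import noncpg as n
from noncpg.modeling import SITE_FEATURES, TILE_PREDICTORS


def _tile_frame(n_tiles, seed, effect=0.5, noise=0.05):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        c: rng.random(n_tiles)
        for c in ("a_content", "c_content", "g_content", "repeat_content",
                  "cpa_content", "cpa_cpg_ratio", "cpc_level", "cpg_level",
                  "cpt_level", "conservation")
    })
    df["h3k36me3"] = rng.integers(0, 2, n_tiles).astype(float)
    df["cpa_level"] = effect * df["cpg_level"] + rng.normal(0, noise, n_tiles)
    return df


class TestSampleLevelModel:
    def test_planted_dnmt3a_effect_recovered(self):
        rows = n.simulate_expression_cohort(40, effect_dnmt3a=0.5,
                                            effect_dnmt3b=0.0, noise_sd=0.2,
                                            seed=1)
        res = n.sample_level_model(rows)
        assert res.ranking[0] == "DNMT3A"
        lo, hi = res.fit.conf_int().loc["DNMT3A"]
        assert lo <= 0.5 <= hi
        assert res.r_squared > 0.5

    def test_null_response_uninformative(self):
        rows = n.simulate_expression_cohort(40, effect_dnmt3a=0.0,
                                            effect_dnmt3b=0.0, noise_sd=1.0,
                                            seed=2)
        res = n.sample_level_model(rows)
        assert res.r_squared < 0.35
        assert res.f_pvalue > 0.01

    def test_row_order_invariance(self):
        rows = n.simulate_expression_cohort(30, seed=3)
        res1 = n.sample_level_model(rows)
        res2 = n.sample_level_model(rows.sample(frac=1, random_state=0))
        assert res1.r_squared == pytest.approx(res2.r_squared)
        assert np.allclose(res1.params, res2.params)

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            n.sample_level_model(n.simulate_expression_cohort(5, seed=0))


class TestTileLevelModel:
    def test_cpg_level_tops_ranking_for_planted_dependence(self):
        res = n.tile_level_model(_tile_frame(2000, seed=4))
        assert res.ranking[0] == "cpg_level"
        assert res.r_squared > 0.5

    def test_noise_response_near_zero_r2(self):
        df = _tile_frame(5000, seed=5, effect=0.0, noise=1.0)
        res = n.tile_level_model(df)
        assert res.r_squared < 0.05

    def test_response_and_density_exclusions(self):
        df = _tile_frame(500, seed=6)
        df["cpg_content"] = np.random.default_rng(0).random(500)
        res = n.tile_level_model(df, response="cpa_level")
        assert "cpa_level" not in res.anova.index
        assert "cpg_content" not in res.anova.index
        assert "cpa_cpg_ratio" not in res.anova.index
        rev = n.tile_level_model(df, response="cpg_level",
                                 exclude_cpg_density=False)
        assert "cpa_level" in rev.anova.index

    def test_predictor_column_order_invariant_r2(self):
        df = _tile_frame(800, seed=7)
        res1 = n.tile_level_model(df)
        shuffled = df[list(df.columns[::-1])]
        res2 = n.tile_level_model(shuffled)
        assert res1.r_squared == pytest.approx(res2.r_squared)

    def test_anova_sums_of_squares_conserved(self):
        df = _tile_frame(600, seed=8)
        res = n.tile_level_model(df)
        total_ss = ((df["cpa_level"] - df["cpa_level"].mean()) ** 2).sum()
        assert res.anova["sum_sq"].sum() == pytest.approx(total_ss, rel=1e-10)

    def test_ols_matches_normal_equations(self):
        df = _tile_frame(50, seed=9)
        preds = [p for p in TILE_PREDICTORS if p not in
                 ("cpa_cpg_ratio",)]
        res = n.tile_level_model(df, predictors=preds)
        X = np.hstack([np.ones((len(df), 1)), df[preds].to_numpy()])
        y = df["cpa_level"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-8)


class TestClassificationDataset:
    def _features(self, n_meth, n_unmeth, seed=0):
        rng = np.random.default_rng(seed)
        lv = np.concatenate([rng.uniform(0.05, 1, n_meth),
                             rng.uniform(0, 0.049, n_unmeth)])
        df = pd.DataFrame({"level": lv})
        df["f1"] = rng.normal(size=len(df))
        return df

    def test_balancing_counts(self):
        ds = n.build_classification_dataset(self._features(100, 900), seed=1)
        assert len(ds) == 200
        assert ds["label"].mean() == pytest.approx(0.5)

    def test_deterministic_per_seed(self):
        f = self._features(50, 500)
        a = n.build_classification_dataset(f, seed=3)
        b = n.build_classification_dataset(f, seed=3)
        assert a.equals(b)
        c = n.build_classification_dataset(f, seed=4)
        assert not a.equals(c)

    def test_fewer_unmethylated_keeps_all_with_warning(self):
        with pytest.warns(UserWarning):
            ds = n.build_classification_dataset(self._features(100, 10), seed=1)
        assert len(ds) == 110


class TestCrossvalClassify:
    def _dataset(self, n_rows, separable, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n_rows)
        X = pd.DataFrame(rng.normal(size=(n_rows, 5)),
                         columns=[f"f{i}" for i in range(5)])
        if separable:
            X["f0"] = y + rng.normal(0, 0.01, n_rows)
        X["label"] = y
        return X

    def test_planted_separable_feature_auc_near_one(self):
        ds = self._dataset(600, separable=True, seed=1)
        res = n.crossval_classify(ds, "logistic", folds=5, seed=1,
                                  feature_cols=[f"f{i}" for i in range(5)])
        assert res.mean_auc > 0.99

    def test_random_forest_gini_rescaled_max_one(self):
        ds = self._dataset(400, separable=True, seed=2)
        res = n.crossval_classify(ds, "random_forest", folds=4, seed=2,
                                  feature_cols=[f"f{i}" for i in range(5)])
        assert res.importance.max() == 1.0
        assert res.importance.idxmax() == "f0"
        assert res.mean_auc > 0.95

    def test_svm_runs_and_ranks_planted_feature(self):
        ds = self._dataset(400, separable=True, seed=3)
        res = n.crossval_classify(ds, "svm", folds=4, seed=3,
                                  feature_cols=[f"f{i}" for i in range(5)])
        assert res.importance.abs().idxmax() == "f0"
        assert res.mean_auc > 0.99

    def test_too_many_folds_rejected(self):
        ds = self._dataset(10, separable=False)
        with pytest.raises(ValueError):
            n.crossval_classify(ds, "logistic", folds=8,
                                feature_cols=[f"f{i}" for i in range(5)])

    def test_unknown_method_rejected(self):
        ds = self._dataset(50, separable=False)
        with pytest.raises(ValueError):
            n.crossval_classify(ds, "deep_net", folds=2,
                                feature_cols=["f0"])


def test_site_feature_table_schema(cohort):
    sf = n.build_site_features(cohort["samples"], cohort["genome"], min_cov=15)
    assert len(sf) > 50
    for col in SITE_FEATURES:
        assert col in sf.columns
    assert len(SITE_FEATURES) == 30
    comp = sf[["frac_a", "frac_c", "frac_g", "frac_t"]].sum(axis=1)
    assert np.allclose(comp, 1.0)
    assert (sf["min_coverage"] >= 15).all()


def test_neighbor_cpg_feature_separates_planted_classes(cohort):
    """In the cohort, CpA methylation co-occurs with locally methylated CpGs
    only through chance; a planted dependence must be recoverable."""
    sf = n.build_site_features(cohort["samples"], cohort["genome"], min_cov=10)
    # plant: label determined by a feature column
    sf = sf.copy()
    sf["level"] = (sf["mean_cpg_level_window"] > sf["mean_cpg_level_window"].median()) * 0.2
    ds = n.build_classification_dataset(sf, threshold=0.05, seed=5)
    res = n.crossval_classify(ds, "logistic", folds=5, seed=5)
    assert res.mean_auc > 0.95
    assert res.importance.abs().idxmax() == "mean_cpg_level_window"
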