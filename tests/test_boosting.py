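"""Boosted-ensemble fitting, prediction and variable importance."""

import numpy as np
import pandas as pd
import pytest

from rarepath.boosting import (
    SGBParams,
    fit_sgb,
    predict_sgb,
    variable_importance,
)
from rarepath.synthetic_data import ConfigurationError


@pytest.fixture(scope="module")
def snp_data():
    rng = np.random.default_rng(42)
    n, p = 400, 30
    x = rng.binomial(2, 0.3, size=(n, p)).astype(float)
    beta = np.zeros(p)
    beta[:3] = 0.8
    y = rng.binomial(1, 1 / (1 + np.exp(-(x @ beta - 1.0))))
    return pd.DataFrame(x, columns=[f"x{j}" for j in range(p)]), y


class TestFit:
    def test_zero_trees_predicts_case_fraction(self, snp_data):
        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=0))
        pred = predict_sgb(model, x)
        assert np.allclose(pred, y.mean())

    def test_seeded_fit_is_bit_identical(self, snp_data):
        x, y = snp_data
        params = SGBParams(n_trees=50, seed=3)
        a = fit_sgb(x, y, params)
        b = fit_sgb(x, y, params)
        for ta, tb in zip(a.trees, b.trees):
            assert np.array_equal(ta.feature, tb.feature)
            assert np.array_equal(ta.value, tb.value)
        assert np.array_equal(predict_sgb(a, x), predict_sgb(b, x))

    def test_perfect_separator_reaches_high_training_auc(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"f": np.r_[np.zeros(60), np.ones(60)],
                          "noise": rng.random(120)})
        y = np.r_[np.zeros(60), np.ones(60)].astype(int)
        model = fit_sgb(x, y, SGBParams(n_trees=500, max_terminal_nodes=2,
                                        subsample_fraction=1.0))
        pred = predict_sgb(model, x)
        # training AUC: perfect ordering
        assert pred[y == 1].min() > pred[y == 0].max()

    def test_training_deviance_is_nonincreasing(self, snp_data):
        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=150, shrinkage=0.01,
                                        subsample_fraction=1.0))
        assert np.all(np.diff(model.train_deviance) <= 1e-12)

    def test_constant_outcome_is_an_error(self, snp_data):
        x, _ = snp_data
        with pytest.raises(ConfigurationError):
            fit_sgb(x, np.ones(len(x), dtype=int), SGBParams(n_trees=5))

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            SGBParams(max_terminal_nodes=20).validate()
        with pytest.raises(ConfigurationError):
            SGBParams(shrinkage=0.0).validate()


class TestPredict:
    def test_unknown_columns_raise_schema_error(self, snp_data):
        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=5))
        with pytest.raises(ConfigurationError):
            predict_sgb(model, x.rename(columns={"x0": "zz"}))

    def test_probabilities_monotone_in_score(self, snp_data):
        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=30))
        score = model.decision_function(x)
        prob = predict_sgb(model, x)
        order = np.argsort(score)
        assert np.all(np.diff(prob[order]) >= -1e-15)
        assert ((prob > 0) & (prob < 1)).all()

    def test_agreement_with_reference_implementation(self, snp_data):
        # independent oracle: scikit-learn's gradient boosting with matched
        # hyperparameters; mean absolute probability difference < 0.05
        from sklearn.ensemble import GradientBoostingClassifier

        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=500, shrinkage=0.01,
                                        subsample_fraction=1.0,
                                        max_terminal_nodes=8))
        mine = predict_sgb(model, x)
        ref = GradientBoostingClassifier(
            n_estimators=500, learning_rate=0.01, subsample=1.0,
            max_leaf_nodes=8, random_state=0).fit(x.to_numpy(), y)
        theirs = ref.predict_proba(x.to_numpy())[:, 1]
        assert np.abs(mine - theirs).mean() < 0.05

    def test_json_round_trip_schema(self, snp_data):
        import json
        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=3))
        blob = json.loads(model.to_json())
        assert blob["feature_names"] == list(x.columns)
        assert len(blob["trees"]) == 3
        assert {"feature", "threshold", "left", "right", "value",
                "gain"} <= set(blob["trees"][0])


class TestImportance:
    def test_never_split_variable_has_zero_importance(self, snp_data):
        x, y = snp_data
        x = x.copy()
        x["constant"] = 1.0
        model = fit_sgb(x, y, SGBParams(n_trees=40))
        imp = variable_importance(model).set_index("variable")
        assert imp.loc["constant", "raw_importance"] == 0.0
        assert not imp.loc["constant", "selected"]

    def test_scaled_importance_max_is_100(self, snp_data):
        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=40))
        imp = variable_importance(model)
        assert imp["scaled_importance"].max() == pytest.approx(100.0)
        assert imp["scaled_importance"].is_monotonic_decreasing

    def test_cutoff_zero_selects_every_split_variable(self, snp_data):
        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=40, importance_cutoff=0.0))
        imp = variable_importance(model)
        assert (imp["selected"] == (imp["raw_importance"] > 0) |
                imp["selected"]).all()
        split_vars = imp["raw_importance"] > 0
        assert imp.loc[split_vars, "selected"].all()

    def test_permuting_unselected_feature_leaves_predictions_unchanged(
            self, snp_data):
        x, y = snp_data
        x = x.copy()
        x["constant"] = 0.5
        model = fit_sgb(x, y, SGBParams(n_trees=40))
        base = predict_sgb(model, x)
        shuffled = x.copy()
        shuffled["constant"] = np.random.default_rng(1).permutation(
            shuffled["constant"].to_numpy())
        assert np.array_equal(base, predict_sgb(model, shuffled))

    def test_causal_variables_dominate_importance(self, snp_data):
        x, y = snp_data
        model = fit_sgb(x, y, SGBParams(n_trees=200, seed=2))
        imp = variable_importance(model)
        assert set(imp.head(3)["variable"]) == {"x0", "x1", "x2"}
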