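import numpy as np
import pandas as pd
import pytest

import nifcast as nc
from nifcast.modeling import (
    LAYER1_COLUMN,
    ModelSpec,
    evaluate,
    out_of_fold_predictions,
    train_base,
    train_stacked,
)


@pytest.fixture()
def linear_data(rng):
    X = pd.DataFrame(rng.normal(size=(120, 6)), columns=[f"f{i}" for i in range(6)])
    y = 3.0 * X["f0"].to_numpy()
    return X, y


class TestTrainBase:
    def test_constant_label_classifier(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = train_base(ModelSpec("random_forest", "classification"), X, np.ones(20))
        assert np.allclose(model.predict(X), 1.0)

    def test_tree_fits_linear_signal(self, linear_data):
        X, y = linear_data
        model = train_base(ModelSpec("random_forest", "regression", seed=1), X, y)
        r2 = evaluate(y, model.predict(X), "regression")["R2"]
        assert r2 > 0.95

    def test_schema_freeze(self, linear_data):
        X, y = linear_data
        model = train_base(ModelSpec("random_forest", "regression"), X, y)
        permuted = X[list(X.columns[::-1])]
        with pytest.raises(ValueError, match="schema"):
            model.predict(permuted)

    @pytest.mark.parametrize("family", ["random_forest", "grad_boost_xtreme",
                                        "grad_boost_hist", "grad_boost_classic"])
    def test_tree_families_reproducible(self, linear_data, family):
        X, y = linear_data
        p1 = train_base(ModelSpec(family, "regression", seed=9), X, y).predict(X)
        p2 = train_base(ModelSpec(family, "regression", seed=9), X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_median_imputation_handles_nan(self, linear_data):
        X, y = linear_data
        X = X.copy()
        X.iloc[::7, 2] = np.nan
        model = train_base(ModelSpec("grad_boost_classic", "regression"), X, y)
        assert np.isfinite(model.predict(X)).all()


class TestOutOfFold:
    def _folds(self, index, k):
        parts = np.array_split(np.array(index), k)
        return [
            ([i for j, p in enumerate(parts) if j != f for i in p], list(parts[f]))
            for f in range(k)
        ]

    def test_output_length(self, linear_data):
        X, y = linear_data
        folds = self._folds(X.index, 5)
        oof = out_of_fold_predictions(ModelSpec("random_forest", "regression"), X, y, folds)
        assert len(oof) == len(X)

    def test_leave_one_out(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 2)), columns=["a", "b"])
        y = X["a"].to_numpy()
        folds = self._folds(X.index, 6)
        oof = out_of_fold_predictions(ModelSpec("random_forest", "regression"), X, y, folds)
        assert len(oof) == 6 and np.isfinite(oof).all()

    def test_oof_no_better_than_insample(self, rng):
        X = pd.DataFrame(rng.normal(size=(150, 5)), columns=list("abcde"))
        y = X["a"].to_numpy() + rng.normal(0, 0.5, 150)
        spec = ModelSpec("grad_boost_classic", "regression", seed=2)
        folds = self._folds(X.index, 5)
        oof = out_of_fold_predictions(spec, X, y, folds)
        fitted = train_base(spec, X, y)
        r2_oof = evaluate(y, oof, "regression")["R2"]
        r2_in = evaluate(y, fitted.predict(X), "regression")["R2"]
        assert r2_oof <= r2_in

    def test_non_partition_folds_error(self, linear_data):
        X, y = linear_data
        folds = self._folds(X.index, 5)[:4]  # drop one fold
        with pytest.raises(ValueError, match="partition"):
            out_of_fold_predictions(ModelSpec("random_forest", "regression"), X, y, folds)


class TestStacked:
    def test_layer2_width_is_one_plus_aux(self, rng):
        Xe = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"emb_{i}" for i in range(10)])
        Xa = pd.DataFrame(rng.normal(size=(60, 7)), columns=[f"aux_{i}" for i in range(7)])
        y = Xe.iloc[:, 0].to_numpy()
        folds = TestOutOfFold()._folds(Xe.index, 5)
        bundle = train_stacked(
            ModelSpec("random_forest", "regression"), ModelSpec("random_forest", "regression"),
            Xe, Xa, y, folds,
        )
        assert len(bundle.layer2.schema) == 8
        assert bundle.layer2.schema[0] == LAYER1_COLUMN

    def test_perfect_layer1_feature(self, rng):
        # when the embedding block contains y itself, layer 1 recovers it
        # and layer 2 reaches ~perfect training fit from that one feature
        y = rng.normal(size=80)
        Xe = pd.DataFrame({"emb_y": y})
        Xa = pd.DataFrame({"noise": rng.normal(size=80)})
        folds = TestOutOfFold()._folds(Xe.index, 5)
        bundle = train_stacked(
            ModelSpec("random_forest", "regression", seed=0),
            ModelSpec("grad_boost_xtreme", "regression", seed=0),
            Xe, Xa, y, folds,
        )
        r2 = evaluate(y, bundle.predict(Xe, Xa), "regression")["R2"]
        assert r2 > 0.95

    def test_row_misalignment_errors(self, rng):
        Xe = pd.DataFrame(rng.normal(size=(10, 2)), index=range(10), columns=["a", "b"])
        Xa = pd.DataFrame(rng.normal(size=(10, 2)), index=range(1, 11), columns=["c", "d"])
        with pytest.raises(ValueError, match="misalign"):
            train_stacked(
                ModelSpec("random_forest", "regression"),
                ModelSpec("random_forest", "regression"),
                Xe, Xa, np.zeros(10), [],
            )


class TestEvaluate:
    def test_perfect_separation(self):
        m = evaluate([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], "classification")
        assert m["AUC"] == 1.0 and m["F1"] == 1.0

    def test_r2_zero_for_mean_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(y, np.full(4, y.mean()), "regression")
        assert m["R2"] == pytest.approx(0.0, abs=1e-12)

    def test_mse_is_rmse_squared(self, rng):
        y = rng.normal(size=50)
        m = evaluate(y, y + rng.normal(0, 0.3, 50), "regression")
        assert m["MSE"] == pytest.approx(m["RMSE"] ** 2, abs=1e-12)

    def test_auc_matches_concordant_pair_oracle(self, rng):
        """Rank-statistic AUC == brute-force O(n^2) pair counting."""
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1  # both classes present
        s = rng.random(200).round(2)  # rounding forces ties
        pos = s[y == 1]
        neg = s[y == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = conc / (len(pos) * len(neg))
        assert evaluate(y, s, "classification")["AUC"] == pytest.approx(oracle, abs=1e-12)

    def test_auc_monotone_invariant(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = rng.random(100)
        a1 = evaluate(y, s, "classification")["AUC"]
        a2 = evaluate(y, np.sqrt(s), "classification")["AUC"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_auc_errors(self):
        with pytest.raises(ValueError, match="single-class"):
            evaluate([1, 1, 1], [0.5, 0.6, 0.7], "classification")


class TestRunExperiment:
    def test_report_structure_and_stacking(self, small_features, small_labels, small_plan):
        report = nc.run_experiment(
            small_features, small_labels, small_plan,
            families=("random_forest", "grad_boost_xtreme"),
            tasks=("regression",), n_stacked=1, seed=0,
        )
        base = report[~report.model.str.startswith("stacked")]
        assert set(base.model) == {"random_forest", "grad_boost_xtreme"}
        assert set(report.partition) == {"Train", "Validation", "Test"}
        stacked = report[report.model.str.startswith("stacked")]
        assert stacked.model.nunique() == 1  # only the top validation-R2 family
        assert np.allclose(report.MSE, report.RMSE**2, atol=1e-10)

    def test_deterministic_rerun(self, small_features, small_labels, small_plan):
        kw = dict(families=("grad_boost_xtreme",), tasks=("regression",), n_stacked=0, seed=1)
        r1 = nc.run_experiment(small_features, small_labels, small_plan, **kw)
        r2 = nc.run_experiment(small_features, small_labels, small_plan, **kw)
        pd.testing.assert_frame_equal(r1, r2)
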