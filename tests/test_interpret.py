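"""Attribution engines and their downstream analyses.

The tree engine is checked against brute-force exact Shapley values
computed by subset enumeration over the tree's cover-weighted
conditional expectations; the kernel engine against brute-force
interventional Shapley values over a background sample.
"""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

import nifcast as nc
from nifcast._kernelshap import kernel_shap
from nifcast._treeshap import decision_tree_shap, forest_shap, gradient_boosting_shap
from nifcast.interpret import (
    CopyShapTable,
    copy_shap_table,
    explain_bundle,
    grouped_report,
    minimal_cluster,
    shap_attribution,
    sign_analysis,
)
from nifcast.modeling import ModelSpec, train_base


# --- brute-force oracles ----------------------------------------------------

def _cover_expectation(tree, x, S):
    """E[f(x)] with features outside S marginalized by training cover."""
    t = tree.tree_
    def rec(j):
        if t.children_left[j] == -1:
            return t.value[j].ravel()[0]
        f = t.feature[j]
        if f in S:
            nxt = t.children_left[j] if x[f] <= t.threshold[j] else t.children_right[j]
            return rec(nxt)
        wl = t.weighted_n_node_samples[t.children_left[j]]
        wr = t.weighted_n_node_samples[t.children_right[j]]
        return (wl * rec(t.children_left[j]) + wr * rec(t.children_right[j])) / (wl + wr)
    return rec(0)


def _brute_shapley(value_fn, M):
    phi = np.zeros(M)
    for i in range(M):
        others = [j for j in range(M) if j != i]
        for s in range(M):
            for S in combinations(others, s):
                w = factorial(s) * factorial(M - s - 1) / factorial(M)
                phi[i] += w * (value_fn(set(S) | {i}) - value_fn(set(S)))
    return phi


@pytest.fixture(scope="module")
def tree_data():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(90, 5))
    y = 2 * X[:, 0] + X[:, 1] * X[:, 2] + rng.normal(0, 0.1, 90)
    return X, y


class TestTreeEngine:
    def test_matches_brute_force_enumeration(self, tree_data):
        X, y = tree_data
        tree = DecisionTreeRegressor(max_depth=4, random_state=0).fit(X, y)
        phis, base = decision_tree_shap(tree, X[:6])
        for i in range(6):
            oracle = _brute_shapley(lambda S: _cover_expectation(tree, X[i], S), 5)
            assert np.allclose(phis[i], oracle, atol=1e-10)

    @pytest.mark.parametrize("fit", [
        lambda X, y: (RandomForestRegressor(n_estimators=25, random_state=0).fit(X, y), forest_shap),
        lambda X, y: (GradientBoostingRegressor(n_estimators=40, random_state=0).fit(X, y), gradient_boosting_shap),
    ])
    def test_local_accuracy_exact(self, tree_data, fit):
        X, y = tree_data
        model, engine = fit(X, y)
        phis, base = engine(model, X[:15])
        gap = np.abs(base + phis.sum(1) - model.predict(X[:15]))
        assert gap.max() < 1e-6

    def test_constant_feature_gets_zero(self, tree_data):
        X, y = tree_data
        Xc = np.column_stack([X, np.ones(len(X))])
        model = RandomForestRegressor(n_estimators=15, random_state=0).fit(Xc, y)
        phis, _ = forest_shap(model, Xc[:10])
        assert np.allclose(phis[:, -1], 0.0)


class TestKernelEngine:
    def test_matches_brute_force_interventional(self, rng):
        f = lambda A: A[:, 0] * 2 + np.sin(A[:, 1]) + A[:, 2] * A[:, 0]
        bg = rng.normal(size=(25, 3))
        x = np.array([1.0, 0.5, -2.0])
        def v(S):
            Z = np.array(bg, copy=True)
            for j in S:
                Z[:, j] = x[j]
            return f(Z).mean()
        phi, base = kernel_shap(f, x, bg)
        oracle = _brute_shapley(v, 3)
        assert np.allclose(phi, oracle, atol=1e-8)
        assert base + phi.sum() == pytest.approx(f(x[None])[0], abs=1e-8)

    def test_linear_model_closed_form(self, rng):
        f = lambda A: 2.0 * A[:, 0]
        bg = rng.normal(size=(40, 1))
        x = np.array([1.5])
        phi, base = kernel_shap(f, x, bg)
        assert phi[0] == pytest.approx(2.0 * (1.5 - bg.mean()), abs=1e-10)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(300, 6)), columns=[f"f{i}" for i in range(6)])
    X["const"] = 1.0
    y = 2.0 * X["f0"].to_numpy() - 1.5 * X["f1"].to_numpy() + rng.normal(0, 0.2, 300)
    return X, y


class TestShapAttribution:

    @pytest.mark.parametrize("family,tol", [
        ("random_forest", 1e-6),
        ("grad_boost_classic", 1e-6),
        ("grad_boost_xtreme", 1e-3),
        ("grad_boost_hist", 1e-3),
        ("svm", 1e-3),
    ])
    def test_local_accuracy_by_family(self, planted, family, tol):
        X, y = planted
        model = train_base(ModelSpec(family, "regression", seed=0), X, y)
        n = 30 if family != "svm" else 8
        report = shap_attribution(model, X.iloc[:n], seed=0)
        assert report.additivity_gap().max() < tol

    def test_sign_recovery_planted_effects(self, planted):
        X, y = planted
        model = train_base(ModelSpec("grad_boost_xtreme", "regression", seed=0), X, y)
        report = shap_attribution(model, X, seed=0)
        res = sign_analysis(report, ["f0", "f1", "const"])
        assert res["f0"][1] > 0
        assert res["f1"][1] < 0
        assert np.isnan(res["const"][1])  # undefined, not 0

    def test_mean_abs_total_invariant_to_order(self, planted):
        X, y = planted
        model = train_base(ModelSpec("random_forest", "regression", seed=0), X, y)
        r1 = shap_attribution(model, X.iloc[:20], seed=0)
        Xr = X[list(X.columns[::-1])]
        model2 = train_base(ModelSpec("random_forest", "regression", seed=0), Xr, y)
        r2 = shap_attribution(model2, Xr.iloc[:20], seed=0)
        assert r1.mean_abs().sum() == pytest.approx(r2.mean_abs().sum(), rel=0.2)

    def test_schema_mismatch_errors(self, planted):
        X, y = planted
        model = train_base(ModelSpec("random_forest", "regression", seed=0), X, y)
        with pytest.raises(ValueError, match="schema"):
            shap_attribution(model, X[list(X.columns[::-1])])


class TestMinimalCluster:
    def test_argmax(self):
        t = CopyShapTable({"nifX": {1: -0.01, 2: 0.00, 3: 0.02}})
        assert minimal_cluster(t, ["nifX"]) == {"nifX": 3}

    def test_tie_prefers_smaller(self):
        t = CopyShapTable({"nifH": {1: 0.5, 2: 0.5}})
        assert minimal_cluster(t, ["nifH"]) == {"nifH": 1}

    def test_missing_gene_errors(self):
        with pytest.raises(KeyError):
            minimal_cluster(CopyShapTable({}), ["nifD"])

    def test_cluster_shape(self):
        """Output is gene -> small positive integer for every prevalent gene."""
        table = CopyShapTable({
            g: {1: 0.1, 2: 0.3 if g in ("nifH", "nifB") else 0.0}
            for g in ("nifD", "nifK", "nifH", "nifB")
        })
        out = minimal_cluster(table, ["nifD", "nifK", "nifH", "nifB"])
        assert out == {"nifD": 1, "nifK": 1, "nifH": 2, "nifB": 2}
        assert all(isinstance(v, int) and v >= 1 for v in out.values())


def test_grouped_report_and_copy_table(small_features, small_labels, small_plan):
    """End-to-end: stacked fit, layer-2 attribution, grouped views."""
    X = small_features
    Xe, Xa = nc.split_blocks(X)
    by = {l.strain_id: l for l in small_labels}
    ytr = [by[i].reg_label for i in small_plan.train_ids]
    bundle = nc.train_stacked(
        ModelSpec("random_forest", "regression", seed=0),
        ModelSpec("grad_boost_xtreme", "regression", seed=0),
        Xe.loc[small_plan.train_ids], Xa.loc[small_plan.train_ids], ytr, small_plan.folds,
    )
    report = explain_bundle(bundle, Xe.loc[small_plan.test_ids], Xa.loc[small_plan.test_ids])
    assert report.additivity_gap().max() < 1e-3
    g = grouped_report(report)
    assert {"layer1", "aa_content", "copy_number"} <= set(g.group)
    table = copy_shap_table(report, ["nifH", "nifX"])
    assert set(table.table) == {"nifH", "nifX"}
    for per_copy in table.table.values():
        assert all(isinstance(c, int) for c in per_copy)
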