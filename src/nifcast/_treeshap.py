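"""Exact Shapley attribution for tree ensembles.

Implements the polynomial-time path-dependent tree attribution
(Lundberg-style EXTEND/UNWIND recursion) for scikit-learn decision
trees, random forests and classic gradient boosting.  The conditional
expectation of the tree given a feature subset follows the tree's own
training cover: at a split on an unknown feature both branches are
taken, weighted by their training sample counts.

Local accuracy holds exactly: base value + sum of attributions equals
the model prediction (up to float round-off).

Pure-Python recursion: fine for desk-scale forests (hundreds of trees,
depth <= ~8); the xgboost/lightgbm backends in
:mod:`nifcast.interpret` use those libraries' native C++ TreeSHAP and
should be preferred for large ensembles.
"""

from __future__ import annotations

import numpy as np


def _tree_arrays(sk_tree):
    t = sk_tree.tree_
    return (
        t.children_left,
        t.children_right,
        t.feature,
        t.threshold,
        t.value[:, 0, 0] if t.value.ndim == 3 else t.value[:, 0],
        t.weighted_n_node_samples,
    )


def tree_expected_value(sk_tree) -> float:
    """Cover-weighted mean of leaf values (the tree's base value)."""
    left, right, _, _, value, weight = _tree_arrays(sk_tree)
    total = weight[0]
    leaves = left == -1
    return float(np.sum(value[leaves] * weight[leaves]) / total)


def _extend(m, pz, po, pi):
    m = [e[:] for e in m]
    m.append([pi, pz, po, 1.0 if not m else 0.0])
    l = len(m)
    for i in range(l - 2, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / l
        m[i][3] = pz * m[i][3] * (l - 1 - i) / l
    return m


def _unwind(m, i):
    l = len(m)
    d = l - 1
    _, pz, po, _ = m[i]
    m = [e[:] for e in m]
    n = m[d][3]
    if po != 0.0:
        for j in range(d - 1, -1, -1):
            tmp = m[j][3]
            m[j][3] = n * l / ((j + 1) * po)
            n = tmp - m[j][3] * pz * (d - j) / l
    else:
        for j in range(d - 1, -1, -1):
            m[j][3] = m[j][3] * l / (pz * (d - j))
    for j in range(i, d):
        m[j][0], m[j][1], m[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
    return m[:-1]


def _unwound_sum(m, i):
    l = len(m)
    d = l - 1
    _, pz, po, _ = m[i]
    total = 0.0
    n = m[d][3]
    if po != 0.0:
        for j in range(d - 1, -1, -1):
            tmp = n * l / ((j + 1) * po)
            total += tmp
            n = m[j][3] - tmp * pz * (d - j) / l
    else:
        for j in range(d - 1, -1, -1):
            total += m[j][3] * l / (pz * (d - j))
    return total


def tree_shap_values(sk_tree, x: np.ndarray) -> np.ndarray:
    """Attributions of one decision tree for one sample (length = n features)."""
    left, right, feature, threshold, value, weight = _tree_arrays(sk_tree)
    phi = np.zeros(len(x))

    def recurse(j, m, pz, po, pi):
        m = _extend(m, pz, po, pi)
        if left[j] == -1:
            v = value[j]
            for i in range(1, len(m)):
                phi[m[i][0]] += _unwound_sum(m, i) * (m[i][2] - m[i][1]) * v
            return
        f = feature[j]
        hot, cold = (left[j], right[j]) if x[f] <= threshold[j] else (right[j], left[j])
        iz = io = 1.0
        k = next((idx for idx in range(1, len(m)) if m[idx][0] == f), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = _unwind(m, k)
        recurse(hot, m, iz * weight[hot] / weight[j], io, f)
        recurse(cold, m, iz * weight[cold] / weight[j], 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)
    return phi


def forest_shap(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """(attributions, base value) for a RandomForestRegressor."""
    X = np.asarray(X, dtype=float)
    phis = np.zeros_like(X)
    base = 0.0
    k = len(model.estimators_)
    for est in model.estimators_:
        base += tree_expected_value(est) / k
        for i in range(X.shape[0]):
            phis[i] += tree_shap_values(est, X[i]) / k
    return phis, base


def gradient_boosting_shap(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """(attributions, base value) for a GradientBoostingRegressor."""
    X = np.asarray(X, dtype=float)
    phis = np.zeros_like(X)
    lr = model.learning_rate
    base = float(model.init_.predict(X[:1])[0])
    for stage in model.estimators_:
        est = stage[0]
        base_inc = tree_expected_value(est)
        base += lr * base_inc
        for i in range(X.shape[0]):
            phis[i] += lr * tree_shap_values(est, X[i])
    return phis, base


def decision_tree_shap(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    X = np.asarray(X, dtype=float)
    phis = np.stack([tree_shap_values(model, X[i]) for i in range(X.shape[0])])
    return phis, tree_expected_value(model)
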