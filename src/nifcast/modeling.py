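"""Model zoo, two-layer stacking, and the evaluation harness.

Six learner families are supported for both tasks: random forest,
kernel SVM/SVR, XGBoost, LightGBM, classic gradient boosting, and a
multilayer perceptron.  Every estimator runs behind a schema-frozen
wrapper: the exact ordered feature-name tuple seen at fit time is
required again at predict time.

Stacking follows the two-layer design: layer 1 is fit on the pooled
protein-embedding block only; layer 2 is fit on the layer-1 prediction
concatenated with the auxiliary (codon / context / classical-encoder)
block.  To keep layer 2 from learning on leaked in-sample fits, its
training input uses layer-1 *out-of-fold* predictions; at inference the
bundle uses layer 1's direct prediction.

Evaluation mirrors the nested protocol: a fixed stratified test set,
k-fold cross-validation on the remainder, and per-fold metrics on
train / validation / test averaged over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.impute import SimpleImputer
from sklearn.metrics import (
    f1_score,
    mean_absolute_error,
    mean_squared_error,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

logger = logging.getLogger("nifcast")

FAMILIES = (
    "random_forest",
    "svm",
    "grad_boost_xtreme",
    "grad_boost_hist",
    "grad_boost_classic",
    "mlp",
)

#: families whose predictions are exactly reproducible given the seed
DETERMINISTIC_FAMILIES = (
    "random_forest",
    "grad_boost_xtreme",
    "grad_boost_hist",
    "grad_boost_classic",
)


@dataclass(frozen=True)
class ModelSpec:
    family: str
    task: str  # 'classification' | 'regression'
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")


def _make_estimator(spec: ModelSpec):
    clf = spec.task == "classification"
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.family == "random_forest":
        cls = RandomForestClassifier if clf else RandomForestRegressor
        model = cls(n_estimators=hp.pop("n_estimators", 200), random_state=seed,
                    n_jobs=1, **hp)
    elif spec.family == "svm":
        if clf:
            # Platt-scaled probabilities (the modern replacement for
            # SVC(probability=True))
            from sklearn.calibration import CalibratedClassifierCV

            base = SVC(C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"),
                       random_state=seed, **hp)
            model = CalibratedClassifierCV(base, ensemble=False)
        else:
            model = SVR(C=hp.pop("C", 1.0), gamma=hp.pop("gamma", "scale"), **hp)
    elif spec.family == "grad_boost_xtreme":
        from xgboost import XGBClassifier, XGBRegressor

        cls = XGBClassifier if clf else XGBRegressor
        model = cls(
            n_estimators=hp.pop("n_estimators", 200),
            max_depth=hp.pop("max_depth", 4),
            learning_rate=hp.pop("learning_rate", 0.1),
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            **hp,
        )
    elif spec.family == "grad_boost_hist":
        from lightgbm import LGBMClassifier, LGBMRegressor

        cls = LGBMClassifier if clf else LGBMRegressor
        model = cls(
            n_estimators=hp.pop("n_estimators", 200),
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            **hp,
        )
    elif spec.family == "grad_boost_classic":
        cls = GradientBoostingClassifier if clf else GradientBoostingRegressor
        model = cls(n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp)
    elif spec.family == "mlp":
        cls = MLPClassifier if clf else MLPRegressor
        model = cls(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (128,)),
            max_iter=hp.pop("max_iter", 500),
            random_state=seed,
            **hp,
        )
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(spec.family)

    # keep_empty_features preserves the schema width even if a feature
    # is all-NaN in some training fold (attribution relies on 1:1 columns)
    steps = [("impute", SimpleImputer(strategy="median", keep_empty_features=True))]
    if spec.family in ("svm", "mlp"):
        steps.append(("scale", StandardScaler()))
    steps.append(("model", model))
    return Pipeline(steps)


@dataclass
class FittedModel:
    """A fitted pipeline with its frozen feature schema."""

    spec: ModelSpec
    pipeline: Pipeline
    schema: tuple[str, ...]

    def _check(self, X: pd.DataFrame) -> pd.DataFrame:
        if tuple(X.columns) != self.schema:
            raise ValueError(
                "feature schema mismatch: expected "
                f"{self.schema[:3]}...({len(self.schema)}), got "
                f"{tuple(X.columns[:3])}...({X.shape[1]})"
            )
        return X

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Scores in [0,1] for classification, point predictions for regression."""
        X = self._check(X)
        if self.spec.task == "classification":
            proba = self.pipeline.predict_proba(X)
            if proba.shape[1] == 1:  # degenerate single-class training set
                cls = float(self.pipeline.steps[-1][1].classes_[0])
                return np.full(len(X), cls)
            return proba[:, 1]
        return self.pipeline.predict(X)

    def predict_label(self, X: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        if self.spec.task != "classification":
            raise ValueError("predict_label is for classifiers")
        return (self.predict(X) >= threshold).astype(int)


def train_base(spec: ModelSpec, X: pd.DataFrame, y) -> FittedModel:
    """Fit one base learner; the column order of X becomes the frozen schema."""
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X/y length mismatch")
    pipe = _make_estimator(spec)
    pipe.fit(X, y)
    return FittedModel(spec=spec, pipeline=pipe, schema=tuple(X.columns))


def _resolve_folds(X: pd.DataFrame, folds) -> list[tuple[np.ndarray, np.ndarray]]:
    """Turn id-based or index-based folds into positional index pairs."""
    pos = {idx: i for i, idx in enumerate(X.index)}
    resolved = []
    for tr, va in folds:
        tr_i = np.array([pos[i] for i in tr])
        va_i = np.array([pos[i] for i in va])
        resolved.append((tr_i, va_i))
    all_val = np.concatenate([va for _, va in resolved])
    if len(all_val) != len(X) or len(np.unique(all_val)) != len(X):
        raise ValueError("validation folds must partition the rows of X")
    return resolved


def out_of_fold_predictions(spec: ModelSpec, X: pd.DataFrame, y, folds) -> np.ndarray:
    """Row i's prediction comes from the model not trained on i's fold."""
    y = np.asarray(y)
    oof = np.empty(len(X), dtype=float)
    for tr_i, va_i in _resolve_folds(X, folds):
        model = train_base(spec, X.iloc[tr_i], y[tr_i])
        oof[va_i] = model.predict(X.iloc[va_i])
    return oof


LAYER1_COLUMN = "layer1_pred"


@dataclass
class ModelBundle:
    """Two-layer stacked model."""

    layer1: FittedModel
    layer2: FittedModel
    seeds: tuple[int, int]

    def layer2_input(self, X_emb: pd.DataFrame, X_aux: pd.DataFrame) -> pd.DataFrame:
        pred = self.layer1.predict(X_emb)
        out = X_aux.copy()
        out.insert(0, LAYER1_COLUMN, pred)
        return out

    def predict(self, X_emb: pd.DataFrame, X_aux: pd.DataFrame) -> np.ndarray:
        if not X_emb.index.equals(X_aux.index):
            raise ValueError("embedding and auxiliary blocks are row-misaligned")
        return self.layer2.predict(self.layer2_input(X_emb, X_aux))


def train_stacked(
    spec1: ModelSpec,
    spec2: ModelSpec,
    X_emb: pd.DataFrame,
    X_aux: pd.DataFrame,
    y,
    folds,
) -> ModelBundle:
    """Fit the two-layer stack with out-of-fold layer-1 training inputs."""
    if not X_emb.index.equals(X_aux.index):
        raise ValueError("embedding and auxiliary blocks are row-misaligned")
    y = np.asarray(y)
    oof = out_of_fold_predictions(spec1, X_emb, y, folds)
    layer1 = train_base(spec1, X_emb, y)
    X2 = X_aux.copy()
    X2.insert(0, LAYER1_COLUMN, oof)
    layer2 = train_base(spec2, X2, y)
    return ModelBundle(layer1=layer1, layer2=layer2, seeds=(spec1.seed, spec2.seed))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate(y_true, y_pred_or_scores, task: str, threshold: float = 0.5) -> dict:
    """Metric dict for one partition.

    Classification expects scores in [0, 1]; the operating point for
    precision/recall/F1 is score >= ``threshold``.  Regression metrics
    are computed on whatever scale y is given in (the pipeline uses the
    log10(x+2) scale throughout).
    """
    y_true = np.asarray(y_true)
    y_hat = np.asarray(y_pred_or_scores, dtype=float)
    if len(y_true) != len(y_hat):
        raise ValueError("length mismatch")
    if task == "classification":
        if len(np.unique(y_true)) < 2:
            raise ValueError("AUC undefined for single-class y_true")
        if y_hat.min() < 0 or y_hat.max() > 1:
            raise ValueError("classification scores must lie in [0, 1]")
        labels = (y_hat >= threshold).astype(int)
        return {
            "AUC": float(roc_auc_score(y_true, y_hat)),
            "Precision": float(precision_score(y_true, labels, zero_division=0)),
            "Recall": float(recall_score(y_true, labels, zero_division=0)),
            "F1": float(f1_score(y_true, labels, zero_division=0)),
        }
    elif task == "regression":
        mse = float(mean_squared_error(y_true, y_hat))
        return {
            "R2": float(r2_score(y_true, y_hat)),
            "RMSE": float(np.sqrt(mse)),
            "MSE": mse,
            "MAE": float(mean_absolute_error(y_true, y_hat)),
        }
    raise ValueError(f"unknown task {task!r}")


def _fold_averaged_rows(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    test_X: pd.DataFrame,
    test_y: np.ndarray,
    folds,
    model_name: str,
) -> list[dict]:
    per_part: dict[str, list[dict]] = {"Train": [], "Validation": [], "Test": []}
    for tr_i, va_i in _resolve_folds(X, folds):
        model = train_base(spec, X.iloc[tr_i], y[tr_i])
        per_part["Train"].append(evaluate(y[tr_i], model.predict(X.iloc[tr_i]), spec.task))
        per_part["Validation"].append(evaluate(y[va_i], model.predict(X.iloc[va_i]), spec.task))
        per_part["Test"].append(evaluate(test_y, model.predict(test_X), spec.task))
    return _average_partitions(per_part, model_name, spec.task)


def run_experiment(
    X: pd.DataFrame,
    labels,
    plan,
    families: Sequence[str] = FAMILIES,
    tasks: Sequence[str] = ("classification", "regression"),
    emb_columns: Sequence[str] | None = None,
    seed: int = 0,
    n_stacked: int = 3,
    hyperparameters: dict | None = None,
) -> pd.DataFrame:
    """Cross-validated benchmark of all families plus stacked regressors.

    ``X`` is the full feature table indexed by strain id; ``labels`` a
    list of LabelSet; ``plan`` a SplitPlan with folds.  Stacked variants
    are built for the ``n_stacked`` best regression families by
    validation R2, using the same family in both layers.
    """
    by_id = {l.strain_id: l for l in labels}
    emb_cols = list(emb_columns) if emb_columns is not None else [
        c for c in X.columns if c.startswith("emb_")
    ]
    aux_cols = [c for c in X.columns if c not in set(emb_cols)]
    Xtr = X.loc[plan.train_ids]
    Xte = X.loc[plan.test_ids]
    rows: list[dict] = []
    val_r2: dict[str, float] = {}

    for task in tasks:
        attr = "class_label" if task == "classification" else "reg_label"
        ytr = np.array([getattr(by_id[i], attr) for i in plan.train_ids])
        yte = np.array([getattr(by_id[i], attr) for i in plan.test_ids])
        for family in families:
            hp = (hyperparameters or {}).get(family, {})
            spec = ModelSpec(family=family, task=task, hyperparameters=hp, seed=seed)
            new_rows = _fold_averaged_rows(spec, Xtr, ytr, Xte, yte, plan.folds, family)
            rows.extend(new_rows)
            if task == "regression":
                val_r2[family] = next(
                    r["R2"] for r in new_rows if r["partition"] == "Validation"
                )

    if "regression" in tasks and n_stacked > 0:
        ytr = np.array([by_id[i].reg_label for i in plan.train_ids])
        yte = np.array([by_id[i].reg_label for i in plan.test_ids])
        top = sorted(val_r2, key=val_r2.get, reverse=True)[:n_stacked]
        logger.info("stacking top regression families: %s", top)
        for family in top:
            hp = (hyperparameters or {}).get(family, {})
            spec = ModelSpec(family=family, task="regression", hyperparameters=hp, seed=seed)
            rows.extend(
                _stacked_rows(spec, Xtr[emb_cols], Xtr[aux_cols], ytr,
                              Xte[emb_cols], Xte[aux_cols], yte, plan.folds,
                              f"stacked_{family}")
            )
    return pd.DataFrame(rows)


def _stacked_rows(
    spec: ModelSpec,
    Xe: pd.DataFrame,
    Xa: pd.DataFrame,
    y: np.ndarray,
    Xe_test: pd.DataFrame,
    Xa_test: pd.DataFrame,
    y_test: np.ndarray,
    folds,
    model_name: str,
) -> list[dict]:
    """Per-fold stacked fits: each fold's stack is trained without its
    validation fold, then scored on train/validation/test partitions."""
    per_part: dict[str, list[dict]] = {"Train": [], "Validation": [], "Test": []}
    resolved = _resolve_folds(Xe, folds)
    for fold_i, (tr_i, va_i) in enumerate(resolved):
        inner = _inner_folds(len(tr_i), k=len(folds), seed=spec.seed + fold_i)
        Xe_tr = Xe.iloc[tr_i]
        bundle = train_stacked(
            spec, spec, Xe_tr, Xa.iloc[tr_i], y[tr_i],
            [(list(Xe_tr.index[a]), list(Xe_tr.index[b])) for a, b in inner],
        )
        per_part["Train"].append(
            evaluate(y[tr_i], bundle.predict(Xe_tr, Xa.iloc[tr_i]), "regression"))
        per_part["Validation"].append(
            evaluate(y[va_i], bundle.predict(Xe.iloc[va_i], Xa.iloc[va_i]), "regression"))
        per_part["Test"].append(
            evaluate(y_test, bundle.predict(Xe_test, Xa_test), "regression"))
    return _average_partitions(per_part, model_name, "regression")



def _average_partitions(per_part: dict, model_name: str, task: str) -> list[dict]:
    """Average fold metrics per partition.

    RMSE is recomputed from the fold-averaged MSE (root of the mean,
    not mean of the roots) so MSE = RMSE**2 holds in every report row.
    """
    rows = []
    for part, dicts in per_part.items():
        avg = {k: float(np.mean([d[k] for d in dicts])) for k in dicts[0]}
        if "MSE" in avg:
            avg["RMSE"] = float(np.sqrt(avg["MSE"]))
        rows.append({"model": model_name, "task": task, "partition": part, **avg})
    return rows

def _inner_folds(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts = np.array_split(perm, k)
    return [
        (np.concatenate([p for j, p in enumerate(parts) if j != i]), parts[i])
        for i in range(k)
    ]
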