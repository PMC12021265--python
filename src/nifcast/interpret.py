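"""Shapley attribution reports, feature-effect sign analysis, and the
minimal nif cluster derivation.

Attribution backends by model family:

* ``grad_boost_xtreme`` / ``grad_boost_hist`` — the libraries' native
  exact TreeSHAP (``pred_contribs`` / ``pred_contrib``);
* ``random_forest`` / ``grad_boost_classic`` — the in-package
  path-dependent tree attribution (:mod:`nifcast._treeshap`);
* ``svm`` / ``mlp`` — kernel attribution against a background sample
  (:mod:`nifcast._kernelshap`), exact for small feature counts.

All backends satisfy local accuracy: base value plus the sum of
per-feature attributions equals the model prediction (exactly for tree
backends, by construction for the kernel backend).

Attributions for pipeline models are computed on the model's internal
representation (after median imputation and, for svm/mlp, scaling);
both transforms are column-wise, so attribution i still refers to
feature i of the input schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nifcast import _kernelshap, _treeshap
from nifcast.modeling import LAYER1_COLUMN, FittedModel, ModelBundle

logger = logging.getLogger("nifcast")


@dataclass
class ShapReport:
    """Per-sample, per-feature attribution matrix with its base value."""

    feature_names: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_values: np.ndarray  # the explained inputs, same shape
    predictions: np.ndarray  # model output per sample

    def mean_abs(self) -> pd.Series:
        """Mean |attribution| per feature (global importance ranking)."""
        return pd.Series(
            np.abs(self.values).mean(axis=0), index=list(self.feature_names)
        ).sort_values(ascending=False)

    def pearson(self) -> pd.Series:
        """Pearson r between feature value and its attribution.

        NaN (undefined) for features constant across the explained
        samples or with constant attributions.
        """
        out = {}
        for j, name in enumerate(self.feature_names):
            x = self.feature_values[:, j]
            s = self.values[:, j]
            if np.nanstd(x) == 0 or np.std(s) == 0:
                out[name] = np.nan
                continue
            mask = np.isfinite(x)
            out[name] = float(np.corrcoef(x[mask], s[mask])[0, 1])
        return pd.Series(out)

    def additivity_gap(self) -> np.ndarray:
        """|base + sum(attributions) - prediction| per sample."""
        return np.abs(self.base_value + self.values.sum(axis=1) - self.predictions)


def _transform_for_model(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Run X through the pipeline's preprocessing steps (all but 'model')."""
    Xt = X
    for name, step in model.pipeline.steps[:-1]:
        Xt = step.transform(Xt)
    return np.asarray(Xt, dtype=float)


def _final_estimator(model: FittedModel):
    return model.pipeline.steps[-1][1]


def shap_attribution(
    model: FittedModel,
    X: pd.DataFrame,
    background: pd.DataFrame | None = None,
    background_size: int = 100,
    seed: int = 0,
) -> ShapReport:
    """Shapley attributions of a fitted model on the rows of X.

    ``background`` (default: a seeded subsample of X itself, at most
    ``background_size`` rows) defines the reference distribution for
    the kernel backend; tree backends carry their own background in the
    trees' training cover.
    """
    model._check(X)
    est = _final_estimator(model)
    family = model.spec.family
    Xt = _transform_for_model(model, X)
    task = model.spec.task

    if family == "grad_boost_xtreme":
        import xgboost

        booster = est.get_booster()
        contrib = booster.predict(xgboost.DMatrix(Xt), pred_contribs=True)
        phis, base = contrib[:, :-1], float(contrib[0, -1])
        if task == "classification":
            preds = booster.predict(xgboost.DMatrix(Xt), output_margin=True)
        else:
            preds = est.predict(Xt)
    elif family == "grad_boost_hist":
        contrib = est.predict(Xt, pred_contrib=True)
        phis, base = contrib[:, :-1], float(contrib[0, -1])
        booster = est.booster_
        preds = booster.predict(Xt, raw_score=True)
    elif family in ("random_forest", "grad_boost_classic"):
        if task != "regression":
            raise NotImplementedError(
                "in-package tree attribution covers regressors; use the "
                "xgboost/lightgbm families for classifier attribution"
            )
        if family == "random_forest":
            phis, base = _treeshap.forest_shap(est, Xt)
        else:
            phis, base = _treeshap.gradient_boosting_shap(est, Xt)
        preds = est.predict(Xt)
    elif family in ("svm", "mlp"):
        if background is None:
            rng = np.random.default_rng(seed)
            take = min(background_size, len(X))
            bg = Xt[rng.choice(len(X), size=take, replace=False)]
        else:
            model._check(background)
            bg = _transform_for_model(model, background)
        if task == "classification":
            f = lambda A: est.predict_proba(A)[:, 1]
        else:
            f = est.predict
        phis, base = _kernelshap.kernel_shap_matrix(f, Xt, bg, seed=seed)
        preds = f(Xt)
    else:  # pragma: no cover
        raise ValueError(family)

    return ShapReport(
        feature_names=model.schema,
        values=np.asarray(phis, dtype=float),
        base_value=float(base),
        feature_values=Xt,
        predictions=np.asarray(preds, dtype=float),
    )


def explain_bundle(
    bundle: ModelBundle,
    X_emb: pd.DataFrame,
    X_aux: pd.DataFrame,
    background: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    background_size: int = 100,
    seed: int = 0,
) -> ShapReport:
    """Attribute the stacked model's layer 2 over [layer-1 prediction ⊕ aux].

    This is the interpretability surface of the two-layer model: the
    layer-1 prediction appears as one feature alongside the auxiliary
    block, mirroring how the second stage actually sees its inputs.
    """
    X2 = bundle.layer2_input(X_emb, X_aux)
    bg2 = None
    if background is not None:
        bg2 = bundle.layer2_input(*background)
    return shap_attribution(
        bundle.layer2, X2, background=bg2, background_size=background_size, seed=seed
    )


def sign_analysis(
    report: ShapReport, feature_group: Sequence[str]
) -> dict[str, tuple[float, float]]:
    """Per feature: (mean |attribution|, Pearson r of value vs attribution).

    Positive r means higher feature values push predictions up
    (activity-promoting); r is NaN for constant features.
    """
    missing = set(feature_group) - set(report.feature_names)
    if missing:
        raise KeyError(f"features not in report: {sorted(missing)}")
    mean_abs = report.mean_abs()
    pearson = report.pearson()
    return {f: (float(mean_abs[f]), float(pearson[f])) for f in feature_group}


FEATURE_GROUPS = (
    ("layer1", lambda n: n == LAYER1_COLUMN),
    ("embedding", lambda n: n.startswith("emb_")),
    ("triad", lambda n: n.startswith("ct_")),
    ("dipeptide", lambda n: n.startswith("dpc_")),
    ("aa_content", lambda n: n.startswith("paac_") and not n.startswith("paac_lam")),
    ("paac_order", lambda n: n.startswith("paac_lam")),
    ("codon_rscu", lambda n: n.startswith("rscu_")),
    ("codon_expression", lambda n: n.startswith("Average_") or n == "ECD"),
    ("gene_distance", lambda n: n.startswith("dist_")),
    ("copy_number", lambda n: n.startswith("copy_")),
)


def grouped_report(report: ShapReport) -> pd.DataFrame:
    """Tidy (feature, group, mean_abs_shap, pearson_r) table, sorted by
    importance — the CSV behind the grouped importance bar charts."""
    mean_abs = report.mean_abs()
    pearson = report.pearson()
    rows = []
    for name in report.feature_names:
        group = next((g for g, match in FEATURE_GROUPS if match(name)), "other")
        rows.append(
            {
                "feature": name,
                "group": group,
                "mean_abs_shap": float(mean_abs[name]),
                "pearson_r": float(pearson[name]),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("mean_abs_shap", ascending=False)
        .reset_index(drop=True)
    )


@dataclass
class CopyShapTable:
    """gene -> copy number -> mean attribution of that gene's copy-number
    feature over the samples showing that copy number."""

    table: Mapping[str, Mapping[int, float]]

    def genes(self) -> list[str]:
        return sorted(self.table)


def copy_shap_table(
    report: ShapReport, genes: Sequence[str], prefix: str = "copy_"
) -> CopyShapTable:
    """Aggregate copy-number feature attributions by observed copy count."""
    name_to_col = {n: j for j, n in enumerate(report.feature_names)}
    table: dict[str, dict[int, float]] = {}
    for gene in genes:
        col = name_to_col.get(f"{prefix}{gene}")
        if col is None:
            raise KeyError(f"no copy-number feature for gene {gene!r}")
        copies = report.feature_values[:, col]
        shaps = report.values[:, col]
        per_copy: dict[int, float] = {}
        for c in sorted(set(int(v) for v in copies[np.isfinite(copies)])):
            mask = copies == c
            per_copy[c] = float(shaps[mask].mean())
        table[gene] = per_copy
    return CopyShapTable(table=table)


def minimal_cluster(
    table: CopyShapTable, prevalent: Sequence[str]
) -> dict[str, int]:
    """Copy number per prevalent gene maximizing mean attribution.

    Ties resolve to the smaller copy number — the most parsimonious
    cluster consistent with the attribution evidence.
    """
    out = {}
    for gene in prevalent:
        if gene not in table.table or not table.table[gene]:
            raise KeyError(f"gene {gene!r} missing from copy-attribution table")
        per_copy = table.table[gene]
        best = max(sorted(per_copy), key=lambda c: (per_copy[c], -c))
        out[gene] = int(best)
    return out
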