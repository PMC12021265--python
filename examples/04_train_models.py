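"""Cross-validated benchmark: nested 80/20 split, five folds, several
learner families, plus a stacked regressor for the best family."""

import nifcast as nc
from nifcast.synthetic import SyntheticConfig, generate_strains

records, _ = generate_strains(SyntheticConfig(n_strains=150, seed=5))
X = nc.build_feature_table(records)
labels = nc.make_labels(records)
plan = nc.stratified_split(labels, seed=5)
plan.folds = nc.make_cv_folds(plan.train_ids, labels, k=5, seed=5)

report = nc.run_experiment(
    X, labels, plan,
    families=("random_forest", "grad_boost_xtreme", "svm"),
    tasks=("classification", "regression"),
    n_stacked=1, seed=5,
)
clf = report[report.task == "classification"]
reg = report[report.task == "regression"]
print("classification (fold-averaged):")
print(clf[["model", "partition", "AUC", "F1"]].round(3).to_string(index=False))
print()
print("regression on the log10(x+2) scale (fold-averaged):")
print(reg[["model", "partition", "R2", "RMSE", "MAE"]].round(3).to_string(index=False))
# Validation rows estimate generalization from the five folds; Test rows
# score each fold's model on the one held-out stratified test set. The
# stacked_* row trains layer 1 on embeddings only and layer 2 on the
# out-of-fold layer-1 prediction plus the auxiliary block.
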