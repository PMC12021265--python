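"""Activity labels and the nested train/test + cross-validation plan.

Classification: a strain is positive (high activity) when its
acetylene-reduction rate reaches 50 nmol C2H4/mg protein/hour; the tie
at exactly 50 counts as positive.  Regression targets are compressed to
``y = log10(x + 2)`` so that the heavy right tail of measured rates does
not dominate the loss.

Splitting: stratified 80/20 train/test with per-class training counts
``floor(0.8 * class size)`` (remainder to test), then k-fold
cross-validation within the training set.  Counts are a deterministic
function of the class sizes; only membership depends on the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from nifcast.records import StrainRecord

ACTIVITY_THRESHOLD = 50.0  # nmol C2H4 / mg protein / hour


def transform_activity(x) -> np.ndarray | float:
    """Regression label y = log10(x + 2)."""
    return np.log10(np.asarray(x, dtype=float) + 2.0)


def inverse_transform(y) -> np.ndarray | float:
    """Raw activity x = 10**y - 2."""
    return np.power(10.0, np.asarray(y, dtype=float)) - 2.0


@dataclass(frozen=True)
class LabelSet:
    strain_id: str
    activity: float
    class_label: int
    reg_label: float


def make_labels(
    records: Sequence[StrainRecord], threshold: float = ACTIVITY_THRESHOLD
) -> list[LabelSet]:
    out = []
    for rec in records:
        if rec.activity is None:
            raise ValueError(f"strain {rec.strain_id!r} has no activity value")
        if rec.activity < 0:
            raise ValueError(f"strain {rec.strain_id!r}: negative activity")
        out.append(
            LabelSet(
                strain_id=rec.strain_id,
                activity=float(rec.activity),
                class_label=int(rec.activity >= threshold),
                reg_label=float(transform_activity(rec.activity)),
            )
        )
    return out


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train/test overlap")
        if self.folds:
            val_ids = [i for _, val in self.folds for i in val]
            if sorted(val_ids) != sorted(self.train_ids):
                raise ValueError("validation folds do not partition the training set")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "train_ids": self.train_ids,
                    "test_ids": self.test_ids,
                    "folds": [[tr, va] for tr, va in self.folds],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            d = json.load(fh)
        plan = cls(
            train_ids=d["train_ids"],
            test_ids=d["test_ids"],
            folds=[(tr, va) for tr, va in d.get("folds", [])],
            seed=d.get("seed", 0),
        )
        plan.validate()
        return plan


def stratified_split(
    labels: Sequence[LabelSet], train_frac: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Per-class split with exactly floor(train_frac * class size) in train.

    With the 209-negative / 193-positive cohort this yields the
    canonical (167 neg, 154 pos) training and (42 neg, 39 pos) test
    partition.
    """
    classes = sorted({l.class_label for l in labels})
    if len(classes) < 2:
        raise ValueError("both classes must be present for a stratified split")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls_val in classes:
        ids = [l.strain_id for l in labels if l.class_label == cls_val]
        if len(ids) < 2:
            raise ValueError(f"class {cls_val} has fewer than 2 samples")
        n_train = int(np.floor(train_frac * len(ids)))
        perm = rng.permutation(len(ids))
        train_ids += [ids[i] for i in perm[:n_train]]
        test_ids += [ids[i] for i in perm[n_train:]]
    plan = SplitPlan(train_ids=train_ids, test_ids=test_ids, seed=seed)
    plan.validate()
    return plan


def make_cv_folds(
    train_ids: Sequence[str],
    labels: Sequence[LabelSet],
    k: int = 5,
    stratified: bool = True,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """k validation folds over the training ids (sizes differ by <= 1)."""
    train_ids = list(train_ids)
    if k > len(train_ids):
        raise ValueError(f"k={k} exceeds training size {len(train_ids)}")
    by_id = {l.strain_id: l for l in labels}
    y = np.array([by_id[i].class_label for i in train_ids])
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(len(train_ids)), y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(len(train_ids)))
    folds = []
    for tr_idx, va_idx in split_iter:
        folds.append(
            ([train_ids[i] for i in tr_idx], [train_ids[i] for i in va_idx])
        )
    return folds
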