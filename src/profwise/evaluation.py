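"""Fold planning, the fixed model zoo, and the two performance metrics.

Classification is scored by accuracy ACC = (TP+TN)/(TP+TN+FP+FN); regression
by mean squared error MSE = sum((y_i - yhat_i)^2)/n. Candidate subsets are
evaluated as the unweighted mean of per-fold test scores under a fixed,
stratified (for binary targets) 5-fold plan.

Model hyperparameters are pinned: SVM (C=1, RBF kernel, gamma scaling), LR
(L2, C=1.0), KNN (5 neighbors, Minkowski, uniform weights), RF (100 trees,
Gini), AdaBoost (50 estimators, learning rate 1.0); SVR and RF regressor at
library defaults. Every stochastic component uses random_state=0. Config
strings map onto scikit-learn as follows: "automatic gamma scaling" ->
``gamma="scale"``; "Minkowski" -> ``metric="minkowski"`` (p=2); "SAMME.R" ->
the library's current (and only) real-valued boosting implementation — the
``algorithm`` switch no longer exists; "L2 penalty" -> ``l1_ratio=0.0``.

Features handed to a model are standardized on the training fold only
(fit on train, apply to test) so no test-fold information leaks into
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, SVR

from .io_transforms import ExpressionMatrix, TargetVector

CLASSIFIER_ORDER = ("SVM", "LR", "KNN", "RF", "AdaBoost")
REGRESSOR_ORDER = ("SVR", "RF")


@dataclass
class ConfusionCounts:
    """Binary confusion-table counts."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("confusion counts must total at least 1")


def accuracy(c: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (TP + TN + FP + FN)."""
    total = c.TP + c.TN + c.FP + c.FN
    return (c.TP + c.TN) / total


def mean_squared_error(actual, predicted) -> float:
    """MSE = mean of squared prediction errors."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {actual.shape} vs {predicted.shape}"
        )
    if actual.size < 1:
        raise ValueError("need at least one observation")
    return float(np.mean((actual - predicted) ** 2))


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """A fixed assignment of samples to CV folds.

    ``assignments[i]`` is the fold whose *test* set holds sample i; test
    sets therefore partition the samples.
    """

    n_folds: int
    assignments: np.ndarray
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        found = set(self.assignments.tolist())
        if found != set(range(self.n_folds)):
            raise ValueError(
                f"assignments must cover folds 0..{self.n_folds - 1}, got {sorted(found)}"
            )

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def __iter__(self):
        for fold in range(self.n_folds):
            yield self.train_indices(fold), self.test_indices(fold)


def make_folds(
    target: TargetVector,
    n_folds: int = 5,
    seed: int = 0,
    stratify_labels: np.ndarray | None = None,
) -> FoldPlan:
    """Build a deterministic fold plan over the samples of ``target``.

    Binary targets get stratified folds (each fold's class counts within 1
    of the proportional share). Continuous targets get plain shuffled folds
    unless ``stratify_labels`` supplies a per-sample categorical label to
    stratify on (e.g. a methylation-status column accompanying a regression
    task).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = len(target)
    labels = None
    if target.kind == "binary":
        labels = target.binary_codes()
        if (labels < 0).any():
            raise ValueError(
                "make_folds on a binary target requires all statuses known; "
                "drop unknown samples first"
            )
    elif stratify_labels is not None:
        labels = np.asarray(stratify_labels)

    assignments = np.empty(n, dtype=int)
    if labels is not None:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples; needs >= {n_folds}"
            )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)), labels)
        stratified = True
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)))
        stratified = False
    for fold, (_, test) in enumerate(split):
        assignments[test] = fold
    return FoldPlan(n_folds, assignments, stratified, seed)


# ---------------------------------------------------------------------------
# Model zoo
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """The fixed model set for a task, with the pinned hyperparameters."""

    task: str  # "classification" | "regression"
    random_state: int = 0
    model_names: tuple = field(init=False)

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        object.__setattr__(
            self,
            "model_names",
            CLASSIFIER_ORDER if self.task == "classification" else REGRESSOR_ORDER,
        )

    def build(self, name: str):
        rs = self.random_state
        factories = {
            "SVM": lambda: SVC(C=1.0, kernel="rbf", gamma="scale", random_state=rs),
            "LR": lambda: LogisticRegression(
                l1_ratio=0.0, C=1.0, random_state=rs, max_iter=1000
            ),
            "KNN": lambda: KNeighborsClassifier(
                n_neighbors=5, metric="minkowski", weights="uniform"
            ),
            "RF": lambda: (
                RandomForestClassifier(
                    n_estimators=100, criterion="gini", random_state=rs
                )
                if self.task == "classification"
                else RandomForestRegressor(random_state=rs)
            ),
            "AdaBoost": lambda: AdaBoostClassifier(
                n_estimators=50, learning_rate=1.0, random_state=rs
            ),
            "SVR": lambda: SVR(),
        }
        if name not in self.model_names:
            raise KeyError(f"model {name!r} not in task {self.task!r}")
        return factories[name]()


# ---------------------------------------------------------------------------
# Subset evaluation
# ---------------------------------------------------------------------------


def _fold_standardize(train: np.ndarray, test: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (train - mean) / safe, (test - mean) / safe


def evaluate_subset(
    matrix: ExpressionMatrix,
    target: TargetVector,
    subset,
    models: ModelConfig,
    plan: FoldPlan,
    per_fold: bool = False,
):
    """Mean cross-validated score per model for one candidate feature subset.

    Each model is trained on every fold's training rows (restricted to the
    subset, standardized on the training rows) and scored on the fold's
    test rows — ACC for classification, MSE for regression. Returns
    {model: mean score}; with ``per_fold=True`` also returns the
    {model: [fold scores]} breakdown.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("cannot evaluate an empty feature subset")
    values = matrix.columns(subset)  # canonical column order: order-invariant
    yv = target.numeric()
    if target.kind == "binary" and (yv < 0).any():
        raise ValueError("evaluate_subset requires known statuses only")

    fold_scores: dict[str, list[float]] = {m: [] for m in models.model_names}
    for fold, (train, test) in enumerate(plan):
        Xtr, Xte = _fold_standardize(values[train], values[test])
        ytr, yte = yv[train], yv[test]
        for name in models.model_names:
            est = models.build(name)
            try:
                est.fit(Xtr, ytr)
                pred = est.predict(Xte)
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"model {name} failed on fold {fold}: {exc}"
                ) from exc
            if models.task == "classification":
                tp = int(((pred == 1) & (yte == 1)).sum())
                tn = int(((pred == 0) & (yte == 0)).sum())
                fp = int(((pred == 1) & (yte == 0)).sum())
                fn = int(((pred == 0) & (yte == 1)).sum())
                score = accuracy(ConfusionCounts(tp, fp, tn, fn))
            else:
                score = mean_squared_error(yte, pred)
            fold_scores[name].append(score)
    means = {m: float(np.mean(s)) for m, s in fold_scores.items()}
    if per_fold:
        return means, fold_scores
    return means


# ---------------------------------------------------------------------------
# Alteration analysis
# ---------------------------------------------------------------------------


def alteration_analysis(
    matrix: ExpressionMatrix, target: TargetVector, band: float = 0.3
) -> pd.DataFrame:
    """Per-feature difference of class-mean expression.

    diff = mean over positive-class samples - mean over negative-class
    samples; a feature is flagged as altered iff |diff| > band (default
    0.3, on the post-transform scale). Rows are sorted by |diff|
    descending and numbered by rank.
    """
    if target.kind != "binary":
        raise ValueError("alteration_analysis requires a binary target")
    codes = target.binary_codes()
    if (codes < 0).any():
        raise ValueError("alteration_analysis requires known statuses only")
    n_pos, n_neg = int((codes == 1).sum()), int((codes == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    mean_pos = matrix.values[codes == 1].mean(axis=0)
    mean_neg = matrix.values[codes == 0].mean(axis=0)
    diff = mean_pos - mean_neg
    df = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "mean_positive": mean_pos,
            "mean_negative": mean_neg,
            "diff": diff,
            "flagged": np.abs(diff) > band,
        }
    )
    df = df.sort_values(
        by=["diff", "feature_id"], key=lambda s: s.abs() if s.name == "diff" else s,
        ascending=[False, True],
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
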