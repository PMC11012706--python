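"""Rank-based fold weighting, threshold sweep and best-subset choice.

The method runs both selectors (LASSO and mRMR) inside every CV fold and
turns the per-fold selections into one integer weight per feature:

    weight(f) = sum over folds [ w_lasso * 1(f in lasso_set)
                               + w_mrmr  * 1(f in mrmr_set) ]

with the two rank assignments {w_lasso, w_mrmr} = {1, 2} tried both ways
(weight 2 marks the selector ranked more effective). With 5 folds the
maximum attainable weight is 5 * (1 + 2) = 15. Sweeping a minimum-weight
threshold k yields nested candidate subsets {f : weight(f) >= k}; each
subset is scored by cross-validated mean ACC (classification) or MSE
(regression) for every model, and the winner is the best score achieved
with the fewest features.

By default the same fold plan drives both selection and evaluation, which
reproduces the single-CV protocol this method was designed around; a
``nested`` evaluation mode re-splits evaluation folds (different seed
stream) for bias-controlled estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (
    FoldPlan,
    ModelConfig,
    evaluate_subset,
    make_folds,
)
from .io_transforms import ExpressionMatrix, TargetVector
from .selectors import LassoConfig, MrmrConfig, lasso_select, mrmr_rank


@dataclass(frozen=True)
class MethodWeights:
    """The rank weights given to the two selectors; always one 1 and one 2."""

    w_lasso: int
    w_mrmr: int

    def __post_init__(self) -> None:
        if {self.w_lasso, self.w_mrmr} != {1, 2}:
            raise ValueError("weights must be exactly {1, 2} in some order")

    @property
    def label(self) -> str:
        return f"lasso{self.w_lasso}_mrmr{self.w_mrmr}"


WEIGHT_ASSIGNMENTS = (MethodWeights(1, 2), MethodWeights(2, 1))


@dataclass
class WeightTable:
    """Accumulated per-feature selection weights across folds; features never
    selected are absent (weight 0 is not stored)."""

    weights: dict[str, int]
    n_folds: int
    weights_used: MethodWeights

    def __post_init__(self) -> None:
        cap = self.n_folds * (self.weights_used.w_lasso + self.weights_used.w_mrmr)
        for f, w in self.weights.items():
            if not 1 <= w <= cap:
                raise ValueError(
                    f"weight {w} for feature {f!r} outside [1, {cap}]"
                )

    @property
    def max_weight(self) -> int:
        return max(self.weights.values()) if self.weights else 0

    def total(self) -> int:
        return sum(self.weights.values())


def accumulate_weights(
    per_fold: list[tuple[set, set]], mw: MethodWeights, n_folds: int
) -> WeightTable:
    """Sum each feature's selection events across folds, weighted by the
    selector that picked it. ``per_fold`` is one (lasso_set, mrmr_set) pair
    per fold."""
    if len(per_fold) != n_folds:
        raise ValueError(f"expected {n_folds} fold selections, got {len(per_fold)}")
    weights: dict[str, int] = {}
    for lasso_set, mrmr_set in per_fold:
        for f in lasso_set:
            weights[f] = weights.get(f, 0) + mw.w_lasso
        for f in mrmr_set:
            weights[f] = weights.get(f, 0) + mw.w_mrmr
    return WeightTable(weights, n_folds, mw)


def subset_at_threshold(wt: WeightTable, k: int) -> set[str]:
    """{f : weight(f) >= k}; empty for k above the maximum observed weight."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {f for f, w in wt.weights.items() if w >= k}


@dataclass
class SweepRow:
    k: int
    subset: frozenset
    n_features: int
    scores: dict[str, float] | None  # None for empty (unevaluated) subsets


@dataclass
class SweepResult:
    """One row per threshold k = 1..max weight, plus the chosen best cell."""

    task: str
    rows: list[SweepRow]
    model_order: tuple
    best: tuple | None = None  # (k, subset, model, score)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"k": r.k, "n_features": r.n_features}
            for m in self.model_order:
                rec[m] = r.scores.get(m) if r.scores else None
            recs.append(rec)
        return pd.DataFrame(recs)


def sweep(wt: WeightTable, evaluator, task: str, model_order) -> SweepResult:
    """Evaluate the nested subsets at every threshold k.

    ``evaluator`` maps a feature set to {model: score}. Identical
    consecutive subsets are scored once and the row reused; empty subsets
    are recorded with size 0 and no scores.
    """
    rows: list[SweepRow] = []
    cache: dict[frozenset, dict[str, float]] = {}
    for k in range(1, wt.max_weight + 1):
        subset = frozenset(subset_at_threshold(wt, k))
        if not subset:
            rows.append(SweepRow(k, subset, 0, None))
            continue
        if subset not in cache:
            try:
                cache[subset] = dict(evaluator(subset))
            except Exception as exc:
                raise RuntimeError(f"evaluation failed at threshold k={k}: {exc}") from exc
        rows.append(SweepRow(k, subset, len(subset), cache[subset]))
    return SweepResult(task, rows, tuple(model_order))


def select_best(sr: SweepResult) -> tuple:
    """Pick (k, subset, model, score): best score, then fewest features,
    then smallest k, then the fixed model order. Classification maximizes
    ACC; regression minimizes MSE."""
    sign = -1.0 if sr.task == "classification" else 1.0
    best_key = None
    best_cell = None
    for row in sr.rows:
        if not row.scores:
            continue
        for mi, model in enumerate(sr.model_order):
            key = (sign * row.scores[model], row.n_features, row.k, mi)
            if best_key is None or key < best_key:
                best_key = key
                best_cell = (row.k, row.subset, model, row.scores[model])
    if best_cell is None:
        raise ValueError("sweep contains no evaluated (non-empty) subsets")
    return best_cell


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class ProfwiseConfig:
    """Run settings for the full selection pipeline."""

    task: str  # "classification" | "regression"
    n_folds: int = 5
    seed: int = 0
    mrmr: MrmrConfig = field(default_factory=MrmrConfig)
    lasso: LassoConfig | None = None  # default depends on task
    nested_evaluation: bool = False

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        if self.lasso is None:
            self.lasso = (
                LassoConfig(penalty=1.0, objective="logistic")
                if self.task == "classification"
                else LassoConfig(penalty=0.1, objective="linear")
            )


@dataclass
class ProfwiseReport:
    """Everything a run produces: per-fold selections, both weight tables,
    both sweep grids, and the overall winner across weight assignments."""

    task: str
    config: ProfwiseConfig
    fold_plan: FoldPlan
    per_fold_selections: list[tuple[set, set]]  # (lasso_set, mrmr_set) per fold
    weight_tables: dict[str, WeightTable]  # keyed by MethodWeights.label
    sweeps: dict[str, SweepResult]
    winner: tuple  # (assignment label, k, subset, model, score)
    gene_symbols: dict[str, str] | None

    @property
    def winning_subset(self) -> frozenset:
        return self.winner[2]

    def winner_summary(self) -> dict:
        label, k, subset, model, score = self.winner
        features = sorted(subset)
        symbols = self.gene_symbols or {}
        return {
            "task": self.task,
            "weight_assignment": label,
            "k": k,
            "model": model,
            "score": score,
            "n_features": len(features),
            "features": features,
            "gene_symbols": {f: symbols[f] for f in features if f in symbols},
        }

    def to_json(self) -> str:
        payload = {
            "winner": self.winner_summary(),
            "fold_assignments": self.fold_plan.assignments.tolist(),
            "per_fold_selections": [
                {"fold": i, "lasso": sorted(l), "mrmr": sorted(m)}
                for i, (l, m) in enumerate(self.per_fold_selections)
            ],
            "weight_tables": {
                label: dict(sorted(wt.weights.items()))
                for label, wt in self.weight_tables.items()
            },
            "sweeps": {
                label: sr.to_frame().to_dict(orient="records")
                for label, sr in self.sweeps.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_profwise(
    matrix: ExpressionMatrix,
    target: TargetVector,
    config: ProfwiseConfig,
    stratify_labels: np.ndarray | None = None,
) -> ProfwiseReport:
    """Execute the full pipeline on a preprocessed matrix.

    For binary targets, samples with unknown status are dropped up front.
    Fold-wise LASSO and mRMR selections are computed once (they do not
    depend on the weight assignment); then, for both rank assignments
    {1,2} and {2,1}, weights are accumulated, the threshold swept, and the
    per-assignment best picked. The overall winner applies the same tie
    rules across the two assignments (score, then fewest features, then
    smaller k, then model order, then assignment order).
    """
    if target.kind == "binary" and target.unknown_mask.any():
        keep = target.known_indices
        matrix = matrix.subset_samples(keep)
        target = target.subset(keep)

    plan = make_folds(target, config.n_folds, config.seed, stratify_labels)

    per_fold: list[tuple[set, set]] = []
    for train, _test in plan:
        Xtr = matrix.subset_samples(train)
        ytr = target.subset(train)
        lasso_set = lasso_select(Xtr, ytr, config.lasso)
        mrmr_set = set(mrmr_rank(Xtr, ytr, config.mrmr))
        per_fold.append((lasso_set, mrmr_set))

    models = ModelConfig(task=config.task)
    eval_plan = (
        make_folds(target, config.n_folds, config.seed + 1, stratify_labels)
        if config.nested_evaluation
        else plan
    )

    memo: dict[frozenset, dict[str, float]] = {}

    def evaluator(subset):
        key = frozenset(subset)
        if key not in memo:  # subsets recur across k and across assignments
            memo[key] = evaluate_subset(matrix, target, subset, models, eval_plan)
        return memo[key]

    weight_tables: dict[str, WeightTable] = {}
    sweeps: dict[str, SweepResult] = {}
    candidates = []
    sign = -1.0 if config.task == "classification" else 1.0
    for ai, mw in enumerate(WEIGHT_ASSIGNMENTS):
        wt = accumulate_weights(per_fold, mw, config.n_folds)
        sr = sweep(wt, evaluator, config.task, models.model_names)
        sr.best = select_best(sr)
        weight_tables[mw.label] = wt
        sweeps[mw.label] = sr
        k, subset, model, score = sr.best
        mi = models.model_names.index(model)
        candidates.append(
            ((sign * score, len(subset), k, mi, ai), (mw.label, k, subset, model, score))
        )
    winner = min(candidates)[1]
    return ProfwiseReport(
        task=config.task,
        config=config,
        fold_plan=plan,
        per_fold_selections=per_fold,
        weight_tables=weight_tables,
        sweeps=sweeps,
        winner=winner,
        gene_symbols=matrix.gene_symbols,
    )
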