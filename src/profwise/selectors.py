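"""Per-fold feature selectors: greedy mRMR ranking and LASSO selection.

mRMR (minimum-redundancy-maximum-relevance) scores a candidate feature X_i
against the target Y and the already-selected set S as

    f(X_i) = I(Y, X_i) - (1/|S|) * sum_{X_s in S} I(X_s, X_i)

and greedily picks the maximizer at every step; the first pick maximizes
relevance alone. The greedy loop is implemented here directly (it is the
method's core primitive) with two interchangeable relevance/redundancy
estimators:

* ``mutual_information`` (default): plug-in mutual information after
  equal-frequency discretization of continuous variables into ``mi_bins``
  bins; binary targets are used as-is.
* ``f_statistic``: ANOVA/regression F statistic for relevance and absolute
  Pearson correlation for redundancy (the classical FCQ-style variant) —
  faster, no discretization.

LASSO selection fits an L1-penalized model on the (internally standardized)
training block and returns the features with coefficient magnitude above
``nonzero_tol``. The linear objective is

    argmin_b ||y - X b||^2 / (2n) + penalty * ||b||_1

on standardized X and y; for binary targets an L1-penalized logistic model
is used with inverse strength C = 1/penalty.

Ties in the greedy mRMR score are broken by ascending feature-ID order so
that identical inputs always give identical rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LogisticRegression

from .io_transforms import ExpressionMatrix, TargetVector

RELEVANCE_ESTIMATORS = ("mutual_information", "f_statistic")

# Greedy scores within this absolute margin of the step maximum count as
# tied (and break by ascending feature ID). Float summation order can
# perturb mathematically equal scores by ~1e-16; 1e-9 sits far above that
# noise and far below any scientifically meaningful score difference.
TIE_TOL = 1e-9


@dataclass(frozen=True)
class MrmrConfig:
    """Greedy mRMR settings: how many features to rank per fold and which
    relevance/redundancy estimator to use."""

    n_select: int = 50
    relevance_estimator: str = "mutual_information"
    mi_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.relevance_estimator not in RELEVANCE_ESTIMATORS:
            raise ValueError(
                f"relevance_estimator must be one of {RELEVANCE_ESTIMATORS}"
            )
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")


@dataclass(frozen=True)
class LassoConfig:
    """L1 selection settings. ``penalty`` is the regularization strength
    (lambda); for the logistic objective the model is fit with C = 1/penalty.
    """

    penalty: float = 1.0
    objective: str = "logistic"  # "linear" | "logistic"
    nonzero_tol: float = 1e-10
    max_iter: int = 3000

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("penalty must be > 0")
        if self.objective not in ("linear", "logistic"):
            raise ValueError("objective must be 'linear' or 'logistic'")
        if self.nonzero_tol < 0:
            raise ValueError("nonzero_tol must be >= 0")


# ---------------------------------------------------------------------------
# Discretization and mutual information
# ---------------------------------------------------------------------------


def equal_frequency_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize a 1-D array into at most ``bins`` equal-frequency codes.

    Quantile edges with ties collapsed; values on an edge go to the upper
    bin (np.searchsorted side='right' on interior edges). A constant vector
    maps to a single code.
    """
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


def _codes_matrix(values: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise equal-frequency codes; returns (codes, n_levels per col)."""
    n, p = values.shape
    codes = np.empty((n, p), dtype=np.int64)
    levels = np.empty(p, dtype=np.int64)
    for j in range(p):
        c = equal_frequency_codes(values[:, j], bins)
        codes[:, j] = c
        levels[j] = c.max() + 1
    return codes, levels


def mutual_information_vs_all(
    ref: np.ndarray, n_ref_levels: int, codes: np.ndarray, levels: np.ndarray
) -> np.ndarray:
    """Plug-in MI (nats) between one discrete vector and every column of a
    discrete code matrix, via a single vectorized contingency count."""
    n, p = codes.shape
    max_lv = int(levels.max())
    joint = codes * n_ref_levels + ref[:, None]  # per-column joint cell index
    width = max_lv * n_ref_levels
    flat = joint + np.arange(p, dtype=np.int64) * width
    counts = np.bincount(flat.ravel(), minlength=p * width).reshape(
        p, max_lv, n_ref_levels
    )
    pxy = counts / n
    px = pxy.sum(axis=2, keepdims=True)
    py = pxy.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * (np.log(pxy) - np.log(px) - np.log(py))
    return np.where(counts > 0, terms, 0.0).sum(axis=(1, 2))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) between two discrete code vectors."""
    nx, ny = int(x.max()) + 1, int(y.max()) + 1
    return float(
        mutual_information_vs_all(
            np.asarray(y, dtype=np.int64), ny,
            np.asarray(x, dtype=np.int64)[:, None], np.array([nx]),
        )[0]
    )


# ---------------------------------------------------------------------------
# mRMR greedy ranking
# ---------------------------------------------------------------------------


def _target_codes(y: TargetVector, bins: int) -> tuple[np.ndarray, int]:
    if y.kind == "binary":
        codes = y.binary_codes()
        if (codes < 0).any():
            raise ValueError("mrmr_rank requires a target without unknowns")
        return codes.astype(np.int64), 2
    vals = y.numeric()
    codes = equal_frequency_codes(vals, bins)
    return codes.astype(np.int64), int(codes.max()) + 1


def _f_relevance(values: np.ndarray, y: TargetVector) -> np.ndarray:
    """F-statistic relevance: two-sample ANOVA F for binary targets,
    univariate regression F for continuous ones (zero-variance features
    score 0, never error)."""
    n = values.shape[0]
    sd = values.std(axis=0)
    ok = sd > 0
    rel = np.zeros(values.shape[1])
    if y.kind == "binary":
        codes = y.binary_codes()
        a, b = values[codes == 1], values[codes == 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = stats.f_oneway(a, b).statistic
        rel[ok] = np.nan_to_num(f, nan=0.0, posinf=0.0)[ok]
    else:
        yv = y.numeric()
        yc = yv - yv.mean()
        xc = values - values.mean(axis=0)
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc * yc[:, None]).sum(axis=0) / denom
        r2 = np.nan_to_num(r, nan=0.0) ** 2
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        rel[ok] = (r2 * (n - 2) / (1.0 - r2))[ok]
    return rel


def mrmr_rank(
    X: ExpressionMatrix, y: TargetVector, cfg: MrmrConfig | None = None
) -> list[str]:
    """Greedy mRMR ranking: returns ``cfg.n_select`` feature IDs in
    selection order.

    Step 1 maximizes relevance I(Y, X_i); each later step maximizes
    relevance minus the mean redundancy to the already-selected set. Score
    ties break by ascending feature ID.
    """
    cfg = cfg or MrmrConfig()
    if cfg.n_select > X.n_features:
        raise ValueError(
            f"n_select={cfg.n_select} exceeds n_features={X.n_features}"
        )
    if y.unknown_mask.any():
        raise ValueError("mrmr_rank requires a target without unknowns")
    values = X.values
    ids = np.array(X.feature_ids)

    if cfg.relevance_estimator == "mutual_information":
        codes, levels = _codes_matrix(values, cfg.mi_bins)
        ycodes, ylv = _target_codes(y, cfg.mi_bins)
        relevance = mutual_information_vs_all(ycodes, ylv, codes, levels)

        def redundancy_with(j: int) -> np.ndarray:
            return mutual_information_vs_all(
                codes[:, j], int(levels[j]), codes, levels
            )
    else:
        relevance = _f_relevance(values, y)
        sd = values.std(axis=0)
        xc = (values - values.mean(axis=0))
        norm = np.where(sd > 0, np.sqrt((xc**2).sum(axis=0)), 1.0)
        xn = xc / norm

        def redundancy_with(j: int) -> np.ndarray:
            if sd[j] == 0:
                return np.zeros(len(ids))
            return np.abs(xn.T @ xn[:, j])

    p = X.n_features
    selected: list[int] = []
    remaining = np.ones(p, dtype=bool)
    red_sum = np.zeros(p)

    for step in range(cfg.n_select):
        score = relevance if step == 0 else relevance - red_sum / step
        cand = np.flatnonzero(remaining)
        best_score = score[cand].max()
        tied = cand[score[cand] >= best_score - TIE_TOL]
        j = tied[np.argmin(ids[tied])] if len(tied) > 1 else tied[0]
        selected.append(int(j))
        remaining[j] = False
        if step + 1 < cfg.n_select:
            red_sum += redundancy_with(int(j))
    return [str(ids[j]) for j in selected]


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------


def _standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize (population sd); returns (standardized, sd)."""
    mean = a.mean(axis=0)
    sd = a.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (a - mean) / safe, sd


def lasso_select(
    X: ExpressionMatrix, y: TargetVector, cfg: LassoConfig | None = None
) -> set[str]:
    """L1-penalized selection on the training block.

    Standardizes X (and y, for the linear objective) internally, fits the
    penalized model and returns the features whose coefficient magnitude
    exceeds ``cfg.nonzero_tol``. Zero-variance columns can never be
    selected. Solver non-convergence downgrades to a warning and the
    current nonzero set is returned.
    """
    cfg = cfg or LassoConfig()
    if y.unknown_mask.any():
        raise ValueError("lasso_select requires a target without unknowns")
    Xs, sd = _standardize(X.values)
    ids = np.array(X.feature_ids)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if cfg.objective == "linear":
            yv = y.numeric().astype(float)
            ysd = yv.std()
            ys = (yv - yv.mean()) / (ysd if ysd > 0 else 1.0)
            model = Lasso(
                alpha=cfg.penalty, fit_intercept=False, max_iter=cfg.max_iter
            )
            model.fit(Xs, ys)
            coef = model.coef_
        else:
            codes = y.binary_codes()
            model = LogisticRegression(
                l1_ratio=1.0,
                solver="liblinear",
                C=1.0 / cfg.penalty,
                random_state=0,
                max_iter=cfg.max_iter,
            )
            model.fit(Xs, codes)
            coef = model.coef_.ravel()
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            warnings.warn(
                "LASSO solver did not converge within "
                f"{cfg.max_iter} iterations; returning current nonzero set",
                UserWarning,
                stacklevel=2,
            )
            break

    nz = (np.abs(coef) > cfg.nonzero_tol) & (sd > 0)
    return set(map(str, ids[nz]))
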