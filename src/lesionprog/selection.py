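"""Linear prognostic models and LOOCV-driven feature selection.

The model class is ordinary multivariate linear regression (with
intercept).  Model search is an iterated combination of forward selection
and backwards elimination over the predictor-table columns, seeded with
time post-stroke and driven by leave-one-out cross-validated prediction
error (mean absolute error by default).  A separate sampler draws random
feature sets for the robustness ensemble.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Accepted steps must improve the criterion by more than this (absolute);
#: prevents cycling on numerical ties.
IMPROVEMENT_TOL = 1e-9

DEFAULT_SEED_FEATURES = ("time_post_stroke_months",)


class DegenerateFoldWarning(UserWarning):
    """LOOCV fold had fewer rows than features; minimum-norm fit used."""


def fit_linear_model(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares fit of ``y`` on ``X`` with an intercept.

    Returns ``(intercept, coefficients)``.  For rank-deficient designs the
    minimum-norm solution is returned (so a duplicated predictor column
    splits its weight equally across the duplicates).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if y.shape[0] < 1:
        raise ValueError("cannot fit on empty data")
    A = np.column_stack([np.ones(X.shape[0]), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(beta[0]), beta[1:]


def predict_linear(intercept: float, coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    return intercept + np.atleast_2d(np.asarray(X, dtype=float)) @ np.asarray(coef)


def loocv_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out predictions: patient i predicted by a model fit
    without patient i.

    Uses the exact hat-matrix identity ``e_loo = e / (1 - h_ii)`` when the
    intercept-augmented design has full column rank (identical to
    refitting each fold, to floating-point precision), and falls back to
    explicit minimum-norm refits otherwise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("LOOCV needs at least 2 rows")
    # standardize columns: leaves least-squares predictions (and the hat
    # matrix) unchanged but makes the rank check scale-free
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    A = np.column_stack([np.ones(n), Xs])
    p = A.shape[1]
    if n > p:
        Q, R = np.linalg.qr(A, mode="reduced")
        diag = np.abs(np.diag(R))
        if diag.min() > max(n, p) * np.finfo(float).eps * max(diag.max(), 1.0):
            h = np.einsum("ij,ij->i", Q, Q)
            if h.max() < 1.0 - 1e-12:
                resid = y - Q @ (Q.T @ y)
                return y - resid / (1.0 - h)
    else:
        warnings.warn(
            f"LOOCV with n={n} rows and {p} parameters: folds are "
            "under-determined; minimum-norm fits used",
            DegenerateFoldWarning,
            stacklevel=2,
        )
    # rank-deficient or under-determined: minimum-norm refits on the
    # original (unscaled) design, matching fit_linear_model's convention
    return _loocv_refit(np.column_stack([np.ones(n), X]), y)


def _loocv_refit(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = y.shape[0]
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        beta, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        out[i] = A[i] @ beta
    return out


def selection_criterion(predictions: np.ndarray, y: np.ndarray, kind: str = "mae") -> float:
    """Prediction-error criterion: mean absolute error (default) or RMSE."""
    predictions = np.asarray(predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if predictions.shape != y.shape:
        raise ValueError("predictions and y must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    err = predictions - y
    if kind == "mae":
        return float(np.mean(np.abs(err)))
    if kind == "rmse":
        return float(np.sqrt(np.mean(err**2)))
    raise ValueError(f"unknown criterion {kind!r}")


@dataclass
class SelectionStep:
    phase: str  # "forward" | "backward" | "seed"
    action: str  # "add" | "remove" | "start"
    feature: str | None
    criterion: float


@dataclass
class PrognosticModel:
    """A fitted linear prognostic model for one task."""

    task: str
    features: list[str]
    intercept: float
    coefficients: np.ndarray
    criterion: float
    criterion_kind: str = "mae"
    training_group: str = "a"
    trace: list[SelectionStep] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=float)
        return predict_linear(self.intercept, self.coefficients, X)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "task": self.task,
            "features": self.features,
            "intercept": self.intercept,
            "coefficients": np.asarray(self.coefficients).tolist(),
            "criterion": self.criterion,
            "criterion_kind": self.criterion_kind,
            "training_group": self.training_group,
            "trace": [
                {"phase": s.phase, "action": s.action, "feature": s.feature, "criterion": s.criterion}
                for s in self.trace
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PrognosticModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            task=d["task"],
            features=list(d["features"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            criterion=float(d["criterion"]),
            criterion_kind=d.get("criterion_kind", "mae"),
            training_group=d.get("training_group", "a"),
            trace=[SelectionStep(**s) for s in d.get("trace", [])],
        )


def _evaluate(table_arr: np.ndarray, cols: list[int], y: np.ndarray, kind: str) -> float:
    preds = loocv_predictions(table_arr[:, cols], y)
    return selection_criterion(preds, y, kind)


def select_features(
    table: pd.DataFrame,
    y: pd.Series | np.ndarray,
    seed_features: Sequence[str] = DEFAULT_SEED_FEATURES,
    criterion: str = "mae",
    task: str = "",
    candidates: Sequence[str] | None = None,
    tol: float = IMPROVEMENT_TOL,
) -> PrognosticModel:
    """Iterated forward-selection / backwards-elimination model search.

    Starting from ``seed_features`` (time post-stroke by default), the
    forward phase repeatedly adds the candidate whose addition most
    reduces the LOOCV criterion, until no addition improves it; the
    backward phase repeatedly removes the member whose removal most
    reduces the criterion; the two-phase cycle repeats until a full cycle
    changes nothing.  Steps are accepted only if they improve the
    criterion by more than ``tol`` and ties between candidates break to
    the lowest column index, so the trace criterion is strictly
    decreasing and the search terminates.  Rows where ``y`` is missing are
    dropped (complete-case per task); zero-variance candidate columns
    within that subset are skipped.  The seed feature is not protected
    from elimination.
    """
    y_ser = pd.Series(y, index=table.index) if not isinstance(y, pd.Series) else y
    mask = y_ser.notna()
    if not mask.any():
        raise ValueError("y is entirely missing")
    sub = table.loc[mask]
    yv = y_ser.loc[mask].to_numpy(dtype=float)

    labels = list(table.columns)
    col_of = {name: i for i, name in enumerate(labels)}
    for f in seed_features:
        if f not in col_of:
            raise ValueError(f"seed feature {f!r} not in table")
    cand_names = list(candidates) if candidates is not None else labels
    arr = sub.to_numpy(dtype=float)
    variable = arr.std(axis=0) > 0
    cand_cols = [col_of[c] for c in cand_names if variable[col_of[c]]]

    current = [col_of[f] for f in seed_features]
    crit = _evaluate(arr, current, yv, criterion)
    trace = [SelectionStep("seed", "start", None, crit)]

    changed_in_cycle = True
    while changed_in_cycle:
        changed_in_cycle = False
        # forward phase
        while True:
            best_col, best_crit = None, crit
            in_set = set(current)
            for c in cand_cols:
                if c in in_set:
                    continue
                val = _evaluate(arr, current + [c], yv, criterion)
                if val < best_crit - tol:
                    best_col, best_crit = c, val
            if best_col is None:
                break
            current.append(best_col)
            crit = best_crit
            trace.append(SelectionStep("forward", "add", labels[best_col], crit))
            changed_in_cycle = True
        # backward phase
        while len(current) > 1:
            best_j, best_crit = None, crit
            for j, c in enumerate(current):
                trial = current[:j] + current[j + 1 :]
                val = _evaluate(arr, trial, yv, criterion)
                if val < best_crit - tol:
                    best_j, best_crit = j, val
            if best_j is None:
                break
            removed = current.pop(best_j)
            crit = best_crit
            trace.append(SelectionStep("backward", "remove", labels[removed], crit))
            changed_in_cycle = True

    intercept, coef = fit_linear_model(arr[:, current], yv)
    return PrognosticModel(
        task=task,
        features=[labels[c] for c in current],
        intercept=intercept,
        coefficients=coef,
        criterion=crit,
        criterion_kind=criterion,
        trace=trace,
    )


def sample_random_feature_sets(
    n_models: int,
    size_range: tuple[int, int],
    labels: Sequence[str],
    seed: int,
) -> list[list[str]]:
    """Draw random feature sets for the robustness ensemble.

    Sizes are uniform over ``size_range`` (inclusive) and members are
    drawn uniformly without replacement from ``labels``; default usage is
    sizes 2-40 over all predictor-table columns.  Reproducible from
    ``seed``.
    """
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(labels)):
        raise ValueError(f"size_range {size_range} invalid for {len(labels)} labels")
    rng = np.random.default_rng(seed)
    labels = list(labels)
    sizes = rng.integers(lo, hi + 1, size=n_models)
    return [list(rng.choice(labels, size=int(s), replace=False)) for s in sizes]
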