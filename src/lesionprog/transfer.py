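"""Cross-group transfer of prognostic models and group-difference tests.

The reference group ("a") is predicted by leave-one-out cross-validation;
the transfer group ("b") is predicted in a single pass by a model trained
on all of group a.  Prediction error is predicted minus actual, so a
positive error means the model overestimates the patient's ability.
Per-task error shifts between groups are tested with independent-samples
t-tests (equal variance after a Levene pre-check) and family-wise error
across tasks is controlled by min-p/max-statistic permutation of the
group labels.  A random-feature-set ensemble checks that shifts are not
artefacts of model selection, and a screen relates language-history
fields to prediction errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .selection import (
    PrognosticModel,
    fit_linear_model,
    loocv_predictions,
    predict_linear,
)

GROUP_A = "a"
GROUP_B = "b"


# ---------------------------------------------------------------------------
# Prediction transfer
# ---------------------------------------------------------------------------

def _features_of(model: PrognosticModel | Sequence[str]) -> list[str]:
    if isinstance(model, PrognosticModel):
        return list(model.features)
    return list(model)


def transfer_predict(
    models_by_task: Mapping[str, PrognosticModel | Sequence[str]],
    table_a: pd.DataFrame,
    scores_a: pd.DataFrame,
    table_b: pd.DataFrame,
    scores_b: pd.DataFrame,
) -> pd.DataFrame:
    """Predict both groups for every task and return prediction records.

    Group-a predictions come from LOOCV over group a's complete cases;
    group-b predictions come from one model fitted on all of group a's
    complete cases.  Returns one row per (patient, task) with columns
    ``patient, task, group, predicted, actual, error``.
    """
    if list(table_a.columns) != list(table_b.columns):
        raise ValueError("group predictor tables must share an identical header")
    frames = []
    for task, model in models_by_task.items():
        feats = _features_of(model)
        missing = [f for f in feats if f not in table_a.columns]
        if missing:
            raise ValueError(f"features not in predictor table: {missing}")
        ya = scores_a[task]
        yb = scores_b[task]
        ca = ya.notna()
        cb = yb.notna()
        Xa = table_a.loc[ca, feats].to_numpy(dtype=float)
        yav = ya.loc[ca].to_numpy(dtype=float)
        pred_a = loocv_predictions(Xa, yav)
        intercept, coef = fit_linear_model(Xa, yav)
        Xb = table_b.loc[cb, feats].to_numpy(dtype=float)
        pred_b = predict_linear(intercept, coef, Xb)
        frames.append(
            pd.DataFrame(
                {
                    "patient": list(table_a.index[ca]) + list(table_b.index[cb]),
                    "task": task,
                    "group": [GROUP_A] * int(ca.sum()) + [GROUP_B] * int(cb.sum()),
                    "predicted": np.concatenate([pred_a, pred_b]),
                    "actual": np.concatenate([yav, yb.loc[cb].to_numpy(dtype=float)]),
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records["error"] = records["predicted"] - records["actual"]
    return records


def errors_by_task(records: pd.DataFrame) -> dict[str, pd.Series]:
    """Split prediction records into per-task error Series indexed by patient."""
    out = {}
    for task, grp in records.groupby("task", sort=False):
        out[str(task)] = pd.Series(grp["error"].to_numpy(), index=pd.Index(grp["patient"], name="patient"))
    return out


# ---------------------------------------------------------------------------
# Descriptive tests
# ---------------------------------------------------------------------------

def independent_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided independent-samples t-test for mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if equal_var and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def t_from_summary(
    n1: int, m1: float, s1: float, n2: int, m2: float, s2: float, equal_var: bool = True
) -> tuple[float, float]:
    """Independent-samples t-test from summary statistics (n, mean, SD)."""
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def levene_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classic (mean-centred) Levene test for equality of variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if np.all(a == a[0]) and np.all(b == b[0]):
        raise ValueError("both samples constant: Levene statistic undefined")
    stat, p = stats.levene(a, b, center="mean")
    return float(stat), float(p)


def wilcoxon_rank_sum(
    a: np.ndarray, b: np.ndarray, method: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, returning (z, p).

    ``z`` is the tie-corrected (midrank) normal deviate of the rank sum of
    ``a``.  ``p`` comes from the normal approximation by default, or from
    exact enumeration of the rank-sum null (``method='exact'``, no ties).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 and n2 == 0:
        raise ValueError("both samples empty")
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    if method == "asymptotic":
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "exact":
        if np.any(counts > 1):
            raise ValueError("exact method requires no ties")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(z), float(min(p, 1.0))


def paired_t(differences: np.ndarray) -> tuple[float, float, float]:
    """Two-sided paired-samples t-test on a vector of differences.

    Returns ``(t, p, mean_diff)``.  Raises on zero-variance differences
    (the statistic is undefined), including the all-zero case.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) < 2:
        raise ValueError("need at least 2 differences")
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue), float(np.mean(d))


# ---------------------------------------------------------------------------
# Permutation family-wise threshold
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Label-permutation null for the family of per-task shift tests."""

    n_perm: int
    seed: int
    alpha: float
    corrected_alpha: float
    min_p: np.ndarray  # per-permutation minimum p across tasks
    t_samples: dict[str, np.ndarray] = field(default_factory=dict)


def _vectorized_shift_t(
    e: np.ndarray, labels_b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """t statistics (mean_b - mean_a) for many label vectors at once.

    ``labels_b`` is (n_perm, n) boolean.  Returns (t, p) with NaN where a
    permutation leaves fewer than 2 patients in a group.
    """
    m = e.shape[0]
    nb = labels_b.sum(axis=1).astype(float)
    na = m - nb
    ok = (nb >= 2) & (na >= 2)
    L = labels_b.astype(float)
    sum_b = L @ e
    sum_b2 = L @ (e**2)
    tot, tot2 = e.sum(), (e**2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_b = sum_b / nb
        mean_a = (tot - sum_b) / na
        ssb = sum_b2 - nb * mean_b**2
        ssa = (tot2 - sum_b2) - na * mean_a**2
        if equal_var:
            pooled = (ssa + ssb) / (m - 2)
            se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
            df = np.full(nb.shape, m - 2.0)
        else:
            va = ssa / (na - 1)
            vb = ssb / (nb - 1)
            se = np.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        t = (mean_b - mean_a) / se
    t = np.where(ok & np.isfinite(t), t, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def permutation_familywise_threshold(
    errors: Mapping[str, pd.Series],
    groups: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    equal_var: bool | Mapping[str, bool] = True,
) -> PermutationNull:
    """Min-p/max-statistic permutation threshold over the task family.

    Each permutation shuffles the pooled cohort's group labels once and
    recomputes every per-task shift t-test on the labels induced on that
    task's complete cases, preserving the dependence between tasks.  The
    corrected per-test alpha is the largest alpha at which the fraction of
    permutations whose minimum per-task p falls below it stays within the
    nominal ``alpha`` (the k-th smallest min-p, k = floor(alpha*n_perm)),
    capped at the nominal level.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse null; use >= 100", UserWarning, stacklevel=2
        )
    for task, e in errors.items():
        vc = groups.loc[e.index].value_counts()
        if vc.min() < 2 or len(vc) < 2:
            raise ValueError(f"task {task!r} needs >= 2 patients per group")
    rng = np.random.default_rng(seed)
    pooled = groups.index
    is_b = (groups == GROUP_B).to_numpy()
    n = len(pooled)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    label_mat = is_b[order]  # (n_perm, n) permuted labels

    pos_of = {pid: i for i, pid in enumerate(pooled)}
    min_p = np.full(n_perm, np.inf)
    t_samples: dict[str, np.ndarray] = {}
    for task, e in errors.items():
        cols = np.array([pos_of[pid] for pid in e.index])
        ev = e.to_numpy(dtype=float)
        evar = equal_var[task] if isinstance(equal_var, Mapping) else equal_var
        t, p = _vectorized_shift_t(ev, label_mat[:, cols], evar)
        t_samples[str(task)] = t
        min_p = np.fmin(min_p, np.where(np.isnan(p), np.inf, p))
    min_p = np.where(np.isinf(min_p), np.nan, min_p)
    finite = min_p[~np.isnan(min_p)]
    k = max(1, int(np.floor(alpha * len(finite))))
    corrected = float(np.sort(finite)[k - 1])
    corrected = min(corrected, alpha)
    return PermutationNull(
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        corrected_alpha=corrected,
        min_p=min_p,
        t_samples=t_samples,
    )


# ---------------------------------------------------------------------------
# Per-task shift table (Table-4 layout)
# ---------------------------------------------------------------------------

def shift_tests(
    records: pd.DataFrame,
    corrected_alpha: float | None = 0.05,
    levene_gate: bool = True,
    levene_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-task comparison of group error distributions.

    Positive t means the transfer group's errors are positively shifted
    (the models overestimate its scores).  Equal-variance t is used unless
    a Levene pre-check rejects at ``levene_alpha`` (then Welch).  A task
    is flagged significant iff its nominal p <= ``corrected_alpha``; pass
    ``corrected_alpha=None`` for an uncorrected table (flags NaN).
    """
    rows = []
    for task, grp in records.groupby("task", sort=False):
        ea = grp.loc[grp["group"] == GROUP_A, "error"].to_numpy(dtype=float)
        eb = grp.loc[grp["group"] == GROUP_B, "error"].to_numpy(dtype=float)
        pa = grp.loc[grp["group"] == GROUP_A]
        pb = grp.loc[grp["group"] == GROUP_B]
        equal_var = True
        if levene_gate:
            _, lev_p = levene_test(ea, eb)
            equal_var = lev_p > levene_alpha
        t, p = independent_t(eb, ea, equal_var=equal_var)
        rows.append(
            {
                "task": task,
                "n_a": len(ea),
                "n_b": len(eb),
                "mean_error_a": float(ea.mean()),
                "mean_error_b": float(eb.mean()),
                "mae_a": float(np.abs(ea).mean()),
                "mae_b": float(np.abs(eb).mean()),
                "r_pred_actual_a": _safe_corr(pa["predicted"], pa["actual"]),
                "r_pred_actual_b": _safe_corr(pb["predicted"], pb["actual"]),
                "equal_var": equal_var,
                "t": t,
                "p": p,
                "significant": (p <= corrected_alpha) if corrected_alpha is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _safe_corr(x: pd.Series, y: pd.Series) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Random-model robustness ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Consistency of the error shift across randomly-featured models."""

    fraction_consistent: float  # significant positive shifts / total tests
    n_tests: int
    n_significant_positive: int
    n_significant_negative: int
    per_task: pd.DataFrame  # task, n_models, n_positive, n_negative, fraction


def random_model_consistency(
    random_sets: Sequence[Sequence[str]],
    table_a: pd.DataFrame,
    scores_a: pd.DataFrame,
    table_b: pd.DataFrame,
    scores_b: pd.DataFrame,
    tasks_of_interest: Sequence[str],
    threshold_alpha: float = 0.05,
    equal_var: bool = True,
) -> EnsembleResult:
    """Re-run the transfer shift test for every (random model, task) pair.

    For each random feature set and each flagged task, predictions are
    regenerated (LOOCV for group a, single-pass transfer for group b) and
    the shift t-test recomputed; returns the fraction of tests with a
    significant positive shift at ``threshold_alpha`` (the corrected
    alpha from the best-model analysis), plus the count of significant
    shifts in the opposite direction.
    """
    if len(random_sets) == 0:
        raise ValueError("random_sets must be non-empty")
    prepared = {}
    for task in tasks_of_interest:
        ca = scores_a[task].notna()
        cb = scores_b[task].notna()
        prepared[task] = (
            table_a.loc[ca].to_numpy(dtype=float),
            scores_a.loc[ca, task].to_numpy(dtype=float),
            table_b.loc[cb].to_numpy(dtype=float),
            scores_b.loc[cb, task].to_numpy(dtype=float),
        )
    col_of = {name: i for i, name in enumerate(table_a.columns)}
    n_pos = {t: 0 for t in tasks_of_interest}
    n_neg = {t: 0 for t in tasks_of_interest}
    for feats in random_sets:
        cols = [col_of[f] for f in feats]
        for task in tasks_of_interest:
            Xa, ya, Xb, yb = prepared[task]
            pred_a = loocv_predictions(Xa[:, cols], ya)
            intercept, coef = fit_linear_model(Xa[:, cols], ya)
            pred_b = predict_linear(intercept, coef, Xb[:, cols])
            t, p = independent_t(pred_b - yb, pred_a - ya, equal_var=equal_var)
            if p <= threshold_alpha:
                if t > 0:
                    n_pos[task] += 1
                else:
                    n_neg[task] += 1
    n_models = len(random_sets)
    per_task = pd.DataFrame(
        {
            "task": list(tasks_of_interest),
            "n_models": n_models,
            "n_positive": [n_pos[t] for t in tasks_of_interest],
            "n_negative": [n_neg[t] for t in tasks_of_interest],
        }
    )
    per_task["fraction"] = per_task["n_positive"] / n_models
    total = n_models * len(tasks_of_interest)
    tot_pos = int(per_task["n_positive"].sum())
    tot_neg = int(per_task["n_negative"].sum())
    return EnsembleResult(
        fraction_consistent=tot_pos / total,
        n_tests=total,
        n_significant_positive=tot_pos,
        n_significant_negative=tot_neg,
        per_task=per_task,
    )


# ---------------------------------------------------------------------------
# Language-history screen
# ---------------------------------------------------------------------------

def history_screen(
    history: pd.DataFrame,
    errors: Mapping[str, pd.Series],
    flagged_tasks: Sequence[str] | None = None,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Correlate language-history fields with per-task prediction errors.

    Uses pairwise-complete observations; cells with fewer than
    ``min_pairs`` complete pairs (or a constant field) are skipped and
    logged.  P-values are nominal — the table's ``note`` attribute records
    that no multiplicity correction is applied.
    """
    tasks = list(flagged_tasks) if flagged_tasks is not None else list(errors)
    rows = []
    log: list[str] = []
    for col in history.columns:
        fvals = history[col]
        if fvals.notna().sum() == 0:
            log.append(f"field {col!r}: all missing, skipped")
            continue
        for task in tasks:
            e = errors[task]
            joined = pd.concat([fvals, e], axis=1, join="inner").dropna()
            if len(joined) < min_pairs:
                log.append(f"({col!r}, {task!r}): {len(joined)} complete pairs < {min_pairs}, skipped")
                continue
            x = joined.iloc[:, 0].to_numpy(dtype=float)
            y = joined.iloc[:, 1].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                log.append(f"({col!r}, {task!r}): constant values, skipped")
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"field": col, "task": task, "n": len(joined), "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows, columns=["field", "task", "n", "r", "p"])
    table.attrs["note"] = "nominal p-values; no multiple-comparison correction applied"
    return table, log
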