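"""Region-wise lesion-load/score associations and default Bayes factors.

For every (region, task, group) this module computes the Pearson
correlation between region lesion load and task score over that task's
complete cases, the univariate regression slope (T-score units per %
load), and a default Bayes factor BF10 for the presence of a correlation
versus an intercept-plus-Gaussian-noise null.  BF10 is the JZS-class
g-prior Bayes factor that depends on the data only through (r, n):

    BF10(r, n) = sqrt(n/2) / Gamma(1/2) * ∫_0^∞ (1+g)^((n-2)/2)
                 * (1 + (1-r^2) g)^(-(n-1)/2) * g^(-3/2) * e^(-n/(2g)) dg

evaluated by adaptive quadrature in log space after mapping (0, ∞) to
(0, 1).  Evidence is classified on the Jeffreys convention (>3 / >10
substantial / strong for a correlation; <1/3 / <1/10 the same for the
null).  The convergence screen enumerates the (region, task) cases with
strong evidence in the transfer group and asks whether the reference
group shares them; the slope comparison then contrasts the per-case
univariate slopes across groups with a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

STRONG, SUBSTANTIAL = 10.0, 3.0

EVIDENCE_CATEGORIES = (
    "strong_H1",
    "substantial_H1",
    "inconclusive",
    "substantial_H0",
    "strong_H0",
)


class BayesFactorNumericalError(ArithmeticError):
    """The BF quadrature failed to converge; never silently defaulted."""


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; raises on constant input or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def _log_integrand(u: np.ndarray, n: int, r2: float) -> np.ndarray:
    """Log of the transformed BF integrand on u in (0, 1), g = u/(1-u).

    Includes the Jacobian 1/(1-u)^2 = (1+g)^2.
    """
    g = u / (1.0 - u)
    with np.errstate(divide="ignore"):
        return (
            ((n - 2) / 2.0 + 2.0) * np.log1p(g)
            - ((n - 1) / 2.0) * np.log1p((1.0 - r2) * g)
            - 1.5 * np.log(g)
            - n / (2.0 * g)
        )


def default_bf_correlation(
    r: float, n: int, epsrel: float = 1e-8, limit: int = 200
) -> float:
    """Default Bayes factor BF10 for a correlation, from (r, n) alone.

    Symmetric in the sign of r.  Returns ``inf`` for |r| = 1 (the
    integral diverges: the data are perfectly collinear).  Raises
    :class:`BayesFactorNumericalError` if the quadrature does not
    converge — never a silent default.
    """
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError(f"r must be in [-1, 1], got {r}")
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    r2 = float(r) ** 2
    if r2 >= 1.0:
        return float("inf")

    # scale out the integrand's peak so quad works near log-magnitude 1
    u_grid = np.linspace(1e-8, 1.0 - 1e-10, 2001)
    log_m = float(np.max(_log_integrand(u_grid, n, r2)))

    def f(u: float) -> float:
        return float(np.exp(_log_integrand(np.asarray(u), n, r2) - log_m))

    try:
        val, abserr = integrate.quad(f, 0.0, 1.0, epsrel=epsrel, epsabs=0.0, limit=limit)
    except Exception as exc:  # pragma: no cover - scipy-internal failures
        raise BayesFactorNumericalError(f"quadrature failed for r={r}, n={n}") from exc
    if not np.isfinite(val) or val <= 0 or abserr > max(1e-6 * val, 1e-12):
        raise BayesFactorNumericalError(
            f"quadrature did not converge for r={r}, n={n} (value={val}, err={abserr})"
        )
    log_bf = log_m + np.log(val) + 0.5 * np.log(n / 2.0) - np.log(np.sqrt(np.pi))
    return float(np.exp(log_bf))


def classify_evidence(bf10: float) -> str:
    """Jeffreys evidence category for a Bayes factor.

    strong_H1 (>10), substantial_H1 ((3, 10]), inconclusive ([1/3, 3]),
    substantial_H0 ([1/10, 1/3)), strong_H0 (<1/10).
    """
    if not bf10 > 0:
        raise ValueError(f"Bayes factor must be positive, got {bf10}")
    if bf10 > STRONG:
        return "strong_H1"
    if bf10 > SUBSTANTIAL:
        return "substantial_H1"
    if bf10 >= 1.0 / SUBSTANTIAL:
        return "inconclusive"
    if bf10 >= 1.0 / STRONG:
        return "substantial_H0"
    return "strong_H0"


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

def region_association_table(
    loads: pd.DataFrame,
    scores: pd.DataFrame,
    groups: pd.Series,
    tasks: Sequence[str] | None = None,
    regions: Sequence[str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-(region, task, group) correlation, slope and Bayes factor.

    Complete cases differ per (task, group); ``n`` is reported in every
    row.  Cells where lesion load or score is constant within the group's
    complete cases are omitted (the correlation is undefined there).  No
    multiplicity correction is applied — evidence is read off the
    Jeffreys categories (recorded in the table's ``note`` attribute).
    """
    tasks = list(tasks) if tasks is not None else list(scores.columns)
    regions = list(regions) if regions is not None else list(loads.columns)
    rows = []
    for group in pd.unique(groups):
        g_idx = groups.index[groups == group]
        for task in tasks:
            y = scores.loc[g_idx, task].dropna()
            if len(y) < min_n:
                continue
            L = loads.loc[y.index, regions].to_numpy(dtype=float)
            yv = y.to_numpy(dtype=float)
            n = len(yv)
            y_c = yv - yv.mean()
            sy = y_c.std()
            L_c = L - L.mean(axis=0)
            sx = L_c.std(axis=0)
            cov = (L_c * y_c[:, None]).mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = cov / (sx * sy)
                slope = cov / (sx**2)
            for j, region in enumerate(regions):
                if sx[j] == 0 or sy == 0:
                    continue
                bf = default_bf_correlation(float(np.clip(r[j], -1, 1)), n)
                rows.append(
                    {
                        "region": region,
                        "task": task,
                        "group": group,
                        "n": n,
                        "r": float(r[j]),
                        "slope": float(slope[j]),
                        "bf10": bf,
                        "category": classify_evidence(bf),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["region", "task", "group", "n", "r", "slope", "bf10", "category"]
    )
    table.attrs["note"] = (
        "Jeffreys evidence categories; no multiplicity correction applied"
    )
    return table


@dataclass
class ConvergenceScreen:
    """Shared-vs-divergent screen over strong transfer-group associations."""

    cases: pd.DataFrame  # one row per strong-in-b (region, task): bf_b, bf_a, shared, slopes
    n_strong_b: int
    n_shared: int
    divergent: pd.DataFrame  # strong in b but not in a, with the group-a bf attached


def convergence_screen(
    associations: pd.DataFrame,
    group_a: str = "a",
    group_b: str = "b",
    strong_threshold: float = STRONG,
) -> ConvergenceScreen:
    """Screen: does the reference group share the transfer group's strong
    lesion-deficit associations?

    Enumerates all (region, task) with BF10 > ``strong_threshold`` in the
    transfer group and reports, for each, the reference group's BF10 and
    whether it too exceeds the threshold; the divergent list holds the
    cases strong in b but not in a.
    """
    a = associations[associations["group"] == group_a].set_index(["region", "task"])
    b = associations[associations["group"] == group_b].set_index(["region", "task"])
    strong_b = b[b["bf10"] > strong_threshold]
    rows = []
    for (region, task), row in strong_b.iterrows():
        in_a = (region, task) in a.index
        bf_a = float(a.loc[(region, task), "bf10"]) if in_a else np.nan
        rows.append(
            {
                "region": region,
                "task": task,
                "bf10_b": float(row["bf10"]),
                "bf10_a": bf_a,
                "shared": bool(in_a and bf_a > strong_threshold),
                "slope_b": float(row["slope"]),
                "slope_a": float(a.loc[(region, task), "slope"]) if in_a else np.nan,
                "n_b": int(row["n"]),
                "n_a": int(a.loc[(region, task), "n"]) if in_a else 0,
            }
        )
    cases = pd.DataFrame(
        rows,
        columns=[
            "region", "task", "bf10_b", "bf10_a", "shared",
            "slope_b", "slope_a", "n_b", "n_a",
        ],
    )
    n_strong = len(cases)
    n_shared = int(cases["shared"].sum()) if n_strong else 0
    divergent = cases[~cases["shared"]].copy() if n_strong else cases.copy()
    return ConvergenceScreen(
        cases=cases, n_strong_b=n_strong, n_shared=n_shared, divergent=divergent
    )


@dataclass
class SlopeComparison:
    """Paired comparison of per-case univariate slopes across groups."""

    t: float
    p: float
    df: int
    mean_diff: float  # mean(slope_a - slope_b); positive when b more negative
    degenerate: bool = False


def slope_comparison(cases: pd.DataFrame) -> SlopeComparison:
    """Paired t-test of group slopes over the shared strong cases.

    For each (region, task) case the two groups' univariate slopes of
    score on lesion load are paired; positive t means the transfer
    group's slopes are more negative (steeper deficit per % damage).
    Identical slope pairs give a degenerate (zero-variance) result, which
    is returned explicitly rather than as a spurious statistic.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 shared cases for a paired comparison")
    d = (cases["slope_a"] - cases["slope_b"]).to_numpy(dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("cases with missing slopes cannot be compared")
    if np.var(d, ddof=1) == 0:
        return SlopeComparison(
            t=np.nan, p=np.nan, df=len(d) - 1, mean_diff=float(d.mean()), degenerate=True
        )
    res = stats.ttest_1samp(d, 0.0)
    return SlopeComparison(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=len(d) - 1,
        mean_diff=float(d.mean()),
    )
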