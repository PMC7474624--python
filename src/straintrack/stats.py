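"""Statistical kernel used by every reporting stage of the pipeline.

Implements the tests and estimators the downstream analyses report: Welch and
paired t tests, one-way ANOVA with Tukey's HSD post hoc, ordinary least squares
with an overall F test, Shannon alpha diversity, and mean +/- SE group
summaries. All p-values are two-sided (or upper-tail for F-type statistics).

The functions here are deliberately small wrappers around well-tested scipy
primitives, with explicit handling of the degenerate inputs a screening
pipeline actually produces (identical groups, zero-variance differences,
constant predictors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InputError

__all__ = [
    "TestResult",
    "RegressionResult",
    "welch_t_test",
    "pooled_t_test",
    "paired_t_test",
    "one_way_anova",
    "tukey_hsd",
    "linear_regression_f",
    "shannon_diversity",
    "group_summary",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` is a float for t-type tests and a ``(df1, df2)`` pair for F-type
    tests. ``effect`` is a difference of means for two-sample tests, the mean
    paired difference for the paired test, and eta-squared (between-group share
    of total variance) for ANOVA, where no single mean difference exists.
    """

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect: float
    label: str = ""

    def as_dict(self) -> dict:
        df = self.df
        return {
            "statistic": self.statistic,
            "df": df if np.isscalar(df) else f"{df[0]:g},{df[1]:g}",
            "p_value": self.p_value,
            "effect": self.effect,
            "label": self.label,
        }


@dataclass
class RegressionResult:
    """Simple-OLS fit of y on x with the overall F test on the slope."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int = 0
    label: str = ""


def _as_1d(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def welch_t_test(x: Sequence[float], y: Sequence[float], *, label: str = "") -> TestResult:
    """Two-sided two-sample t test with Welch-Satterthwaite degrees of freedom.

    ``effect`` is ``mean(x) - mean(y)``. Raises :class:`DegenerateDataError`
    when both samples have zero variance (no scale against which to test).
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise InputError("each sample needs at least 2 observations")
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    effect = float(x.mean() - y.mean())
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        raise DegenerateDataError("both samples have zero variance")
    t = effect / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, effect, label or "welch t test")


def pooled_t_test(x: Sequence[float], y: Sequence[float], *, label: str = "") -> TestResult:
    """Classic equal-variance two-sample t test (available where Welch is not wanted)."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise InputError("each sample needs at least 2 observations")
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        raise DegenerateDataError("pooled variance is zero")
    effect = float(x.mean() - y.mean())
    t = effect / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, effect, label or "pooled t test")


def paired_t_test(pre: Sequence[float], post: Sequence[float], *, label: str = "") -> TestResult:
    """One-sample t test on per-pair differences ``post - pre``, two-sided.

    Identical vectors (all differences exactly zero) return t=0, p=1; a
    constant *nonzero* difference has no variance to scale by and raises
    :class:`DegenerateDataError`.
    """
    pre, post = _as_1d(pre, "pre"), _as_1d(post, "post")
    if len(pre) != len(post):
        raise InputError("paired samples must have equal length")
    if len(pre) < 2:
        raise InputError("need at least 2 pairs")
    d = post - pre
    effect = float(d.mean())
    sd = d.std(ddof=1)
    df = len(d) - 1
    if sd == 0.0:
        if effect == 0.0:
            return TestResult(0.0, float(df), 1.0, 0.0, label or "paired t test")
        raise DegenerateDataError("differences are constant and nonzero")
    t = effect / (sd / np.sqrt(len(d)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, effect, label or "paired t test")


def _anova_ss(groups: list[np.ndarray]):
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return float(ssb), float(ssw), len(all_v)


def one_way_anova(groups: Sequence[Sequence[float]], *, label: str = "") -> TestResult:
    """One-way fixed-effects ANOVA; F with (g-1, N-g) df, upper-tail p.

    ``effect`` is eta-squared. Identical groups give F=0, p=1.
    """
    gs = [_as_1d(g, "group") for g in groups]
    if len(gs) < 2:
        raise InputError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise InputError("every group needs at least 2 observations")
    ssb, ssw, n = _anova_ss(gs)
    df1, df2 = len(gs) - 1, n - len(gs)
    sst = ssb + ssw
    if ssw == 0.0:
        if ssb == 0.0:
            raise DegenerateDataError("all observations identical")
        return TestResult(float("inf"), (df1, df2), 0.0, 1.0, label or "one-way ANOVA")
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    eta2 = ssb / sst if sst > 0 else 0.0
    return TestResult(float(f), (float(df1), float(df2)), p, float(eta2), label or "one-way ANOVA")


def tukey_hsd(groups: Sequence[Sequence[float]], names: Sequence[str] | None = None) -> list[TestResult]:
    """All-pairs comparisons with Tukey's honestly-significant-difference correction.

    The statistic reported per pair is the studentized range
    ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` with the ANOVA
    within-group mean square; adjusted p-values come from the studentized-range
    distribution with ``(g, N-g)`` parameters (Tukey-Kramer for unequal n).
    """
    gs = [_as_1d(g, "group") for g in groups]
    if len(gs) < 2:
        raise InputError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise InputError("every group needs at least 2 observations")
    if names is None:
        names = [f"g{i}" for i in range(len(gs))]
    _, ssw, n = _anova_ss(gs)
    g = len(gs)
    df2 = n - g
    msw = ssw / df2
    if msw == 0.0:
        raise DegenerateDataError("zero within-group variance")
    out: list[TestResult] = []
    for i in range(g):
        for j in range(i + 1, g):
            diff = float(gs[i].mean() - gs[j].mean())
            se = np.sqrt(msw / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, g, df2), 0.0, 1.0))
            out.append(TestResult(float(q), float(df2), p, diff, f"{names[i]} vs {names[j]} (Tukey HSD)"))
    return out


def linear_regression_f(x: Sequence[float], y: Sequence[float], *, label: str = "") -> RegressionResult:
    """Ordinary least squares of y on x with R-squared and the overall F test.

    F has (1, n-2) degrees of freedom and equals the squared slope t statistic.
    A constant response gives slope 0, R-squared 0, p 1. Refuses constant x and
    fewer than 3 distinct points.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    if len(x) < 3:
        raise InputError("need at least 3 observations")
    if np.unique(np.column_stack([x, y]), axis=0).shape[0] <= 2:
        raise InputError("need more than 2 distinct (x, y) points")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0.0:
        raise InputError("x is constant; slope undefined")
    syy = ((y - y.mean()) ** 2).sum()
    n = len(x)
    if syy == 0.0:
        return RegressionResult(0.0, float(y.mean()), 0.0, 0.0, 1.0, n, label)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    ss_res = syy - slope * sxy
    r2 = float(np.clip(1.0 - ss_res / syy, 0.0, 1.0))
    df2 = n - 2
    if ss_res <= 0.0:
        return RegressionResult(float(slope), float(intercept), 1.0, float("inf"), 0.0, n, label)
    f = (syy - ss_res) / (ss_res / df2)
    p = float(sps.f.sf(f, 1, df2))
    return RegressionResult(float(slope), float(intercept), r2, float(f), p, n, label)


def shannon_diversity(abundances: Sequence[float]) -> float:
    """Shannon index H = -sum p_i ln p_i of a (re-normalized) abundance vector.

    Zeros are skipped; natural log. H is 0 for a single taxon and ln(S) for a
    uniform community of S taxa.
    """
    a = _as_1d(abundances, "abundances")
    if np.any(a < 0):
        raise InputError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise InputError("abundance vector sums to zero")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def group_summary(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean, standard error and n per group, as reported in group scatter plots.

    SE = sd/sqrt(n) with ddof=1; single-observation groups get SE = NaN and
    ``se_defined = False``.
    """
    rows = []
    for name, vals in values_by_group.items():
        v = _as_1d(vals, f"group {name!r}")
        if len(v) == 0:
            raise InputError(f"group {name!r} is empty")
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        rows.append({"group": name, "n": len(v), "mean": float(v.mean()), "se": se, "se_defined": len(v) > 1})
    return pd.DataFrame(rows).set_index("group")
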