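"""Cohort-level statistics for normal-vs-injured comparisons.

The statistical layer mirrors a conventional morphometry workflow: ordinary
least squares for the axon-diameter / myelin-thickness relationship (reported
as slope, intercept and R²), Levene's test for homogeneity of variances
gating the choice between Student's and Welch's unpaired t-test, and one-way
repeated-measures ANOVA with Tukey HSD post-hoc for within-axon comparisons
across measurement conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

LEVENE_ALPHA = 0.05


@dataclass
class RegressionResult:
    slope: float  # µm myelin per µm axon diameter
    intercept: float  # µm
    r_squared: float
    n: int


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    equal_variances: bool | None = None
    levene_f: float | None = None
    levene_p: float | None = None


def fit_diameter_thickness(
    points: list[tuple[float, float]] | np.ndarray
) -> RegressionResult:
    """OLS of myelin thickness on axon diameter; R² = 1 - SS_res/SS_tot."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected (n, 2) array of (diameter, thickness)")
    if len(arr) < 3:
        raise ValueError("need at least 3 points")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: zero variance in diameter")
    if np.ptp(y) == 0:
        # flat response: zero slope explains nothing beyond the mean
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, n=len(arr))
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(arr),
    )


def levene_test(a, b) -> TestResult:
    """Classic Levene test (deviations from group means) for equal variances."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    dev_a = np.abs(a - a.mean())
    dev_b = np.abs(b - b.mean())
    if dev_a.mean() == dev_b.mean() and np.var(dev_a) + np.var(dev_b) == 0:
        # identical dispersion (e.g. both constant): no evidence against
        # homogeneity; the F ratio is 0/0 and conventionally reported as 0
        return TestResult("levene", 0.0, 1.0, (len(a), len(b)))
    f, p = sps.levene(a, b, center="mean")
    if not np.isfinite(f):
        f, p = 0.0, 1.0
    return TestResult("levene", float(f), float(p), (len(a), len(b)))


def unpaired_t_test(a, b, equal_var: bool | None = None) -> TestResult:
    """Two-sided unpaired t-test; Student's or Welch's form.

    When ``equal_var`` is None, Levene's test at alpha = 0.05 decides:
    homogeneous variances -> Student's pooled t, otherwise Welch.
    Degenerate zero-variance, equal-mean groups return t = 0, p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    lev = levene_test(a, b)
    if equal_var is None:
        equal_var = lev.p_value >= LEVENE_ALPHA
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        name="student_t" if equal_var else "welch_t",
        statistic=float(t),
        p_value=float(p),
        group_sizes=(len(a), len(b)),
        equal_variances=bool(equal_var),
        levene_f=lev.statistic,
        levene_p=lev.p_value,
    )


@dataclass
class TukeyPair:
    cond_a: str
    cond_b: str
    mean_diff: float
    p_adjusted: float


@dataclass
class RMAnovaResult:
    f_statistic: float
    p_value: float
    df_condition: int
    df_error: int
    ms_error: float
    pairwise: list[TukeyPair]


def rm_anova_tukey(values: np.ndarray, conditions: list[str]) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Tukey HSD post-hoc.

    ``values`` is a complete subjects x conditions matrix (here: axons x
    measurement conditions).  The subject-blocked two-way decomposition is
    SS_total = SS_subject + SS_condition + SS_error; the condition effect is
    tested against MS_error, and Tukey HSD compares condition means using the
    same error mean square via the studentized range distribution.
    """
    m = np.asarray(values, float)
    if m.ndim != 2:
        raise ValueError("values must be a 2D subjects x conditions matrix")
    n_sub, n_cond = m.shape
    if n_cond != len(conditions):
        raise ValueError("condition labels do not match matrix columns")
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(m).all():
        raise ValueError("incomplete matrix: every subject must be measured "
                         "in every condition")

    grand = m.mean()
    subj_means = m.mean(axis=1)
    cond_means = m.mean(axis=0)
    ss_subject = n_cond * np.sum((subj_means - grand) ** 2)
    ss_condition = n_sub * np.sum((cond_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_error = ss_total - ss_subject - ss_condition
    df_cond = n_cond - 1
    df_err = (n_sub - 1) * (n_cond - 1)
    ms_cond = ss_condition / df_cond
    ms_err = max(ss_error / df_err, 0.0)
    if ms_err == 0.0:
        f = 0.0 if ms_cond == 0.0 else float("inf")
        p = 1.0 if ms_cond == 0.0 else 0.0
    else:
        f = float(ms_cond / ms_err)
        p = float(sps.f.sf(f, df_cond, df_err))

    pairwise = []
    se = np.sqrt(ms_err / n_sub) if ms_err > 0 else 0.0
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            diff = float(cond_means[j] - cond_means[i])
            if se == 0.0:
                p_adj = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, n_cond, df_err))
            pairwise.append(
                TukeyPair(conditions[i], conditions[j], diff, min(p_adj, 1.0))
            )
    return RMAnovaResult(
        f_statistic=f,
        p_value=p,
        df_condition=df_cond,
        df_error=df_err,
        ms_error=float(ms_err),
        pairwise=pairwise,
    )
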