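"""Two-group comparisons: unpaired Student's t and Welch's t.

The study design compares young and aged cohorts metric by metric.
Metrics with approximately equal group variances (coverage, regional CBF,
AVR, NVC metrics) use the pooled-variance unpaired Student's t-test;
pixel-level speed and local-thickness distributions, whose variances
differ between groups and which can be skewed, use Welch's t-test with
Welch-Satterthwaite degrees of freedom.

Significance stars follow the figure-legend convention:
* p < 0.05, ** p < 0.005, *** p < 0.001, **** p < 0.0001.

The t statistics and p-values themselves come from scipy
(``scipy.stats.ttest_ind``); this module adds the result container, the
degenerate-input checks, and the per-metric method policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.005, "**"), (0.05, "*"))

#: metric name -> test method; anything absent defaults to student
DEFAULT_POLICY = {
    "speed": "welch",
    "thickness": "welch",
    "diameter": "welch",
}


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    group_means: tuple[float, float]
    group_sems: tuple[float, float]
    n_per_group: tuple[int, int]

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _prepare(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return a, b


def _result(a: np.ndarray, b: np.ndarray, res, method: str) -> TestResult:
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        method=method,
        group_means=(float(a.mean()), float(b.mean())),
        group_sems=(
            float(a.std(ddof=1) / np.sqrt(a.size)),
            float(b.std(ddof=1) / np.sqrt(b.size)),
        ),
        n_per_group=(int(a.size), int(b.size)),
    )


def student_t(a, b) -> TestResult:
    """Unpaired two-sided Student's t-test with pooled variance."""
    a, b = _prepare(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("pooled variance is zero; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return _result(a, b, res, "student")


def welch_t(a, b) -> TestResult:
    """Unpaired two-sided Welch's t-test (no equal-variance assumption)."""
    a, b = _prepare(a, b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both variances are zero; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return _result(a, b, res, "welch")


def compare_groups(a, b, method: str) -> TestResult:
    if method == "student":
        return student_t(a, b)
    if method == "welch":
        return welch_t(a, b)
    raise ValueError(f"unknown test method {method!r}")


def method_for_metric(metric: str, policy: dict[str, str] | None = None) -> str:
    """Resolve the test method for a metric name under a policy.

    Matching is by substring on the policy keys so that e.g. both
    'speed' and 'speed_hippocampus' pick up the Welch rule.
    """
    policy = DEFAULT_POLICY if policy is None else policy
    for key, method in policy.items():
        if key in metric:
            return method
    return "student"


def compare_metric(
    table: pd.DataFrame,
    metric: str | None = None,
    policy: dict[str, str] | None = None,
    value_col: str = "value",
    group_col: str = "group",
) -> TestResult:
    """Run the policy-selected test on a tidy per-observation table.

    ``table`` holds one row per observation with a group label column; if
    ``metric`` is given and a 'metric' column exists, rows are filtered to
    that metric first.  Exactly two groups must be present.
    """
    df = table
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {list(groups)}")
    a = df.loc[df[group_col] == groups[0], value_col]
    b = df.loc[df[group_col] == groups[1], value_col]
    method = method_for_metric(metric or "", policy)
    return compare_groups(a, b, method)


def summary_row(metric: str, groups: tuple[str, str], res: TestResult) -> dict:
    """Flatten a TestResult into a CSV-friendly record."""
    return {
        "metric": metric,
        "group_a": groups[0],
        "group_b": groups[1],
        "mean_a": res.group_means[0],
        "mean_b": res.group_means[1],
        "sem_a": res.group_sems[0],
        "sem_b": res.group_sems[1],
        "n_a": res.n_per_group[0],
        "n_b": res.n_per_group[1],
        "method": res.method,
        "t": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "stars": res.stars,
    }
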