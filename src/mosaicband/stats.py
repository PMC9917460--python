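"""Statistical comparisons used on the zone measurement tables.

Implements exactly the comparisons the measurement design calls for —
paired t, one- and two-way fixed-effects ANOVA, Spearman correlation, and
a semi-log regression of a response on log10(clone area) — via scipy and
statsmodels.  No multiple-testing correction is applied (stated in output
provenance).  Two-way ANOVA uses type-II sums of squares; on the balanced
designs the synthetic generator produces, the SS types agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

TESTS = ("paired_t", "anova_1way", "anova_2way", "spearman", "semilog_fit")


class DegenerateVarianceError(ValueError):
    """Paired differences (or residuals) have zero variance."""


@dataclass
class TestSpec:
    """What to test on a tidy table.

    (Not a pytest class, despite the name.)

    test
        One of ``paired_t``, ``anova_1way``, ``anova_2way``, ``spearman``,
        ``semilog_fit``.
    response
        Column holding the response values.
    groups
        Grouping column(s): one for one-way ANOVA / paired t / the x of a
        Spearman or semi-log fit, two for two-way ANOVA.
    pairing
        Column identifying pairs (paired t only).
    """

    test: str
    response: str
    groups: list[str] = field(default_factory=list)
    pairing: str | None = None

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"test must be one of {TESTS}")

    __test__ = False  # keep pytest from collecting this dataclass


@dataclass
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p: float
    estimates: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    note: str = "no multiple-testing correction applied"

    def to_row(self) -> dict:
        row = {"test": self.test, "statistic": self.statistic,
               "df": "/".join(f"{d:g}" for d in self.df), "p": self.p,
               "note": self.note}
        for k, v in self.estimates.items():
            row[f"est_{k}"] = v
        for k, (lo, hi) in self.ci95.items():
            row[f"ci95_{k}"] = f"[{lo:.6g}, {hi:.6g}]"
        return row


def mean_ci95(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mean with its t-based 95 % confidence interval."""
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    n = values.size
    if n < 2:
        return m, (np.nan, np.nan)
    half = sps.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n)
    return m, (m - half, m + half)


def run_test(table: pd.DataFrame, spec: TestSpec) -> TestResult:
    """Dispatch a TestSpec against a tidy table."""
    for col in [spec.response, *spec.groups, *( [spec.pairing]
                                                if spec.pairing else [] )]:
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    y = table[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if spec.test == "paired_t":
        return _paired_t(table, spec)
    if spec.test == "anova_1way":
        return _anova_1way(table, spec)
    if spec.test == "anova_2way":
        return _anova_2way(table, spec)
    if spec.test == "spearman":
        return _spearman(table, spec)
    return _semilog_fit(table, spec)


def _paired_t(table: pd.DataFrame, spec: TestSpec) -> TestResult:
    (gcol,) = spec.groups
    if spec.pairing is None:
        raise ValueError("paired_t needs a pairing column")
    wide = table.pivot_table(index=spec.pairing, columns=gcol,
                             values=spec.response)
    if wide.shape[1] != 2:
        raise ValueError(f"paired_t needs exactly 2 groups, got {wide.shape[1]}")
    wide = wide.dropna()
    if len(wide) < 2:
        raise ValueError("paired_t needs >= 2 complete pairs")
    a, b = wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy()
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateVarianceError("zero within-pair variance")
    t, p = sps.ttest_rel(a, b)
    md, ci = mean_ci95(diff)
    return TestResult("paired_t", float(t), (len(diff) - 1,), float(p),
                      {"mean_difference": md}, {"mean_difference": ci})


def _group_arrays(table: pd.DataFrame, gcol: str, response: str):
    return {k: v[response].to_numpy(dtype=float)
            for k, v in table.groupby(gcol, observed=True)}


def _anova_1way(table: pd.DataFrame, spec: TestSpec) -> TestResult:
    (gcol,) = spec.groups
    groups = _group_arrays(table, gcol, spec.response)
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    arrays = list(groups.values())
    f, p = sps.f_oneway(*arrays)
    if np.isnan(f):  # all groups identical constant -> zero between & within SS
        f, p = 0.0, 1.0
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    est, ci = {}, {}
    for name, arr in groups.items():
        est[f"mean[{name}]"], ci[f"mean[{name}]"] = mean_ci95(arr)
    return TestResult("anova_1way", float(f), (k - 1, n - k), float(p), est, ci)


def _anova_2way(table: pd.DataFrame, spec: TestSpec) -> TestResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    g1, g2 = spec.groups
    df = table[[spec.response, g1, g2]].copy()
    df.columns = ["y", "A", "B"]
    counts = df.groupby(["A", "B"], observed=True).size()
    if counts.nunique() > 1:
        log.info("unbalanced two-way design: type-II SS reported")
    model = smf.ols("y ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    est, ci = {}, {}
    for name, arr in _group_arrays(df, "A", "y").items():
        est[f"mean[{name}]"], ci[f"mean[{name}]"] = mean_ci95(arr)
    f_a = float(aov.loc["C(A)", "F"])
    p_a = float(aov.loc["C(A)", "PR(>F)"])
    for row in aov.index:
        if row == "Residual":
            continue
        est[f"F[{row}]"] = float(aov.loc[row, "F"])
        est[f"p[{row}]"] = float(aov.loc[row, "PR(>F)"])
    dfs = (float(aov.loc["C(A)", "df"]), float(aov.loc["Residual", "df"]))
    return TestResult("anova_2way", f_a, dfs, p_a, est, ci)


def _spearman(table: pd.DataFrame, spec: TestSpec) -> TestResult:
    (xcol,) = spec.groups
    x = table[xcol].to_numpy(dtype=float)
    y = table[spec.response].to_numpy(dtype=float)
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), (len(x) - 2,), float(p),
                      {"rho": float(rho)}, {})


def _semilog_fit(table: pd.DataFrame, spec: TestSpec) -> TestResult:
    """Least-squares fit of ``response = a + b * log10(x)``."""
    (xcol,) = spec.groups
    x = table[xcol].to_numpy(dtype=float)
    y = table[spec.response].to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("semilog fit needs strictly positive x")
    lx = np.log10(x)
    res = sps.linregress(lx, y)
    n = len(x)
    tcrit = sps.t.ppf(0.975, n - 2) if n > 2 else np.nan
    resid = y - (res.intercept + res.slope * lx)
    return TestResult(
        "semilog_fit", float(res.slope / res.stderr) if res.stderr else np.inf,
        (n - 2,), float(res.pvalue),
        {"intercept_a": float(res.intercept), "slope_b": float(res.slope),
         "r": float(res.rvalue), "rss": float((resid**2).sum())},
        {"slope_b": (res.slope - tcrit * res.stderr,
                     res.slope + tcrit * res.stderr)},
    )


def append_stats_csv(path, results: list[TestResult],
                     provenance: str = "") -> pd.DataFrame:
    """Append result rows to a stats CSV (created with header if absent)."""
    import os

    rows = [r.to_row() | {"provenance": provenance} for r in results]
    df = pd.DataFrame(rows)
    header = not os.path.exists(path)
    df.to_csv(path, mode="a", header=header, index=False)
    return df
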