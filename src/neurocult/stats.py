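"""Replicate-aware nonparametric comparison statistics.

The group comparison of record is the one-sided Mann-Whitney U test, exact
by full enumeration of label assignments for small samples (n1·n2 ≤ 100,
ties handled by permuting the pooled sample) and a tie-corrected,
continuity-corrected normal approximation otherwise.  Summaries follow the
plotting conventions of the emulated study: quartiles by linear
interpolation, whiskers at the min/max of non-outlier values, outliers
beyond 1.5 interquartile ranges from the quartile fences excluded in a
single pass, mean ± standard error, and star annotations at
p < 0.05 / 0.005 / 0.0005 / 0.00005 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import norm

#: Star thresholds, strict inequality, most significant first.
STAR_LEVELS = ((5e-5, "****"), (5e-4, "***"), (5e-3, "**"), (5e-2, "*"))

#: Largest n1·n2 for which the exact enumeration path is used.
EXACT_LIMIT = 100


@dataclass(frozen=True)
class MWUResult:
    """One-sided Mann-Whitney outcome: U of the favored sample, p, method."""

    U: float
    p_one_sided: float
    method: str  # "exact" | "normal-approximation"
    stars: str
    n1: int
    n2: int


def significance_stars(p: float) -> str:
    """Star annotation for a p-value; strict inequality at each level."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    for thr, stars in STAR_LEVELS:
        if p < thr:
            return stars
    return ""


def _u_statistic(ranks_x: np.ndarray, n1: int, n2: int) -> float:
    """U for sample x from its pooled midranks."""
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2)


def mwu_one_sided(
    x: np.ndarray, y: np.ndarray, alternative: str = "x_greater"
) -> MWUResult:
    """One-sided Mann-Whitney U test of two independent samples.

    ``alternative="x_greater"`` tests whether x is stochastically greater
    than y (``"y_greater"`` the reverse).  The reported U is the U statistic
    of the favored sample.  For n1·n2 ≤ 100 the p-value is exact: every
    C(n1+n2, n1) assignment of the pooled values to the two labels is
    enumerated and p is the fraction with a U at least as extreme as
    observed, which handles ties by construction.  Larger samples use the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("x_greater", "y_greater"):
        raise ValueError("alternative must be 'x_greater' or 'y_greater'")
    if alternative == "y_greater":
        res = mwu_one_sided(y, x, "x_greater")
        return MWUResult(res.U, res.p_one_sided, res.method, res.stars,
                         res.n2, res.n1)

    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    u_obs = _u_statistic(ranks[:n1], n1, n2)

    if n1 * n2 <= EXACT_LIMIT:
        # Exact: enumerate all label assignments over the pooled sample.
        idx_all = np.fromiter(
            (i for comb in combinations(range(n1 + n2), n1) for i in comb),
            dtype=np.intp,
        ).reshape(-1, n1)
        rank_sums = ranks[idx_all].sum(axis=1)
        u_all = rank_sums - n1 * (n1 + 1) / 2
        # Tolerance guards float midrank sums.
        p = float(np.mean(u_all >= u_obs - 1e-9))
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u_obs - mu - 0.5) / np.sqrt(var)
            p = float(norm.sf(z))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        method = "normal-approximation"
    return MWUResult(u_obs, p, method, significance_stars(p), n1, n2)


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Q1, median, Q3 by the linear-interpolation quantile convention."""
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def iqr_outlier_filter(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exclude values beyond 1.5 IQR from the quartiles, in a single pass.

    Fences are computed once from the full sample — values below
    ``Q1 − 1.5·IQR`` or above ``Q3 + 1.5·IQR`` are excluded and the fences
    are *not* recomputed afterwards.  Returns ``(kept, outliers)`` in the
    original order.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("iqr_outlier_filter requires at least one value")
    q1, _, q3 = _quartiles(values)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out_mask = (values < lo) | (values > hi)
    return values[~out_mask], values[out_mask]


@dataclass(frozen=True)
class BoxplotStats:
    """Quartiles, min/max whiskers of kept values, and excluded outliers."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_stats(values: np.ndarray) -> BoxplotStats:
    """Boxplot summary matching the emulated study's plotting convention.

    The box spans Q1–Q3 with the median inside; whiskers sit at the minimum
    and maximum of the non-outlier values; outliers are the 1.5-IQR
    exclusions of :func:`iqr_outlier_filter`.  As in the standard plotting
    convention, a whisker never retreats inside the box: when every value
    beyond a quartile is an outlier the whisker sits at the box edge.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q1, med, q3 = _quartiles(values)
    kept, outliers = iqr_outlier_filter(values)
    lo = min(float(kept.min()), q1)
    hi = max(float(kept.max()), q3)
    return BoxplotStats(q1, med, q3, lo, hi, outliers)


@dataclass(frozen=True)
class MeanSem:
    """Sample mean with its standard error (n−1 denominator)."""

    mean: float
    sem: float
    n: int


def mean_sem(values: np.ndarray) -> MeanSem:
    """Mean ± standard error of the mean; requires at least two values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("mean_sem requires n >= 2")
    sd = float(values.std(ddof=1))
    return MeanSem(float(values.mean()), sd / np.sqrt(values.size),
                   int(values.size))


def compare_conditions(
    table: pd.DataFrame,
    value_col: str,
    test_condition: str = "co-culture",
    control_label: str = "control",
    condition_col: str = "condition",
    density_col: str = "density",
    alternative: str = "x_greater",
    pool_biological: bool = True,
    exclude_outliers: bool = False,
) -> pd.DataFrame:
    """Per-density comparison of a test condition against the control.

    For each density (and, when ``pool_biological`` is False, each
    biological replicate), the test-condition values (x) are compared to
    control values (y) with :func:`mwu_one_sided`; technical replicates are
    the statistical unit and by default pooled across biological replicates.
    Optional single-pass IQR outlier exclusion is applied per group before
    testing.  Returns a table with U, one-sided p, stars, group sizes and
    mean ± SEM per group.
    """
    group_cols = [density_col] if pool_biological else [density_col, "biological"]
    rows = []
    for key, grp in table.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        x = grp.loc[grp[condition_col] == test_condition, value_col].dropna().values
        y = grp.loc[grp[condition_col] == control_label, value_col].dropna().values
        if exclude_outliers:
            if x.size:
                x, _ = iqr_outlier_filter(x)
            if y.size:
                y, _ = iqr_outlier_filter(y)
        if x.size == 0 or y.size == 0:
            continue
        res = mwu_one_sided(x, y, alternative)
        row = dict(zip(group_cols, key))
        row.update(
            U=res.U, p_one_sided=res.p_one_sided, method=res.method,
            stars=res.stars, n_test=int(x.size), n_control=int(y.size),
            mean_test=float(np.mean(x)), mean_control=float(np.mean(y)),
            sem_test=mean_sem(x).sem if x.size >= 2 else np.nan,
            sem_control=mean_sem(y).sem if y.size >= 2 else np.nan,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summary_table(
    table: pd.DataFrame,
    value_col: str,
    condition_col: str = "condition",
    density_col: str = "density",
) -> pd.DataFrame:
    """Mean ± SEM and boxplot statistics per condition × density group."""
    rows = []
    for (cond, dens), grp in table.groupby([condition_col, density_col]):
        vals = grp[value_col].dropna().values
        if vals.size == 0:
            continue
        bs = boxplot_stats(vals)
        rows.append(
            dict(
                condition=cond, density=dens, n=int(vals.size),
                mean=float(np.mean(vals)),
                sem=mean_sem(vals).sem if vals.size >= 2 else np.nan,
                q1=bs.q1, median=bs.median, q3=bs.q3,
                whisker_low=bs.whisker_low, whisker_high=bs.whisker_high,
                n_outliers=int(bs.outliers.size),
            )
        )
    return pd.DataFrame(rows)
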