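"""Univariate screening of patella measurements.

Descriptive summaries by sex, Wilcoxon rank-sum tests for sexual dimorphism,
Pearson correlation filtering of redundant measurements, Z-score
normalization, and Lin's concordance correlation coefficient for
test–retest reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VARIABLES


# ---------------------------------------------------------------------------
# descriptive summaries


@dataclass
class GroupStats:
    """Summary of one variable within one group (or pooled)."""

    n: int
    n_missing: int
    mean: float | None
    sd: float | None
    median: float | None
    q1: float | None
    q3: float | None
    min: float | None
    max: float | None


@dataclass
class DescriptiveSummary:
    variable: str
    male: GroupStats
    female: GroupStats
    pooled: GroupStats


def _group_stats(x: pd.Series) -> GroupStats:
    vals = x.dropna().to_numpy(dtype=float)
    n_missing = int(x.isna().sum())
    if len(vals) == 0:
        return GroupStats(0, n_missing, *([None] * 7))
    # quartiles by linear interpolation between order statistics
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return GroupStats(
        n=len(vals),
        n_missing=n_missing,
        mean=float(np.mean(vals)),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(vals.min()),
        max=float(vals.max()),
    )


def describe_by_sex(
    table: pd.DataFrame, variables: tuple[str, ...] = VARIABLES
) -> list[DescriptiveSummary]:
    """Per-variable descriptive summaries, split by sex and pooled.

    Missing values are excluded per variable (complete-case per column) and
    counted in ``n_missing``.
    """
    if len(table) == 0:
        raise ValueError("empty measurement table")
    if "sex" not in table.columns:
        raise ValueError("table has no 'sex' column")
    out = []
    males = table[table["sex"] == "M"]
    females = table[table["sex"] == "F"]
    for v in variables:
        out.append(
            DescriptiveSummary(
                variable=v,
                male=_group_stats(males[v]),
                female=_group_stats(females[v]),
                pooled=_group_stats(table[v]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# rank-sum test


@dataclass
class RankSumResult:
    variable: str
    z: float
    p_value: float


def rank_sum_test(
    values_m, values_f, variable: str = ""
) -> RankSumResult:
    """Wilcoxon–Mann–Whitney rank-sum test for a sex difference.

    Normal approximation with tie correction, no continuity correction.
    Sign convention: Z = -(W_M - E[W_M]) / sigma, i.e. Z is negative when
    males rank above females — the direction sexual dimorphism takes for
    every patella measurement.
    """
    x = np.asarray(values_m, dtype=float)
    y = np.asarray(values_f, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w_m = ranks[:n1].sum()
    expect = n1 * (n1 + n2 + 1) / 2.0
    tie_factor = stats.tiecorrect(ranks)
    sigma = math.sqrt(tie_factor * n1 * n2 * (n1 + n2 + 1) / 12.0)
    if sigma == 0:
        return RankSumResult(variable, 0.0, 1.0)
    z = -(w_m - expect) / sigma
    p = 2 * stats.norm.sf(abs(z))
    return RankSumResult(variable, float(z), float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# correlation filtering


@dataclass
class CorrelationFilterResult:
    matrix: pd.DataFrame
    removed: list[str]
    undefined: list[str] = field(default_factory=list)


def correlation_filter(
    table: pd.DataFrame,
    variables: tuple[str, ...] = VARIABLES,
    threshold: float = 0.85,
) -> CorrelationFilterResult:
    """Flag measurements whose pairwise Pearson |r| exceeds ``threshold``.

    For each offending pair, the member with the larger mean absolute
    correlation to the remaining variables is removed, iterating until no
    pair among the survivors exceeds the threshold. Zero-variance variables
    have undefined correlations; they are reported and excluded from
    filtering.
    """
    data = table[list(variables)].dropna()
    if len(data) < 2:
        raise ValueError("need at least 2 complete rows")
    undefined = [v for v in variables if data[v].nunique() <= 1]
    corr = data.corr(method="pearson")
    active = [v for v in variables if v not in undefined]
    removed: list[str] = []
    while True:
        sub = corr.loc[active, active].abs()
        np.fill_diagonal(sub.values, 0.0)
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        if sub.values[i, j] <= threshold:
            break
        a, b = sub.index[i], sub.columns[j]
        # drop the variable more correlated with everything else on average
        mean_a = sub.loc[a].drop(b).mean() if len(active) > 2 else sub.loc[a, b]
        mean_b = sub.loc[b].drop(a).mean() if len(active) > 2 else sub.loc[a, b]
        drop = a if mean_a > mean_b else b if mean_b > mean_a else max(a, b)
        removed.append(drop)
        active.remove(drop)
        if len(active) < 2:
            break
    return CorrelationFilterResult(matrix=corr, removed=removed, undefined=undefined)


# ---------------------------------------------------------------------------
# Z-score normalization


@dataclass
class NormalizationParams:
    """Per-variable training mean and SD for Z-score normalization."""

    mu: dict[str, float]
    sigma: dict[str, float]


def zscore_fit(
    table: pd.DataFrame, variables: tuple[str, ...] = VARIABLES
) -> NormalizationParams:
    """Fit Z-score parameters (training mean and SD per variable).

    SDs use the population (1/n) convention; the fitted transform maps the
    training column to mean 0, SD 1 exactly.
    """
    mu, sigma = {}, {}
    for v in variables:
        vals = table[v].dropna().to_numpy(dtype=float)
        s = float(np.std(vals))
        if s == 0:
            raise ValueError(f"zero training SD for variable {v!r}")
        mu[v] = float(np.mean(vals))
        sigma[v] = s
    return NormalizationParams(mu=mu, sigma=sigma)


def zscore_apply(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """Apply fitted normalization: v' = (v - mu_v) / sigma_v."""
    out = table.copy()
    for v in params.mu:
        out[v] = (table[v] - params.mu[v]) / params.sigma[v]
    return out


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient


@dataclass
class CCCResult:
    variable: str
    ccc: float
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    cov_xy: float


def lins_ccc(x, y, variable: str = "") -> CCCResult:
    """Lin's concordance correlation coefficient between two measurement passes.

    P_c = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), with biased (1/n)
    variance and covariance terms. P_c = 1 only for perfect agreement; unlike
    Pearson's r it is attenuated by both location and scale shifts, which
    makes it the standard intra-observer reproducibility statistic in
    osteometry.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need paired 1-D vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # 1/n convention
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        # both passes constant and equal: perfect agreement by convention
        return CCCResult(variable, 1.0, mx, my, vx, vy, cov)
    return CCCResult(
        variable, float(2 * cov / denom), float(mx), float(my),
        float(vx), float(vy), float(cov),
    )


def ccc_by_variable(
    first: pd.DataFrame, second: pd.DataFrame,
    variables: tuple[str, ...] = VARIABLES,
) -> list[CCCResult]:
    """Per-variable CCC between two aligned measurement passes."""
    if len(first) != len(second):
        raise ValueError("measurement passes have different numbers of rows")
    return [lins_ccc(first[v], second[v], variable=v) for v in variables]
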