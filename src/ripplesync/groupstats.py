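"""Group-level statistics for electrode-wise SWR metrics.

Electrodes are the unit of analysis: per-session metric values are first
averaged within each electrode, and the resulting per-electrode values of
two genotype groups are compared with the Wilcoxon rank-sum test (exact
null distribution for small untied samples, tie- and continuity-corrected
normal approximation otherwise) or, for whole distributions, the two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 20  # pooled size below which the exact rank-sum null is used


@dataclass(frozen=True)
class GroupComparison:
    """Two-group test result with per-group summaries."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    test: str  # "rank_sum" or "ks"
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float


def _summaries(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
    def se(v: np.ndarray) -> float:
        return float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")

    return float(a.mean()), float(b.mean()), se(a), se(b)


def session_average(
    values: pd.DataFrame,
    value_col: str = "value",
    by: tuple[str, ...] = ("electrode_id", "metric"),
) -> pd.DataFrame:
    """Arithmetic mean of per-session values within each electrode.

    ``values`` holds one row per (electrode, session, metric); group
    columns other than ``by`` that are constant within a group (genotype,
    region, ...) are carried through.
    """
    if values.empty:
        raise ValueError("no values to average")
    by = [c for c in by if c in values.columns]
    carry = [
        c
        for c in values.columns
        if c not in by and c != value_col and values.groupby(list(by))[c].nunique().max() == 1
    ]
    agg = {value_col: "mean", **{c: "first" for c in carry}}
    return values.groupby(list(by), as_index=False).agg(agg)


def rank_sum(a, b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled sample is small
    (n_a + n_b <= 20) and tie-free, otherwise the normal approximation with
    tie and continuity corrections.  The reported statistic is the
    Mann-Whitney U of the first group.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    ma, mb, sa, sb = _summaries(a, b)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        test="rank_sum",
        mean_a=ma,
        mean_b=mb,
        se_a=sa,
        se_b=sb,
    )


def ks_compare(a, b) -> GroupComparison:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the p-value
    uses the asymptotic Kolmogorov distribution.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    ma, mb, sa, sb = _summaries(a, b)
    return GroupComparison(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=a.size,
        n_b=b.size,
        test="ks",
        mean_a=ma,
        mean_b=mb,
        se_a=sa,
        se_b=sb,
    )


def duration_fraction_curve(
    durations_ms, bin_ms: float = 5.0
) -> pd.DataFrame:
    """Fraction-of-events histogram and cumulative curve over duration.

    Returns a frame with ``bin_left_ms``, ``bin_right_ms``, ``fraction``
    (sums to 1) and ``cumulative`` (nondecreasing, ends at 1).
    """
    d = np.asarray(durations_ms, float)
    if d.size == 0:
        raise ValueError("empty event table")
    upper = max(np.max(d), bin_ms)
    n_bins = int(np.ceil(upper / bin_ms)) + 1
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(d, bins=edges)
    fraction = counts / d.size
    return pd.DataFrame(
        {
            "bin_left_ms": edges[:-1],
            "bin_right_ms": edges[1:],
            "fraction": fraction,
            "cumulative": np.cumsum(fraction),
        }
    )


def compare_sexes_then_pool(
    values: pd.DataFrame,
    value_col: str = "value",
    sex_col: str = "sex",
    alpha: float = 0.05,
) -> tuple[bool, GroupComparison | None]:
    """Pre-test the sex difference; pool when non-significant.

    Returns ``(pooled, comparison)``: ``pooled`` is True when the rank-sum
    test between sexes does not reach ``alpha`` (or only one sex is
    present), in which case downstream analyses may combine the sexes.
    """
    sexes = values[sex_col].dropna().unique()
    if len(sexes) < 2:
        return True, None
    a = values.loc[values[sex_col] == sexes[0], value_col].to_numpy(float)
    b = values.loc[values[sex_col] == sexes[1], value_col].to_numpy(float)
    cmp = rank_sum(a, b)
    return cmp.p_value >= alpha, cmp
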