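"""Motor-neuron survival fractions and group-comparison statistics.

Survival is tracked per spinal-cord explant: the motor-neuron count at each
observation day is divided by the count first detected in that explant, so
the baseline day maps to exactly 100%. Group comparisons use the classical
two-sample Student's t test (pooled variance, Welch behind a flag) and
one-way ANOVA followed by Fisher's LSD post hoc tests — unadjusted pairwise
t tests on the pooled ANOVA mean-square error with N - k degrees of freedom.
The LSD step is protected (gated on a significant omnibus F at alpha) by
default; ``protected=False`` always reports the pairwise tests.

All summaries are mean ± SEM with the n-1 sample standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError


@dataclass(frozen=True)
class ExplantSeries:
    """Motor-neuron counts of one explant across observation days."""

    explant_id: str
    condition: str
    days: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        days = tuple(int(d) for d in self.days)
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "counts", counts)
        if len(days) != len(counts) or len(days) == 0:
            raise DataError(
                f"explant {self.explant_id!r}: days and counts must be "
                f"non-empty and of equal length"
            )
        if any(b <= a for a, b in zip(days, days[1:])):
            raise DataError(f"explant {self.explant_id!r}: days must be increasing")
        if any(c < 0 for c in counts):
            raise DataError(f"explant {self.explant_id!r}: counts must be >= 0")


def percent_surviving(series: ExplantSeries) -> np.ndarray:
    """100 * count(day) / count(baseline) for each observation day."""
    baseline = series.counts[0]
    if baseline <= 0:
        raise DataError(f"explant {series.explant_id!r}: baseline count is zero")
    return 100.0 * np.asarray(series.counts, dtype=float) / baseline


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def group_timecourse(series_list: Sequence[ExplantSeries]) -> pd.DataFrame:
    """Per-day mean ± SEM of percent surviving, by condition.

    Each day aggregates the explants observed on that day.
    """
    if not series_list:
        raise DataError("no explant series supplied")
    rows = []
    for s in series_list:
        pct = percent_surviving(s)
        for day, p in zip(s.days, pct):
            rows.append({"condition": s.condition, "day": day, "percent": p})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["condition", "day"])["percent"]
        .agg(
            mean_percent="mean",
            sem_percent=lambda v: _sem(v.to_numpy()),
            n="size",
        )
        .reset_index()
    )
    return out


@dataclass
class GroupComparison:
    """One statistical comparison: labels, descriptives and the test result."""

    method: str
    group_labels: tuple[str, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    ns: tuple[int, ...]
    statistic: float
    p_value: float
    df: float | tuple[float, ...] | None = None


def _describe(values: np.ndarray) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), _sem(arr), int(arr.size)


def student_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    two_sided: bool = True,
    equal_var: bool = True,
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sample Student's t test (pooled variance; Welch via equal_var=False).

    One-sided mode tests mean(A) > mean(B).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    alternative = "two-sided" if two_sided else "greater"
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    ma, sa, na = _describe(a)
    mb, sb, nb = _describe(b)
    return GroupComparison(
        method="student_t" if equal_var else "welch_t",
        group_labels=labels,
        means=(ma, mb),
        sems=(sa, sb),
        ns=(na, nb),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
    )


@dataclass
class AnovaLSDResult:
    """One-way ANOVA omnibus plus (optionally gated) Fisher's LSD post hocs."""

    omnibus: GroupComparison
    pairwise: list[GroupComparison] = field(default_factory=list)
    mse: float = float("nan")
    df_error: int = 0
    gated_out: bool = False


def anova_fisher_lsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    protected: bool = True,
) -> AnovaLSDResult:
    """One-way ANOVA with Fisher's LSD post hoc tests.

    Pairwise LSD statistics use the pooled mean-square error with N - k df
    and unadjusted two-sided p values. With ``protected=True`` (classical
    protected LSD) the pairwise tests are withheld when the omnibus F is not
    significant at *alpha*; ``gated_out`` records that this happened.
    """
    labels = list(groups.keys())
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ParameterError("each group needs n >= 2")
    f_res = stats.f_oneway(*arrays)
    ns = [a.size for a in arrays]
    k = len(arrays)
    n_total = sum(ns)
    df_error = n_total - k
    mse = sum((a.size - 1) * a.var(ddof=1) for a in arrays) / df_error
    descr = [_describe(a) for a in arrays]
    omnibus = GroupComparison(
        method="anova",
        group_labels=tuple(labels),
        means=tuple(d[0] for d in descr),
        sems=tuple(d[1] for d in descr),
        ns=tuple(d[2] for d in descr),
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        df=(float(k - 1), float(df_error)),
    )
    result = AnovaLSDResult(omnibus=omnibus, mse=mse, df_error=df_error)
    if protected and not (omnibus.p_value < alpha):
        result.gated_out = True
        return result
    for i in range(k):
        for j in range(i + 1, k):
            mi, si, ni = descr[i]
            mj, sj, nj = descr[j]
            se = math.sqrt(mse * (1.0 / ni + 1.0 / nj))
            t = (mi - mj) / se if se > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), df_error) if se > 0 else 1.0
            result.pairwise.append(
                GroupComparison(
                    method="fisher_lsd",
                    group_labels=(labels[i], labels[j]),
                    means=(mi, mj),
                    sems=(si, sj),
                    ns=(ni, nj),
                    statistic=t,
                    p_value=p,
                    df=float(df_error),
                )
            )
    return result
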