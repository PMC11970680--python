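"""Method-comparison statistics for daily sleep measures.

Builds a paired daily table (one row per participant-day, one column block
per detection method), accounts for nights a method missed entirely,
applies complete-case or zero-imputation missing-data strategies, and
compares methods with

* an extended Bland-Altman analysis for repeated measures within subjects —
  the variance of a single between-method difference is partitioned into
  between- and within-subject components via one-way random-effects ANOVA
  on the per-subject differences, and the 95% limits of agreement are
  bias +/- 1.96 * sqrt(between + within);
* two-sided Wilcoxon signed-rank tests on participant-level mean measures,
  exact (sign-assignment null) for small untied samples and
  normal-approximate with tie and continuity corrections otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from .sleep_measures import MEASURE_NAMES, DailyMeasures

__all__ = [
    "BlandAltmanResult",
    "WilcoxonResult",
    "MissedNightReport",
    "build_paired_daily_table",
    "missed_night_report",
    "apply_missing_strategy",
    "extended_bland_altman",
    "wilcoxon_signed_rank",
    "participant_means",
]


def build_paired_daily_table(
    daily_by_method: dict[str, list[DailyMeasures]],
    log_days: dict[str, list[date]] | None = None,
) -> pd.DataFrame:
    """Assemble the paired daily table from each method's daily measures.

    Returns a DataFrame indexed by (participant_id, day) with hierarchical
    columns (method, measure). Cells are NaN on days where a method
    detected no period. When ``log_days`` (participant -> diary-documented
    days) is given, the row index is the union of those days, so
    method-missed nights appear as missing rows for that method; otherwise
    the index is the union of days any method produced.
    """
    frames = {}
    for method, dailies in daily_by_method.items():
        rows = {}
        for d in dailies:
            key = (d.participant_id, d.calendar_day)
            if key in rows:
                raise ValueError(f"duplicate day {key} for method {method}")
            rec = d.measures.as_dict()
            rec["n_periods"] = d.n_periods
            rows[key] = rec
        frames[method] = pd.DataFrame.from_dict(rows, orient="index")

    if log_days is not None:
        index = pd.MultiIndex.from_tuples(
            [(pid, day) for pid, days in log_days.items() for day in days],
            names=["participant_id", "day"],
        )
    else:
        keys = sorted({k for f in frames.values() for k in f.index})
        index = pd.MultiIndex.from_tuples(keys, names=["participant_id", "day"])

    out = pd.concat(
        {m: f.reindex(index) for m, f in frames.items()}, axis=1
    )
    out.columns.names = ["method", "measure"]
    out.index.names = ["participant_id", "day"]
    return out.sort_index()


@dataclass(frozen=True)
class MissedNightReport:
    method: str
    n_missed_days: int
    n_days: int
    fraction_days_missed: float
    n_affected_participants: int
    n_participants: int
    fraction_participants_affected: float
    mean_missed_per_affected: float


def missed_night_report(daily: pd.DataFrame, method: str) -> MissedNightReport:
    """Count diary-documented nights for which a method found no period.

    ``daily`` must be a paired table whose rows enumerate the documented
    nights; a missing cell block for the method marks a missed night.
    """
    missing = daily[method].isna().all(axis=1)
    per_part = missing.groupby(level="participant_id").sum()
    affected = per_part[per_part > 0]
    n_missed = int(missing.sum())
    return MissedNightReport(
        method=method,
        n_missed_days=n_missed,
        n_days=len(daily),
        fraction_days_missed=n_missed / len(daily) if len(daily) else 0.0,
        n_affected_participants=len(affected),
        n_participants=per_part.size,
        fraction_participants_affected=(
            len(affected) / per_part.size if per_part.size else 0.0
        ),
        mean_missed_per_affected=float(affected.mean()) if len(affected) else 0.0,
    )


def apply_missing_strategy(daily: pd.DataFrame, strategy: str) -> pd.DataFrame:
    """Resolve missing method-days: ``complete_case`` drops any row with a
    missing cell; ``zero_impute`` fills missing cells with zero."""
    if strategy == "complete_case":
        return daily.dropna(axis=0, how="any")
    if strategy == "zero_impute":
        return daily.fillna(0.0)
    raise ValueError(f"unknown missing-data strategy {strategy!r}")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement for repeated paired measurements.

    ``direction`` records which difference was analysed (method_a minus
    method_b); the between/within variance components of a single
    difference are exposed for audit.
    """

    measure: str
    direction: str
    mean_bias: float
    loa_low: float
    loa_high: float
    between_subject_var: float
    within_subject_var: float
    n_subjects: int
    n_observations: int


def extended_bland_altman(
    daily: pd.DataFrame, measure: str, method_a: str, method_b: str
) -> BlandAltmanResult:
    """Repeated-measures limits of agreement for one sleep measure.

    Differences ``method_a - method_b`` are grouped by subject. The bias is
    the grand mean of all differences. Variance components come from
    one-way random-effects ANOVA: within = mean square within subjects;
    between = (MSB - MSW) / n0, clamped at zero, with n0 the standard
    unequal-replicates divisor (N - sum(n_i^2)/N) / (m - 1). The 95% limits
    are bias +/- 1.96 * sqrt(between + within). With one observation per
    subject throughout, the within component has no degrees of freedom and
    the analysis reduces to the classic single-measurement form (total
    variance of the differences).
    """
    pair = daily[[(method_a, measure), (method_b, measure)]].dropna()
    d = (pair[(method_a, measure)] - pair[(method_b, measure)]).astype(float)
    groups = d.groupby(level="participant_id")
    m = groups.ngroups
    if m < 2:
        raise ValueError("at least two subjects are required")
    N = len(d)
    bias = float(d.mean())

    n_i = groups.size().to_numpy(dtype=float)
    means_i = groups.mean().to_numpy()
    ss_between = float(np.sum(n_i * (means_i - bias) ** 2))
    ss_within = float(((d - groups.transform("mean")) ** 2).sum())
    df_between = m - 1
    df_within = N - m
    if df_within > 0:
        msw = ss_within / df_within
        msb = ss_between / df_between
        n0 = (N - np.sum(n_i**2) / N) / (m - 1)
        between = max(0.0, (msb - msw) / n0)
        within = msw
    else:
        # single replicate per subject: classic Bland-Altman
        between = float(d.var(ddof=1))
        within = 0.0
    sd = float(np.sqrt(between + within))
    return BlandAltmanResult(
        measure=measure,
        direction=f"{method_a} - {method_b}",
        mean_bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        between_subject_var=between,
        within_subject_var=within,
        n_subjects=m,
        n_observations=N,
    )


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str  # "exact" | "approx" | "degenerate"


def wilcoxon_signed_rank(means_a, means_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired participant means.

    Zero differences are dropped (classical treatment). The exact
    sign-assignment null distribution is used when at most 25 non-zero
    differences remain and their absolute values are untied; otherwise the
    normal approximation with tie and continuity corrections applies. All
    differences zero yields p = 1 flagged degenerate.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    d = a - b
    d = d[d != 0]
    n_eff = len(d)
    if n_eff == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_effective=0,
                              method="degenerate")
    has_ties = len(np.unique(np.abs(d))) < n_eff
    if n_eff <= 25 and not has_ties:
        res = stats.wilcoxon(d, alternative="two-sided", method="exact",
                             zero_method="wilcox")
        method = "exact"
    else:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             zero_method="wilcox", correction=True)
        method = "approx"
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n_effective=n_eff,
        method=method,
    )


def participant_means(daily: pd.DataFrame, measure: str, method: str) -> pd.Series:
    """Arithmetic mean of a measure over each participant's observed days.

    Participants with no observed day for the method (possible after
    complete-case filtering) are excluded.
    """
    col = daily[(method, measure)]
    means = col.groupby(level="participant_id").mean()
    return means.dropna()
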