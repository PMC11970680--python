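"""The ten per-period sleep measures and their daily aggregation.

Per sleep period (all durations in minutes):

* latency — wake epochs between period start and the first sleep epoch
  (structurally zero for Tudor-Locke periods).
* total minutes in bed (TIB) — the period duration.
* total sleep time (TST) — sleep-classified epochs in the period.
* WASO — wake-classified epochs after the first sleep epoch.
* number of awakenings — maximal wake runs after the first sleep epoch
  (a single epoch counts as a run).
* average awakening length — WASO / number of awakenings (0 when none).
* efficiency — 100 * TST / TIB.
* movement index (MI) — 100 * (epochs with count >= 1) / TIB.
* fragmentation index (FI) — 100 * (one-epoch sleep runs) / (all sleep runs).
* sleep fragmentation index (SFI) — MI + FI.

Daily aggregation pools the building blocks across a day's periods (sums of
TST, TIB, WASO, awakenings, active epochs, sleep runs) and re-forms the
ratio measures from the pooled sums — not by averaging per-period
percentages. A period belongs to the calendar day on which it ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .core_io import EpochSeries
from .sleep_wake_scoring import SLEEP, SleepWakeSeries
from .tudor_locke import SleepPeriod

__all__ = [
    "SleepMeasures",
    "DailyMeasures",
    "MEASURE_NAMES",
    "compute_measures",
    "assign_day",
    "aggregate_daily",
]

MEASURE_NAMES = (
    "latency",
    "efficiency",
    "total_minutes_in_bed",
    "total_sleep_time",
    "waso",
    "n_awakenings",
    "avg_awakening_len",
    "movement_index",
    "fragmentation_index",
    "sleep_fragmentation_index",
)


@dataclass(frozen=True)
class SleepMeasures:
    """The ten sleep measures for one period (or one pooled day).

    Invariants: TIB = latency + TST + WASO; efficiency = 100*TST/TIB;
    SFI = MI + FI.
    """

    latency: float
    efficiency: float
    total_minutes_in_bed: float
    total_sleep_time: float
    waso: float
    n_awakenings: int
    avg_awakening_len: float
    movement_index: float
    fragmentation_index: float
    sleep_fragmentation_index: float
    # pooled building blocks carried for daily aggregation
    n_active_epochs: int = 0
    n_sleep_runs: int = 0
    n_one_epoch_sleep_runs: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


@dataclass(frozen=True)
class DailyMeasures:
    participant_id: str
    calendar_day: date
    measures: SleepMeasures
    n_periods: int


def _sleep_runs(states: np.ndarray) -> tuple[int, int]:
    """(number of maximal sleep runs, number of length-1 sleep runs)."""
    padded = np.concatenate(([0], states == SLEEP, [0])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    return len(lengths), int((lengths == 1).sum())


def compute_measures(
    period: SleepPeriod, sw: SleepWakeSeries, epochs: EpochSeries,
    fi_definition: str = "bout_ratio",
) -> SleepMeasures:
    """Compute the ten measures for one sleep period.

    Awakenings are counted only after the first sleep epoch (the WASO
    anchor); a diary period containing no sleep epochs yields latency equal
    to its full duration with TST, WASO and efficiency of zero.

    ``fi_definition`` selects the fragmentation-index form: ``"bout_ratio"``
    (one-epoch sleep runs over all sleep runs, the default) or ``"per_tst"``
    (one-epoch sleep runs over total sleep time), kept for sensitivity
    checking between the two published phrasings.
    """
    if fi_definition not in ("bout_ratio", "per_tst"):
        raise ValueError(f"unknown fi_definition {fi_definition!r}")
    if not sw.aligned_with(epochs):
        raise ValueError("sleep/wake series is not aligned with the epoch series")
    if period.end_epoch >= len(sw):
        raise ValueError("period extends past the series")
    states = sw.states[period.onset_epoch : period.end_epoch + 1]
    counts = epochs.counts[period.onset_epoch : period.end_epoch + 1]
    tib = len(states)
    if tib == 0:
        raise ValueError("zero-length period")

    sleep_idx = np.flatnonzero(states == SLEEP)
    if len(sleep_idx) == 0:
        latency, tst, waso = tib, 0, 0
        n_awak = 0
        n_runs = n_one = 0
    else:
        first = int(sleep_idx[0])
        latency = first
        tst = int(len(sleep_idx))
        after = states[first:]
        waso = int((after != SLEEP).sum())
        wake_runs, _ = _sleep_runs(1 - after)  # wake runs within the post-onset span
        n_awak = wake_runs
        n_runs, n_one = _sleep_runs(states)

    efficiency = 100.0 * tst / tib
    avg_awak = waso / n_awak if n_awak > 0 else 0.0
    active = int((counts >= 1).sum())
    mi = 100.0 * active / tib
    if fi_definition == "per_tst":
        fi = 100.0 * n_one / tst if tst > 0 else 0.0
    else:
        fi = 100.0 * n_one / n_runs if n_runs > 0 else 0.0
    return SleepMeasures(
        latency=float(latency),
        efficiency=efficiency,
        total_minutes_in_bed=float(tib),
        total_sleep_time=float(tst),
        waso=float(waso),
        n_awakenings=int(n_awak),
        avg_awakening_len=avg_awak,
        movement_index=mi,
        fragmentation_index=fi,
        sleep_fragmentation_index=mi + fi,
        n_active_epochs=active,
        n_sleep_runs=n_runs,
        n_one_epoch_sleep_runs=n_one,
    )


def assign_day(period: SleepPeriod, epochs: EpochSeries) -> date:
    """Calendar day a period belongs to: the date containing its final minute.

    Using the last epoch's *start* resolves the midnight edge case: a period
    whose last epoch is [23:59, 00:00) belongs to the earlier day.
    """
    return epochs.time_at(period.end_epoch).date()


def aggregate_daily(
    measures: list[tuple[SleepPeriod, SleepMeasures]], epochs: EpochSeries
) -> list[DailyMeasures]:
    """Pool per-period measures into one row per calendar day.

    Sums latency, TIB, TST, WASO and awakening counts; re-forms efficiency,
    MI and FI from pooled numerators/denominators; average awakening length
    pools all awakenings (sum WASO / sum awakenings). Duplicate periods over
    the same interval are rejected.
    """
    seen = set()
    for p, _ in measures:
        key = (p.onset_epoch, p.end_epoch)
        if key in seen:
            raise ValueError("duplicate period for the same interval")
        seen.add(key)

    by_day: dict[date, list[tuple[SleepPeriod, SleepMeasures]]] = {}
    for p, m in measures:
        by_day.setdefault(assign_day(p, epochs), []).append((p, m))

    out = []
    for day in sorted(by_day):
        group = by_day[day]
        latency = sum(m.latency for _, m in group)
        tib = sum(m.total_minutes_in_bed for _, m in group)
        tst = sum(m.total_sleep_time for _, m in group)
        waso = sum(m.waso for _, m in group)
        n_awak = sum(m.n_awakenings for _, m in group)
        active = sum(m.n_active_epochs for _, m in group)
        n_runs = sum(m.n_sleep_runs for _, m in group)
        n_one = sum(m.n_one_epoch_sleep_runs for _, m in group)
        mi = 100.0 * active / tib if tib > 0 else 0.0
        fi = 100.0 * n_one / n_runs if n_runs > 0 else 0.0
        pooled = SleepMeasures(
            latency=float(latency),
            efficiency=100.0 * tst / tib if tib > 0 else 0.0,
            total_minutes_in_bed=float(tib),
            total_sleep_time=float(tst),
            waso=float(waso),
            n_awakenings=int(n_awak),
            avg_awakening_len=waso / n_awak if n_awak > 0 else 0.0,
            movement_index=mi,
            fragmentation_index=fi,
            sleep_fragmentation_index=mi + fi,
            n_active_epochs=int(active),
            n_sleep_runs=int(n_runs),
            n_one_epoch_sleep_runs=int(n_one),
        )
        out.append(
            DailyMeasures(
                participant_id=group[0][0].participant_id,
                calendar_day=day,
                measures=pooled,
                n_periods=len(group),
            )
        )
    return out
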