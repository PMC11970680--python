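"""Tudor-Locke sleep-period detection from a sleep/wake epoch series.

The algorithm scans left to right. A sleep period opens at the first run of
at least ``bedtime_def`` consecutive sleep epochs, and is terminated by the
first subsequent run of at least ``waketime_def`` consecutive wake epochs
(or the series end). The period's last epoch is the final sleep epoch before
the terminating wake run, so every detected period both starts and ends on a
sleep epoch — which is why sleep-onset latency is structurally zero for
periods this detector produces. A candidate is kept only if its duration is
at least ``min_period_len`` and below ``max_period_len`` minutes and it
contains at least ``min_nonzero_epochs`` epochs with non-zero activity
counts (the non-wear guard). Rejected candidates do not block later periods:
scanning resumes after the terminating wake run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import EpochSeries, SleepLogEntry
from .sleep_wake_scoring import SLEEP, SleepWakeSeries

__all__ = ["TLParameters", "SleepPeriod", "detect_sleep_periods", "periods_from_log"]


@dataclass(frozen=True)
class TLParameters:
    """The five Tudor-Locke tuning parameters (units: one-minute epochs).

    Defaults are the ActiLife defaults: bedtime definition 5, wake-time
    definition 10, minimum period length 160 min, minimum non-zero epochs 0,
    maximum period length 1440 min.
    """

    bedtime_def: int = 5
    waketime_def: int = 10
    min_period_len: int = 160
    min_nonzero_epochs: int = 0
    max_period_len: int = 1440

    def __post_init__(self):
        if self.bedtime_def < 1 or self.waketime_def < 1:
            raise ValueError("bedtime_def and waketime_def must be >= 1")
        if min(self.min_period_len, self.min_nonzero_epochs, self.max_period_len) < 0:
            raise ValueError("parameters must be non-negative")
        if self.min_period_len > self.max_period_len:
            raise ValueError("min_period_len must not exceed max_period_len")


@dataclass(frozen=True)
class SleepPeriod:
    """A contiguous epoch interval identified as one sleep session.

    ``onset_epoch`` and ``end_epoch`` are inclusive indices into the source
    series; ``source`` is "TL" for algorithm-detected periods (first epoch
    always sleep-classified) or "LOG" for diary-defined periods.
    """

    participant_id: str
    onset_epoch: int
    end_epoch: int
    source: str  # "TL" | "LOG"

    def __post_init__(self):
        if self.end_epoch < self.onset_epoch:
            raise ValueError("end_epoch must be >= onset_epoch")
        if self.source not in ("TL", "LOG"):
            raise ValueError("source must be 'TL' or 'LOG'")

    @property
    def duration_min(self) -> int:
        return self.end_epoch - self.onset_epoch + 1


def _runs(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode: (values, start indices, lengths) of maximal runs."""
    n = len(states)
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return states[starts], starts, ends - starts


def _detect_on_runs(values, starts, lengths, nz_cumsum, params: TLParameters):
    """Core scan over run-length-encoded states; returns (onset, end) pairs.

    ``nz_cumsum`` is the prefix sum of the non-zero-count indicator, length
    n+1, used for the minimum-non-zero-epochs filter.
    """
    out = []
    nruns = len(values)
    i = 0
    while i < nruns:
        # bedtime: first sleep run >= bedtime_def at or after scan position
        while i < nruns and not (values[i] == SLEEP and lengths[i] >= params.bedtime_def):
            i += 1
        if i == nruns:
            break
        onset = int(starts[i])
        # scan forward for terminating wake run
        j = i + 1
        while j < nruns and not (values[j] != SLEEP and lengths[j] >= params.waketime_def):
            j += 1
        if j < nruns:
            end = int(starts[j]) - 1  # epoch before the wake run; sleep by maximality
            resume = j + 1
        else:
            # series ended mid-period: close at last sleep epoch
            k = nruns - 1
            while values[k] != SLEEP:
                k -= 1
            end = int(starts[k] + lengths[k]) - 1
            resume = nruns
        duration = end - onset + 1
        nonzero = int(nz_cumsum[end + 1] - nz_cumsum[onset])
        if (
            params.min_period_len <= duration < params.max_period_len
            and nonzero >= params.min_nonzero_epochs
        ):
            out.append((onset, end))
        i = resume
    return out


def detect_sleep_periods(
    sw: SleepWakeSeries, epochs: EpochSeries, params: TLParameters | None = None
) -> list[SleepPeriod]:
    """Run the Tudor-Locke scan and return accepted sleep periods in time order.

    ``sw`` must be aligned to ``epochs`` (same participant, start, length);
    the counts are needed only for the minimum-non-zero-epochs filter.
    """
    params = params or TLParameters()
    if not sw.aligned_with(epochs):
        raise ValueError("sleep/wake series is not aligned with the epoch series")
    values, starts, lengths = _runs(sw.states)
    nz_cumsum = np.concatenate(([0], np.cumsum(epochs.counts >= 1)))
    pairs = _detect_on_runs(values, starts, lengths, nz_cumsum, params)
    return [
        SleepPeriod(sw.participant_id, onset, end, source="TL") for onset, end in pairs
    ]


def periods_from_log(entries: list[SleepLogEntry], epochs: EpochSeries) -> list[SleepPeriod]:
    """Convert diary entries into LOG-source periods on the epoch grid.

    Each entry maps to the half-open interval [in_bed, out_bed); no duration
    or activity filters apply to diary periods. Entries outside the series
    span raise an error.
    """
    periods = []
    for e in entries:
        if e.participant_id != epochs.participant_id:
            raise ValueError("log entry participant does not match epoch series")
        if e.in_bed < epochs.start_time or e.out_bed > epochs.end_time:
            raise ValueError(f"log entry {e.in_bed}->{e.out_bed} outside series span")
        onset = epochs.index_of(e.in_bed)
        end = onset + e.duration_min - 1
        periods.append(SleepPeriod(epochs.participant_id, onset, end, source="LOG"))
    return sorted(periods, key=lambda p: p.onset_epoch)
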