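"""Data model, readers/writers, and validation for epoch count files and
sleep logs.

The central container is :class:`EpochSeries`: a regular one-minute grid of
non-negative integer activity counts for a single participant-recording.
Epoch ``i`` covers the half-open interval ``[start_time + i min,
start_time + (i+1) min)``; every epoch index maps to exactly one calendar
minute and the mapping is invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "SleepLogEntry",
    "ParticipantDataset",
    "CsvDialect",
    "EligibilityReport",
    "read_epoch_csv",
    "read_epoch_csv_long",
    "write_epoch_csv",
    "read_sleep_log",
    "write_sleep_log",
    "check_night_sufficiency",
]

_MIN = pd.Timedelta(minutes=1)


def round_to_minute(ts: pd.Timestamp) -> pd.Timestamp:
    """Round a timestamp to the nearest whole minute; exact 30 s ties round down."""
    ts = pd.Timestamp(ts)
    floor = ts.floor("min")
    remainder = ts - floor
    if remainder > pd.Timedelta(seconds=30):
        return floor + _MIN
    return floor


@dataclass(frozen=True)
class EpochSeries:
    """One-minute epoch activity counts for a single participant-recording.

    Parameters
    ----------
    participant_id
        Identifier of the participant/recording.
    start_time
        Timestamp of the first epoch's start; must be minute-aligned.
    counts
        Non-negative integer activity count per 60 s epoch, length >= 1,
        contiguous (no gaps).
    wear_mask
        Optional per-epoch boolean, True where the device was worn. Defaults
        to all-worn.
    """

    participant_id: str
    start_time: pd.Timestamp
    counts: np.ndarray
    wear_mask: np.ndarray | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.min() < 0:
            raise ValueError("counts must be >= 0")
        start = pd.Timestamp(self.start_time)
        if start != start.floor("min"):
            raise ValueError("start_time must be minute-aligned")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "start_time", start)
        if self.wear_mask is not None:
            wear = np.asarray(self.wear_mask, dtype=bool)
            if wear.shape != counts.shape:
                raise ValueError("wear_mask must match counts length")
            object.__setattr__(self, "wear_mask", wear)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end_time(self) -> pd.Timestamp:
        """End of the last epoch (exclusive bound of the recording span)."""
        return self.start_time + len(self) * _MIN

    def time_at(self, index: int) -> pd.Timestamp:
        """Start timestamp of epoch ``index``."""
        return self.start_time + int(index) * _MIN

    def index_of(self, ts: pd.Timestamp) -> int:
        """Epoch index whose minute contains ``ts``; raises if outside the span."""
        ts = pd.Timestamp(ts)
        idx = (ts - self.start_time) // _MIN
        if idx < 0 or idx >= len(self):
            raise ValueError(f"timestamp {ts} outside recording span")
        return int(idx)

    def worn(self) -> np.ndarray:
        """Per-epoch wear indicator (all True when no mask supplied)."""
        if self.wear_mask is None:
            return np.ones(len(self), dtype=bool)
        return self.wear_mask


@dataclass(frozen=True, order=True)
class SleepLogEntry:
    """One self-reported night: in-bed and out-of-bed timestamps.

    Covered minutes are the half-open interval ``[in_bed, out_bed)`` on the
    epoch grid; timestamps are rounded to the nearest whole minute.
    """

    participant_id: str = field(compare=False)
    in_bed: pd.Timestamp
    out_bed: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "in_bed", round_to_minute(self.in_bed))
        object.__setattr__(self, "out_bed", round_to_minute(self.out_bed))
        if self.out_bed <= self.in_bed:
            raise ValueError(
                f"out_bed must follow in_bed ({self.in_bed} -> {self.out_bed})"
            )

    @property
    def duration_min(self) -> int:
        return int((self.out_bed - self.in_bed) / _MIN)


@dataclass
class ParticipantDataset:
    """Epoch series plus sleep-log entries for one participant."""

    epochs: EpochSeries
    log: list[SleepLogEntry]

    def __post_init__(self):
        entries = sorted(self.log, key=lambda e: e.in_bed)
        for e in entries:
            if e.participant_id != self.epochs.participant_id:
                raise ValueError("log entry participant does not match epoch series")
            if e.in_bed < self.epochs.start_time or e.out_bed > self.epochs.end_time:
                raise ValueError(f"log entry {e.in_bed}->{e.out_bed} outside series span")
        for a, b in zip(entries, entries[1:]):
            if b.in_bed < a.out_bed:
                raise ValueError("overlapping sleep-log entries")
        self.log = entries

    @property
    def participant_id(self) -> str:
        return self.epochs.participant_id


@dataclass
class CsvDialect:
    """Column names and parsing options for epoch CSV files.

    ``zero_fill=True`` fills interior minute gaps with count 0 and marks the
    filled minutes as non-wear; otherwise a gap is an error.
    """

    timestamp_col: str = "timestamp"
    counts_col: str = "counts"
    wear_col: str = "wear"
    participant_col: str = "participant_id"
    timestamp_format: str | None = None  # None -> ISO-8601 via pandas
    zero_fill: bool = False


def _series_from_frame(df: pd.DataFrame, participant_id: str, dialect: CsvDialect) -> EpochSeries:
    times = pd.to_datetime(df[dialect.timestamp_col], format=dialect.timestamp_format)
    if (times != times.dt.floor("min")).any():
        raise ValueError("epoch timestamps must be minute-aligned")
    diffs = times.diff().dropna()
    if (diffs <= pd.Timedelta(0)).any():
        raise ValueError("epoch timestamps must be strictly increasing")
    counts = pd.to_numeric(df[dialect.counts_col])
    if (counts < 0).any():
        raise ValueError("negative activity counts")
    wear = None
    if dialect.wear_col in df.columns:
        wear = df[dialect.wear_col].astype(int).astype(bool).to_numpy()

    start = times.iloc[0]
    n = int((times.iloc[-1] - start) / _MIN) + 1
    if n != len(times):
        if not dialect.zero_fill:
            raise ValueError("gap in minute grid (set zero_fill to fill as non-wear)")
        idx = ((times - start) / _MIN).astype(int).to_numpy()
        full_counts = np.zeros(n, dtype=np.int64)
        full_counts[idx] = counts.to_numpy()
        full_wear = np.zeros(n, dtype=bool)
        full_wear[idx] = True if wear is None else wear
        counts, wear = full_counts, full_wear
    else:
        counts = counts.to_numpy()
    return EpochSeries(participant_id, start, np.asarray(counts), wear)


def read_epoch_csv(path, dialect: CsvDialect | None = None,
                   participant_id: str | None = None) -> EpochSeries:
    """Read a single-participant epoch CSV into a validated :class:`EpochSeries`.

    The file needs ``timestamp`` and ``counts`` columns (names configurable
    via ``dialect``); an optional ``wear`` column (0/1) becomes the wear mask.
    ``participant_id`` defaults to the file's participant column if present,
    else the file stem.
    """
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path)
    if dialect.participant_col in df.columns:
        ids = df[dialect.participant_col].astype(str).unique()
        if len(ids) > 1:
            raise ValueError("multiple participants in file; use read_epoch_csv_long")
        pid = participant_id or ids[0]
    else:
        from pathlib import Path

        pid = participant_id or Path(path).stem
    return _series_from_frame(df, pid, dialect)


def read_epoch_csv_long(path, dialect: CsvDialect | None = None) -> dict[str, EpochSeries]:
    """Read a long-format epoch CSV (with a participant column) into a dict."""
    dialect = dialect or CsvDialect()
    df = pd.read_csv(path)
    if dialect.participant_col not in df.columns:
        raise ValueError(f"long format requires a {dialect.participant_col!r} column")
    out = {}
    for pid, sub in df.groupby(dialect.participant_col, sort=True):
        out[str(pid)] = _series_from_frame(sub.reset_index(drop=True), str(pid), dialect)
    return out


def write_epoch_csv(series: EpochSeries, path, dialect: CsvDialect | None = None) -> None:
    """Write an EpochSeries to CSV; round-trips exactly through read_epoch_csv."""
    dialect = dialect or CsvDialect()
    times = pd.date_range(series.start_time, periods=len(series), freq="min")
    df = pd.DataFrame(
        {
            dialect.participant_col: series.participant_id,
            dialect.timestamp_col: [t.isoformat() for t in times],
            dialect.counts_col: series.counts,
        }
    )
    if series.wear_mask is not None:
        df[dialect.wear_col] = series.wear_mask.astype(int)
    df.to_csv(path, index=False)


def read_sleep_log(path) -> list[SleepLogEntry]:
    """Read a sleep-log CSV (``participant_id,in_bed,out_bed``) into validated,
    minute-rounded, time-sorted entries; overlapping nights for one
    participant are rejected."""
    df = pd.read_csv(path)
    for col in ("participant_id", "in_bed", "out_bed"):
        if col not in df.columns:
            raise ValueError(f"sleep log missing column {col!r}")
    entries = [
        SleepLogEntry(str(r.participant_id), pd.Timestamp(r.in_bed), pd.Timestamp(r.out_bed))
        for r in df.itertuples()
    ]
    entries.sort(key=lambda e: (e.participant_id, e.in_bed))
    for a, b in zip(entries, entries[1:]):
        if a.participant_id == b.participant_id and b.in_bed < a.out_bed:
            raise ValueError(
                f"overlapping log entries for participant {a.participant_id}"
            )
    return entries


def write_sleep_log(entries: list[SleepLogEntry], path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in entries],
            "in_bed": [e.in_bed.isoformat() for e in entries],
            "out_bed": [e.out_bed.isoformat() for e in entries],
        }
    )
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class EligibilityReport:
    participant_id: str
    n_valid_nights: int
    n_logged_nights: int
    eligible: bool


def check_night_sufficiency(dataset: ParticipantDataset, min_nights: int = 5,
                            min_wear_fraction: float = 0.8) -> EligibilityReport:
    """Count nights with both a log entry and the device worn in bed.

    A logged night is valid when the wear mask is True for at least
    ``min_wear_fraction`` of the logged window. A participant is eligible
    when at least ``min_nights`` (default 5) valid nights exist; nights need
    not be consecutive.
    """
    if min_nights < 1:
        raise ValueError("min_nights must be >= 1")
    worn = dataset.epochs.worn()
    n_valid = 0
    for entry in dataset.log:
        i0 = dataset.epochs.index_of(entry.in_bed)
        i1 = i0 + entry.duration_min  # exclusive
        frac = worn[i0:i1].mean() if i1 > i0 else 0.0
        if frac >= min_wear_fraction:
            n_valid += 1
    return EligibilityReport(
        participant_id=dataset.participant_id,
        n_valid_nights=n_valid,
        n_logged_nights=len(dataset.log),
        eligible=n_valid >= min_nights,
    )
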