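"""Seeded generator of synthetic actigraphy cohorts with known ground truth.

Each participant receives a multi-day one-minute epoch series spanning all
nights plus surrounding daytime. Nightly true sleep windows are drawn
around a mean bedtime and time-in-bed with night-to-night jitter; mid-sleep
wake bouts ("restlessness") are planted inside the window; activity counts
are drawn from wake-like and sleep-like count distributions (wake epochs a
zero-inflated negative binomial with high mean, sleep epochs mostly zero
with a small movement probability); and diary entries are the true windows
perturbed by Gaussian recall noise, rounded to the minute. Optional
non-wear blocks are placed in daytime.

The generator reproduces the statistical structure the pipeline assumes —
regular minute grids, one sleep window per night, diary offsets — not
biomechanically realistic acceleration. All draws are deterministic given
the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import EpochSeries, ParticipantDataset, SleepLogEntry

__all__ = ["CohortSpec", "SyntheticTruth", "generate_cohort", "chronic_pain_preset"]

_MIN = pd.Timedelta(minutes=1)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic actigraphy cohort.

    Times are minutes unless noted. ``mean_bedtime_hour`` is the clock hour
    (0-24) of the average true in-bed time; awakenings per night are
    Poisson with mean ``awakenings_per_night`` and lengths uniform on
    ``awakening_len_range``. ``movement_prob`` is the chance a sleeping
    minute registers any activity. Recall noise (diary vs truth) is
    Gaussian with SD ``recall_noise_sd`` applied independently to both ends
    of each night.
    """

    n_participants: int = 16
    nights_per_participant: int = 7
    mean_bedtime_hour: float = 22.5
    mean_time_in_bed: float = 538.0
    schedule_jitter_sd: float = 30.0
    awakenings_per_night: float = 5.0
    awakening_len_range: tuple[int, int] = (12, 20)
    wake_count_mean: float = 250.0
    wake_count_dispersion: float = 1.5
    wake_zero_prob: float = 0.15
    movement_prob: float = 0.12
    sleep_count_mean: float = 3.0
    recall_noise_sd: float = 10.0
    nonwear_prob: float = 0.0
    nonwear_len_range: tuple[int, int] = (60, 180)
    nap_prob: float = 0.0
    nap_len_range: tuple[int, int] = (30, 90)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.nights_per_participant < 1:
            raise ValueError("cohort must have >= 1 participant and night")
        for name in ("schedule_jitter_sd", "awakenings_per_night", "recall_noise_sd",
                     "movement_prob", "nonwear_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.awakening_len_range
        if not (0 < lo <= hi):
            raise ValueError("awakening_len_range must be positive and ordered")
        if self.awakenings_per_night * hi >= self.mean_time_in_bed * 0.75:
            raise ValueError("awakening load exceeds the sleep window")


@dataclass
class SyntheticTruth:
    """Ground truth for one participant: true nightly sleep windows,
    awakening bouts inside them, and non-wear blocks (epoch index pairs,
    inclusive start / exclusive end)."""

    participant_id: str
    sleep_windows: list[tuple[int, int]]
    awakenings: list[list[tuple[int, int]]]
    nonwear: list[tuple[int, int]]
    naps: list[tuple[int, int]] = field(default_factory=list)


def chronic_pain_preset(seed: int = 0) -> CohortSpec:
    """Cohort shaped like a restless adult chronic-pain study population.

    16 participants, 7 nights each, ~538 min mean time in bed, elevated
    mid-sleep awakening rate with 12-20 min bouts, and 10 min diary recall
    noise.
    """
    return CohortSpec(seed=seed)


def _draw_wake_counts(rng: np.random.Generator, n: int, spec: CohortSpec) -> np.ndarray:
    """Zero-inflated negative binomial wake-epoch counts."""
    r = spec.wake_count_dispersion
    p = r / (r + spec.wake_count_mean)
    counts = rng.negative_binomial(r, p, size=n)
    counts[rng.random(n) < spec.wake_zero_prob] = 0
    return counts.astype(np.int64)


def _draw_sleep_counts(rng: np.random.Generator, n: int, spec: CohortSpec) -> np.ndarray:
    """Mostly-zero sleep-epoch counts: Bernoulli(movement_prob) gate on a
    small positive Poisson."""
    moving = rng.random(n) < spec.movement_prob
    counts = np.zeros(n, dtype=np.int64)
    k = int(moving.sum())
    if k:
        counts[moving] = 1 + rng.poisson(spec.sleep_count_mean, size=k)
    return counts


def _generate_participant(
    pid: str, spec: CohortSpec, rng: np.random.Generator
) -> tuple[ParticipantDataset, SyntheticTruth]:
    start = pd.Timestamp("2024-03-01 12:00")
    n_epochs = (spec.nights_per_participant + 1) * 1440  # noon to noon
    counts = _draw_wake_counts(rng, n_epochs, spec)
    wear = np.ones(n_epochs, dtype=bool)

    windows: list[tuple[int, int]] = []
    awakenings: list[list[tuple[int, int]]] = []
    log: list[SleepLogEntry] = []
    prev_end = 0
    prev_ob = 0
    for night in range(spec.nights_per_participant):
        bed_min = (
            night * 1440
            + (spec.mean_bedtime_hour - 12.0) * 60.0
            + rng.normal(0.0, spec.schedule_jitter_sd)
        )
        tib = spec.mean_time_in_bed + rng.normal(0.0, spec.schedule_jitter_sd)
        tib = int(np.clip(round(tib), 120, 1000))
        bed = int(np.clip(round(bed_min), prev_end + 60, n_epochs - tib - 60))
        wake = bed + tib  # exclusive
        prev_end = wake

        counts[bed:wake] = _draw_sleep_counts(rng, tib, spec)

        # plant mid-sleep wake bouts, kept off the window edges and disjoint
        bouts: list[tuple[int, int]] = []
        n_bouts = rng.poisson(spec.awakenings_per_night)
        occupied = np.zeros(tib, dtype=bool)
        margin = 30
        for _ in range(n_bouts):
            length = int(rng.integers(spec.awakening_len_range[0],
                                      spec.awakening_len_range[1] + 1))
            if tib - 2 * margin - length <= 0:
                continue
            for _attempt in range(10):
                off = int(rng.integers(margin, tib - margin - length))
                if not occupied[max(0, off - 3) : off + length + 3].any():
                    occupied[off : off + length] = True
                    counts[bed + off : bed + off + length] = _draw_wake_counts(
                        rng, length, spec
                    )
                    bouts.append((bed + off, bed + off + length))
                    break
        bouts.sort()
        windows.append((bed, wake))
        awakenings.append(bouts)

        in_noise = rng.normal(0.0, spec.recall_noise_sd)
        out_noise = rng.normal(0.0, spec.recall_noise_sd)
        lb = int(np.clip(round(bed + in_noise), prev_ob, n_epochs - 31))
        ob = int(np.clip(round(wake + out_noise), lb + 30, n_epochs))
        prev_ob = ob
        log.append(
            SleepLogEntry(pid, start + lb * _MIN, start + ob * _MIN)
        )

    # unlogged daytime naps (off by default): exercise multi-period days
    naps: list[tuple[int, int]] = []
    if spec.nap_prob > 0:
        for day in range(spec.nights_per_participant):
            if rng.random() < spec.nap_prob:
                length = int(rng.integers(spec.nap_len_range[0],
                                          spec.nap_len_range[1] + 1))
                off = day * 1440 + int(rng.integers(60, 480 - length))
                counts[off : off + length] = _draw_sleep_counts(rng, length, spec)
                naps.append((off, off + length))

    nonwear: list[tuple[int, int]] = []
    if spec.nonwear_prob > 0:
        in_bed = np.zeros(n_epochs, dtype=bool)
        for b, w in windows:
            in_bed[b:w] = True
        for day in range(spec.nights_per_participant + 1):
            if rng.random() < spec.nonwear_prob:
                length = int(rng.integers(*spec.nonwear_len_range))
                off = day * 1440 + int(rng.integers(0, max(1, 1440 - length)))
                hi = min(off + length, n_epochs)
                seg = ~in_bed[off:hi]
                counts[off:hi][seg] = 0
                wear[off:hi][seg] = False
                if seg.any():
                    nonwear.append((off, hi))

    epochs = EpochSeries(pid, start, counts, wear)
    dataset = ParticipantDataset(epochs, log)
    truth = SyntheticTruth(pid, windows, awakenings, nonwear, naps)
    return dataset, truth


def generate_cohort(spec: CohortSpec) -> list[tuple[ParticipantDataset, SyntheticTruth]]:
    """Generate the cohort; bit-identical across calls with the same spec."""
    root = np.random.SeedSequence(spec.seed)
    out = []
    for i, child in enumerate(root.spawn(spec.n_participants)):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:02d}"
        out.append(_generate_participant(pid, spec, rng))
    return out
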