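"""Per-epoch sleep/wake classification from activity counts (Cole-Kripke).

The scorer computes, for every minute epoch ``t``, a weighted sum of counts
over a centered window (by default four epochs before through two after),

    D(t) = scale * sum_k w_k * A(t + k),

and classifies the epoch as sleep when ``D(t)`` falls below a threshold.
Boundary epochs are evaluated with zero-padded counts. The default
coefficients are the minute-epoch Cole-Kripke weights
(106, 54, 58, 76, 230, 74, 67) with scale 0.001 and threshold 1; counts are
used as provided (no rescaling) unless a divisor/cap is configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import EpochSeries

__all__ = ["SLEEP", "WAKE", "SleepWakeSeries", "ScorerConfig", "score_cole_kripke"]

SLEEP = 1
WAKE = 0


@dataclass(frozen=True)
class SleepWakeSeries:
    """Binary sleep/wake states aligned to a source :class:`EpochSeries`.

    ``states`` holds 1 for sleep, 0 for wake; same length and minute grid as
    the source counts.
    """

    participant_id: str
    start_time: pd.Timestamp
    states: np.ndarray

    def __post_init__(self):
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 1 or len(states) < 1:
            raise ValueError("states must be a non-empty 1-D sequence")
        if not np.isin(states, (SLEEP, WAKE)).all():
            raise ValueError("states must be 0 (wake) or 1 (sleep)")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))

    def __len__(self) -> int:
        return len(self.states)

    def aligned_with(self, epochs: EpochSeries) -> bool:
        return (
            len(self) == len(epochs)
            and self.start_time == epochs.start_time
            and self.participant_id == epochs.participant_id
        )


# Minute-epoch Cole-Kripke weights for offsets -4..+2 relative to the scored epoch.
_CK_WEIGHTS = (106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0)


@dataclass(frozen=True)
class ScorerConfig:
    """Configuration for the weighted-window sleep/wake scorer.

    Parameters
    ----------
    weights
        Window coefficients, one per offset; all non-negative in the default
        set, which makes scoring monotone in every count.
    offsets
        Epoch offsets relative to the scored epoch, same length as weights.
    scale
        Multiplier applied to the weighted sum.
    threshold
        Sleep iff ``scale * weighted_sum < threshold``; must be positive.
    count_divisor, count_cap
        Optional per-epoch rescaling applied before the weighted sum
        (``min(count / divisor, cap)``); disabled by default — counts are
        scored as the file provides them.
    """

    weights: tuple[float, ...] = _CK_WEIGHTS
    offsets: tuple[int, ...] = (-4, -3, -2, -1, 0, 1, 2)
    scale: float = 0.001
    threshold: float = 1.0
    count_divisor: float | None = None
    count_cap: float | None = None

    def __post_init__(self):
        if len(self.weights) != len(self.offsets):
            raise ValueError("weights and offsets must have equal length")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def score_cole_kripke(epochs: EpochSeries, config: ScorerConfig | None = None) -> SleepWakeSeries:
    """Classify each one-minute epoch as sleep or wake.

    Boundary epochs whose window extends past the series are padded with
    zero counts, so a window longer than the series is still valid.
    """
    config = config or ScorerConfig()
    n = len(epochs)
    counts = epochs.counts.astype(float)
    if config.count_divisor is not None:
        counts = counts / config.count_divisor
    if config.count_cap is not None:
        counts = np.minimum(counts, config.count_cap)

    score = np.zeros(n)
    for w, k in zip(config.weights, config.offsets):
        # contribution of A(t+k) to D(t), zero-padded outside [0, n)
        lo_t = max(0, -k)
        hi_t = min(n, n - k)
        if hi_t > lo_t:
            score[lo_t:hi_t] += w * counts[lo_t + k : hi_t + k]
    score *= config.scale
    states = np.where(score < config.threshold, SLEEP, WAKE).astype(np.int8)
    return SleepWakeSeries(epochs.participant_id, epochs.start_time, states)
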