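"""Per-minute percentage-of-agreement and the parameter grid search.

Agreement between two sleep-period detection methods is a Jaccard index
over minute sets: the number of minutes both methods call asleep divided by
the number of minutes either calls asleep. Minutes inside a sleep period
count as asleep regardless of within-period wake (diaries do not record
mid-sleep restlessness), and a method that detects no period for a night is
penalized through the union — the property that motivates this statistic
over chance-corrected agreement.

The grid search exhaustively evaluates Tudor-Locke parameter combinations:
for each parameter set, periods are detected per participant, agreement
against the diary periods is computed per participant, and the unweighted
mean across participants scores the set (limiting bias from unequal
recording lengths). The optimum is the argmax of the mean agreement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ParticipantDataset
from .sleep_wake_scoring import ScorerConfig, SleepWakeSeries, score_cole_kripke
from .tudor_locke import SleepPeriod, TLParameters, _detect_on_runs, _runs, periods_from_log

__all__ = [
    "AgreementResult",
    "GridSpec",
    "GridResult",
    "minute_agreement",
    "cohort_agreement",
    "grid_search",
    "summarize_parameter_effects",
]


@dataclass(frozen=True)
class AgreementResult:
    """Minute-set agreement for one participant.

    ``agreement = minutes_both / minutes_either``; undefined (None) when
    neither method marks any minute asleep.
    """

    participant_id: str
    minutes_both: int
    minutes_either: int

    @property
    def agreement(self) -> float | None:
        if self.minutes_either == 0:
            return None
        return self.minutes_both / self.minutes_either


def _minute_set(periods: list[SleepPeriod]) -> set[int]:
    s: set[int] = set()
    for p in periods:
        s.update(range(p.onset_epoch, p.end_epoch + 1))
    return s


def minute_agreement(
    detected: list[SleepPeriod], logged: list[SleepPeriod]
) -> AgreementResult:
    """Jaccard agreement between the asleep-minute sets of two period lists.

    Each method's asleep set is the union of its periods' covered epochs
    over the whole recording; the statistic is symmetric in its arguments.
    """
    pid = ""
    for p in itertools.chain(detected, logged):
        pid = p.participant_id
        break
    a = _minute_set(detected)
    b = _minute_set(logged)
    return AgreementResult(pid, len(a & b), len(a | b))


def cohort_agreement(per_participant: list[AgreementResult]) -> float:
    """Unweighted mean of defined participant agreements."""
    vals = [r.agreement for r in per_participant if r.agreement is not None]
    if not vals:
        raise ValueError("no participant has a defined agreement")
    return float(np.mean(vals))


@dataclass(frozen=True)
class GridSpec:
    """Candidate values per Tudor-Locke parameter for the sensitivity grid.

    The default grid crosses bedtime and wake-time definitions over
    {5,10,15,20,25,30}, minimum period length over
    {30,60,90,120,150,160,180} and minimum non-zero epochs over
    {0,5,10,15,20,25}, holding maximum period length at 1440 —
    6*6*7*6 = 1512 parameter sets.
    """

    bedtime_def: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    waketime_def: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    min_period_len: tuple[int, ...] = (30, 60, 90, 120, 150, 160, 180)
    min_nonzero_epochs: tuple[int, ...] = (0, 5, 10, 15, 20, 25)
    max_period_len: int = 1440

    def combinations(self) -> list[TLParameters]:
        """Enumerate parameter sets in deterministic (nested ascending) order."""
        if not all(
            (self.bedtime_def, self.waketime_def, self.min_period_len,
             self.min_nonzero_epochs)
        ):
            raise ValueError("every parameter needs at least one candidate value")
        return [
            TLParameters(b, w, m, nz, self.max_period_len)
            for b in self.bedtime_def
            for w in self.waketime_def
            for m in self.min_period_len
            for nz in self.min_nonzero_epochs
        ]

    def __len__(self) -> int:
        return (
            len(self.bedtime_def)
            * len(self.waketime_def)
            * len(self.min_period_len)
            * len(self.min_nonzero_epochs)
        )


_PARAM_COLS = ("bedtime_def", "waketime_def", "min_period_len", "min_nonzero_epochs",
               "max_period_len")


@dataclass
class GridResult:
    """Full sensitivity-analysis table plus the selected optimum.

    ``table`` has one row per parameter set with per-participant agreements
    and their unweighted mean, sorted by mean agreement descending;
    ``best_params`` is the argmax (first in enumeration order among ties);
    ``tied_best`` lists every parameter set achieving the maximum.
    """

    table: pd.DataFrame
    best_params: TLParameters
    best_agreement: float
    tied_best: list[TLParameters] = field(default_factory=list)


def _participant_cache(dataset: ParticipantDataset, scorer_config: ScorerConfig | None):
    """Precompute everything a grid cell needs: state runs, non-zero prefix
    sums, and the diary minute mask's prefix sums."""
    sw = score_cole_kripke(dataset.epochs, scorer_config)
    values, starts, lengths = _runs(sw.states)
    nz_cumsum = np.concatenate(([0], np.cumsum(dataset.epochs.counts >= 1)))
    log_mask = np.zeros(len(dataset.epochs), dtype=np.int64)
    for p in periods_from_log(dataset.log, dataset.epochs):
        log_mask[p.onset_epoch : p.end_epoch + 1] = 1
    log_cumsum = np.concatenate(([0], np.cumsum(log_mask)))
    return values, starts, lengths, nz_cumsum, log_cumsum, int(log_cumsum[-1])


def _cell_agreement(cache, params: TLParameters) -> tuple[int, int]:
    """(minutes_both, minutes_either) for one participant and parameter set."""
    values, starts, lengths, nz_cumsum, log_cumsum, log_total = cache
    pairs = _detect_on_runs(values, starts, lengths, nz_cumsum, params)
    both = 0
    detected_total = 0
    for onset, end in pairs:
        detected_total += end - onset + 1
        both += int(log_cumsum[end + 1] - log_cumsum[onset])
    either = log_total + detected_total - both
    return both, either


def grid_search(
    datasets: list[ParticipantDataset],
    grid: GridSpec | None = None,
    scorer_config: ScorerConfig | None = None,
) -> GridResult:
    """Evaluate every parameter set on every participant and rank by mean
    diary agreement.

    Detection is deterministic, so identical inputs always produce an
    identical table. Participants with no asleep minutes under either
    method for a given cell are excluded from that cell's mean.
    """
    grid = grid or GridSpec()
    combos = grid.combinations()
    if not datasets:
        raise ValueError("at least one participant dataset is required")
    caches = [_participant_cache(d, scorer_config) for d in datasets]
    pids = [d.participant_id for d in datasets]

    rows = []
    for order, params in enumerate(combos):
        agreements = []
        row = {c: getattr(params, c) for c in _PARAM_COLS}
        for pid, cache in zip(pids, caches):
            both, either = _cell_agreement(cache, params)
            val = both / either if either > 0 else np.nan
            row[f"agreement_{pid}"] = val
            if either > 0:
                agreements.append(val)
        row["mean_agreement"] = float(np.mean(agreements)) if agreements else np.nan
        row["_order"] = order
        rows.append(row)

    table = pd.DataFrame(rows)
    best_mean = table["mean_agreement"].max()
    tied = table[table["mean_agreement"] == best_mean].sort_values("_order")
    tied_params = [
        TLParameters(*(int(r[c]) for c in _PARAM_COLS)) for _, r in tied.iterrows()
    ]
    table = (
        table.sort_values(["mean_agreement", "_order"], ascending=[False, True])
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return GridResult(
        table=table,
        best_params=tied_params[0],
        best_agreement=float(best_mean),
        tied_best=tied_params,
    )


def summarize_parameter_effects(result: GridResult) -> pd.DataFrame:
    """Marginal mean agreement per parameter value.

    For each tuning parameter and each of its candidate values, averages the
    mean agreement over all grid rows holding that value; the parameter with
    the largest marginal range (max minus min of its value means) has the
    greatest impact on agreement.
    """
    frames = []
    for col in _PARAM_COLS[:4]:
        marg = (
            result.table.groupby(col)["mean_agreement"].mean().rename("marginal_mean")
        )
        df = marg.reset_index().rename(columns={col: "value"})
        df.insert(0, "parameter", col)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    ranges = out.groupby("parameter")["marginal_mean"].agg(lambda s: s.max() - s.min())
    out["marginal_range"] = out["parameter"].map(ranges)
    return out
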