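# actisleep

Actigraphy sleep analytics for minute-epoch activity counts: sleep/wake
scoring, automated sleep-period detection, the standard ActiLife-style
sleep measures, and a sensitivity analysis that tunes the detector's
parameters against self-report sleep diaries.

## The problem

Wrist-worn accelerometers summarize movement as an integer *activity count*
per one-minute epoch. Turning those counts into nightly sleep measures is a
three-stage pipeline:

1. **Sleep/wake scoring** — each epoch is classified sleep or wake from a
   weighted window of surrounding counts (Cole-Kripke):
   `D(t) = 0.001 · (106·A(t−4) + 54·A(t−3) + 58·A(t−2) + 76·A(t−1) +
   230·A(t) + 74·A(t+1) + 67·A(t+2))`, sleep iff `D(t) < 1`.
2. **Sleep-period detection** — the Tudor-Locke algorithm finds in-bed
   sessions in the sleep/wake series using five parameters: the *bedtime
   definition* (consecutive sleep epochs that open a period, default 5), the
   *wake-time definition* (consecutive wake epochs that end one, default 10),
   the *minimum period length* (default 160 min), the *minimum non-zero
   epochs* (non-wear guard, default 0) and the *maximum period length*
   (default 1440 min).
3. **Sleep measures** — per period and per calendar day: latency,
   efficiency, total minutes in bed (TIB), total sleep time (TST), WASO,
   number and average length of awakenings, movement index, fragmentation
   index, and sleep fragmentation index.

The default detector parameters were validated on healthy children; in
populations with restless sleep (e.g. chronic pain), frequent long
mid-sleep wake bouts make the default 10-minute wake-time definition end
periods too early or miss nights entirely. `actisleep` quantifies this with
a per-minute **percentage of agreement** between detected periods and diary
periods — a Jaccard index over asleep-minute sets,

    agreement = |minutes both asleep| / |minutes either asleep|,

computed per participant and averaged unweighted across the cohort — and
optimizes the detector by exhaustive grid search (6·6·7·6 = 1,512 parameter
sets by default). A method-comparison layer supplies repeated-measures
Bland-Altman limits of agreement (one-way random-effects variance
partition) and exact Wilcoxon signed-rank tests on participant means. A
seeded synthetic-cohort generator with known ground truth makes the whole
stack runnable and testable without any device data.

## Worked example

```python
import actisleep as a

# a restless 16-participant, 7-night cohort with 12-20 min wake bouts
cohort = a.generate_cohort(a.chronic_pain_preset(seed=1))
datasets = [ds for ds, _ in cohort]

result = a.grid_search(datasets)           # all 1,512 parameter sets
print(len(result.table))                   # 1512
print(result.best_params.waketime_def)     # 30
print(f"{result.best_agreement:.3f}")      # 0.951

ds, _ = cohort[0]
sw = a.score_cole_kripke(ds.epochs)
default = a.detect_sleep_periods(sw, ds.epochs, a.TL_DEFAULT)
optimized = a.detect_sleep_periods(sw, ds.epochs, a.TL_CHRONIC_PAIN)
log = a.periods_from_log(ds.log, ds.epochs)
print(f"{a.minute_agreement(default, log).agreement:.3f}")    # 0.265
print(f"{a.minute_agreement(optimized, log).agreement:.3f}")  # 0.656
```

On this synthetic cohort the default parameters reach a mean diary
agreement of 0.223 while the preset tuned for restless sleepers
(`TL_CHRONIC_PAIN`: wake-time definition 25, minimum non-zero epochs 5)
reaches 0.750; the grid argmax always selects a wake-time definition longer
than the 12–20 min wake bouts, which would otherwise split or erase true
sleep periods.

A CLI mirrors the library stages:

```bash
actisleep simulate --seed 1 --out sim/
actisleep detect sim/P01_epochs.csv --out periods.csv --preset tl-chronic-pain
actisleep agree sim/*_epochs.csv --sleep-log sim/sleep_log.csv --preset tl-chronic-pain
actisleep run config.yaml     # full score/detect/measures/agree/compare run
```

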