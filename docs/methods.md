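# Methods

## Data model

Activity data live on a strict one-minute grid: epoch `i` of an
`EpochSeries` covers `[start + i min, start + (i+1) min)`, counts are
non-negative integers, and the index↔timestamp mapping is invertible.
Files with interior minute gaps are rejected unless zero-fill is requested,
in which case filled minutes get count 0 and are flagged non-wear. Sleep
diaries are rounded to the nearest whole minute (exact 30 s ties round
down, keeping rounding deterministic) and cover the half-open interval
`[in_bed, out_bed)`, consistent with the epoch convention. Wear detection
is out of scope: the wear mask is taken from the file or assumed all-worn,
which matches overnight protocols where devices are worn in bed; the
night-sufficiency check (≥ 5 logged nights with the device worn for at
least a configurable fraction of the logged window, default 0.8) is the
guard against under-worn recordings. The 0.8 default tolerates brief
mid-night removal without accepting half-worn nights.

## Sleep/wake scoring

The scorer is the minute-epoch Cole-Kripke weighted window: offsets −4..+2,
weights (106, 54, 58, 76, 230, 74, 67), scale 0.001, sleep iff the scaled
sum is below 1. Boundaries are zero-padded, so series shorter than the
window are still scored. Counts are used exactly as the file provides them;
producers differ in axis selection and pre-scaling, and the package does
not second-guess the file. An optional divisor/cap rescale is exposed in
`ScorerConfig` for files whose counts are on a different scale, and the
weights/threshold are fully configurable so other published variants can
be swapped in. No rescoring rules are applied after classification; a
post-processing hook can be composed by the caller. All default weights are
non-negative, which gives the scorer a useful monotonicity: raising any
count can only move epochs from sleep to wake, never the reverse (this is
property-tested).

## Sleep-period detection

The Tudor-Locke scan proceeds left to right over the sleep/wake series. A
period opens at the first run of ≥ `bedtime_def` consecutive sleep epochs;
the first subsequent run of ≥ `waketime_def` consecutive wake epochs (or
the series end) terminates it. The terminating wake run is not part of the
period: the period ends at the last sleep epoch before it. This trimming
choice makes periods symmetric (first and last epochs are sleep), keeps
efficiency from being diluted by out-of-bed wake, and forces sleep-onset
latency to be structurally zero for every detected period — a property the
comparison layer relies on (the latency comparison between two detector
configurations is skipped as identically zero). A candidate is accepted iff
`min_period_len ≤ duration < max_period_len` and it contains at least
`min_nonzero_epochs` epochs with count ≥ 1 (the guard that separates true
sleep from non-wear, both of which score as sleep). Over-long candidates
are discarded, not truncated. Rejected candidates never block later
periods: scanning resumes immediately after the terminating wake run, which
also covers the case of a bedtime run inside a rejected candidate.
Detection is a pure function of (states, counts, parameters); the
implementation operates on run-length-encoded states in O(#runs) per call,
and is verified epoch-by-epoch against an independent brute-force scan on
randomized series.

Diary periods are converted to the epoch grid with no filters — length and
activity requirements are detector concepts, not diary concepts.

## Sleep measures and daily aggregation

Per period: latency = wake epochs before the first sleep epoch; TST =
sleep epochs; WASO = wake epochs after the first sleep epoch; awakenings =
maximal wake runs after the first sleep epoch (a single epoch is a run);
efficiency = 100·TST/TIB; movement index = 100·(epochs with count ≥ 1)/TIB;
fragmentation index = 100·(one-epoch sleep runs)/(all sleep runs); sleep
fragmentation index = MI + FI. The bout-ratio form of FI is used (count of
one-minute sleep runs over count of sleep runs), matching the ActiLife
aggregation convention; the per-TST phrasing (one-minute sleep runs over
total sleep time) is selectable per period for sensitivity checking. The exact identity TIB = latency + TST + WASO holds
for every period and every aggregated day. Awakenings before sleep onset in
diary periods are part of latency, not WASO, so they are not counted as
awakenings. A diary period containing no sleep epochs degenerates to
latency = TIB with all other measures zero. With zero awakenings the
average awakening length is reported as 0 rather than missing, so
complete-case and zero-imputation pipelines treat perfect nights
identically.

Daily aggregation pools building blocks, never percentages: sums of TST,
TIB, WASO, awakening counts, active epochs and sleep runs are formed per
calendar day, and the ratio measures are recomputed from the pooled sums
(e.g. daily efficiency = 100·ΣTST/ΣTIB, which lies between the contributing
periods' efficiencies, and daily SFI = pooled MI + pooled FI — summing
per-period percentages would be unit-inconsistent). A period belongs to the
day containing its final minute, i.e. the date of its last epoch's start;
this assigns a period ending exactly at midnight to the earlier day and
resolves the edge case deterministically.

## Agreement and grid search

Percentage of agreement is a Jaccard index over asleep-minute sets: each
method's set is the union of its periods' covered epochs over the whole
recording (within-period wake counts as asleep, since diaries do not record
it), agreement = |intersection|/|union|. The statistic is symmetric,
bounded in [0, 1], equals 1 iff the sets coincide, and strictly penalizes
nights where one method detects nothing — the reason it is preferred over
chance-corrected agreement here. It is computed per participant and
averaged unweighted, so participants with longer recordings do not dominate.
A participant with no asleep minutes under either method is undefined and
excluded from the mean (defensive only; night-sufficiency filtering makes
this unreachable in practice). The agreement window is the full recording
span rather than per-night windows; minute sets make per-night matching
unnecessary.

The default grid crosses bedtime and wake-time definitions over
{5,10,15,20,25,30}, minimum period length over {30,60,90,120,150,160,180}
and minimum non-zero epochs over {0,5,10,15,20,25} with the maximum period
length fixed at 1440 — 1,512 parameter sets. Enumeration order is nested
ascending (bedtime, wake-time, minimum length, non-zero), argmax ties are
broken by that order and all tied optima are reported. The search is
deterministic; per-participant state runs, non-zero-count prefix sums and
diary-mask prefix sums are precomputed once, making each grid cell O(#runs).
Marginal parameter effects are summarized as the mean agreement over all
rows holding a value, and the parameter with the largest marginal range is
flagged as the most influential (on restless cohorts this is always the
wake-time definition).

## Method-comparison statistics

The paired daily table keys rows by (participant, day-of-end) with one
column block per method; rows enumerate diary-documented nights, so a
method's missed nights appear as missing cells and are counted by the
missed-night report (days missed, % of days, participants affected, mean
missed per affected participant). Two missing-data strategies are
implemented: complete-case (drop incomplete rows) and zero-imputation
(fill missing cells with 0); they agree exactly on fully observed tables.

Bland-Altman with repeated measures: per-subject difference series are
decomposed by one-way random-effects ANOVA. Within-subject variance is the
mean square within; the between-subject component is (MSB − MSW)/n₀ with
n₀ = (N − Σnᵢ²/N)/(m − 1) for unequal replicates, clamped at zero when MSB
< MSW. Bias is the grand mean of all differences and the 95% limits are
bias ± 1.96·√(between + within). When every subject contributes a single
difference the within component has no degrees of freedom and the
calculation reduces to the classic single-measurement limits. The
difference direction is recorded explicitly in the result rather than
assumed.

Wilcoxon signed-rank on participant means: zeros are dropped (classical
treatment, not Pratt), the exact sign-assignment null is used when ≤ 25
non-zero untied differences remain, otherwise the normal approximation with
tie and continuity corrections. All-zero differences return p = 1 flagged
degenerate. Exactness is verified against full enumeration of all 2ⁿ sign
assignments for n ≤ 12. P-values are reported raw, with no
multiple-testing correction, at the conventional 0.05 threshold.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline consumes:
per participant, a noon-to-noon minute grid spanning `nights + 1` days;
nightly true sleep windows drawn around a mean bedtime (22:30) and mean
time in bed (538 min) with Gaussian night-to-night jitter (SD 30 min);
Poisson-count mid-sleep wake bouts (mean 5/night, lengths uniform 12–20
min, kept ≥ 30 min from window edges and mutually disjoint); wake-epoch
counts from a zero-inflated negative binomial (mean 250, dispersion 1.5,
15% extra zeros) and sleep-epoch counts mostly zero with a 12% movement
probability gating a small Poisson. Diary entries are the true windows with
independent Gaussian recall noise (SD 10 min) on each end, clamped to keep
entries positive, ordered and in-span. Optional non-wear blocks zero
daytime counts and clear the wear mask. All draws derive from
`numpy.random.SeedSequence(seed)` spawned per participant, so cohorts are
bit-identical given a spec.

The `chronic_pain_preset` fixes 16 participants × 7 nights with the
defaults above — a restless adult cohort whose bout lengths (12–20 min)
exceed the default 10-minute wake-time definition. This is what drives the
package's reproducible qualitative result: short wake-time definitions
split or erase true periods, the grid argmax selects wake-time definitions
above 10, and the tuned preset (wake-time 25, min non-zero 5) beats the
default by a wide margin in diary agreement.

What the generator does *not* model: naps are off by default (a nap option
exists to exercise multi-period days), circadian drift, weekend effects,
correlated recall bias, realistic 30 Hz acceleration, or the count
distributions of any particular device. Count distributions were chosen so
the Cole-Kripke default threshold separates states cleanly; passing tests
therefore demonstrate the pipeline's internal correctness and the direction
of the parameter-optimization effect on restless sleep, not device-level
accuracy on real cohorts. Absolute agreement numbers on synthetic cohorts
(e.g. default ≈ 0.22, tuned ≈ 0.75) depend on these choices and should not
be read as field estimates.

## Problem sizes and numerical choices

The test suite runs brute-force cross-validation on 1,000 random series
(mostly 100–2,500 epochs, periodically 10⁴) and the directional
optimization check over 20 seeded cohorts at the full 1,512-set grid; both
finish in well under a minute thanks to the run-length-encoded scan. The
acceptance script runs one full cohort end-to-end. Floating-point outputs
are written at full precision; ratios with empty denominators (no sleep
runs, no awakenings, empty days) are defined as 0 and noted where they
occur; all detection and aggregation arithmetic is exact integer work.
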