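"""Independent brute-force reference implementations used as test oracles.

Everything here works per-epoch with plain Python loops and explicit set
arithmetic, deliberately avoiding the vectorized/run-length code paths of
the package under test.
"""

from __future__ import annotations

import itertools


def brute_force_score(counts, weights, offsets, scale, threshold):
    """Naive per-epoch weighted-window sleep/wake scoring (1=sleep)."""
    n = len(counts)
    states = []
    for t in range(n):
        d = 0.0
        for w, k in zip(weights, offsets):
            j = t + k
            if 0 <= j < n:
                d += w * counts[j]
        states.append(1 if scale * d < threshold else 0)
    return states


def brute_force_tl(states, counts, bedtime_def, waketime_def, min_period_len,
                   min_nonzero_epochs, max_period_len):
    """Per-epoch scan for sleep periods; returns (onset, end) inclusive pairs."""
    n = len(states)
    periods = []
    pos = 0
    while pos < n:
        onset = None
        for i in range(pos, n - bedtime_def + 1):
            if all(states[i + j] == 1 for j in range(bedtime_def)):
                onset = i
                break
        if onset is None:
            break
        term_start = term_end = None
        i = onset
        while i < n:
            if states[i] == 0:
                j = i
                while j < n and states[j] == 0:
                    j += 1
                if j - i >= waketime_def:
                    term_start, term_end = i, j
                    break
                i = j
            else:
                i += 1
        if term_start is not None:
            end = term_start - 1
            resume = term_end
        else:
            end = max(k for k in range(onset, n) if states[k] == 1)
            resume = n
        duration = end - onset + 1
        nonzero = sum(1 for k in range(onset, end + 1) if counts[k] >= 1)
        if min_period_len <= duration < max_period_len and nonzero >= min_nonzero_epochs:
            periods.append((onset, end))
        pos = resume
    return periods


def brute_force_measures(states, counts):
    """Run-length sleep measures for one period (states/counts sliced to it)."""
    tib = len(states)
    sleep_pos = [i for i, s in enumerate(states) if s == 1]
    if not sleep_pos:
        return {
            "latency": tib, "total_minutes_in_bed": tib, "total_sleep_time": 0,
            "waso": 0, "n_awakenings": 0, "avg_awakening_len": 0.0,
            "efficiency": 0.0, "movement_index": 100.0 * sum(
                1 for c in counts if c >= 1) / tib,
            "fragmentation_index": 0.0,
        }
    first = sleep_pos[0]
    latency = first
    tst = len(sleep_pos)
    after = states[first:]
    waso = sum(1 for s in after if s == 0)
    awakenings = [list(g) for v, g in itertools.groupby(after) if v == 0]
    sleep_runs = [list(g) for v, g in itertools.groupby(states) if v == 1]
    n_one = sum(1 for r in sleep_runs if len(r) == 1)
    return {
        "latency": latency,
        "total_minutes_in_bed": tib,
        "total_sleep_time": tst,
        "waso": waso,
        "n_awakenings": len(awakenings),
        "avg_awakening_len": waso / len(awakenings) if awakenings else 0.0,
        "efficiency": 100.0 * tst / tib,
        "movement_index": 100.0 * sum(1 for c in counts if c >= 1) / tib,
        "fragmentation_index": (
            100.0 * n_one / len(sleep_runs) if sleep_runs else 0.0
        ),
    }


def brute_force_agreement(periods_a, periods_b):
    """(both, either) minute counts from explicit per-minute boolean sets."""
    set_a = set()
    for onset, end in periods_a:
        set_a.update(range(onset, end + 1))
    set_b = set()
    for onset, end in periods_b:
        set_b.update(range(onset, end + 1))
    return len(set_a & set_b), len(set_a | set_b)


def exact_wilcoxon_pvalue(diffs):
    """Two-sided signed-rank p by full enumeration of sign assignments.

    Requires non-zero, untied absolute differences (classical exact case).
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    abs_sorted = sorted(abs(x) for x in d)
    assert len(set(abs_sorted)) == n, "oracle requires untied |differences|"
    ranks = {a: i + 1 for i, a in enumerate(abs_sorted)}
    w_obs = sum(ranks[abs(x)] for x in d if x > 0)
    all_w = []
    for signs in itertools.product((0, 1), repeat=n):
        all_w.append(sum(r for s, r in zip(signs, (ranks[abs(x)] for x in d)) if s))
    total = len(all_w)
    p_le = sum(1 for w in all_w if w <= w_obs) / total
    p_ge = sum(1 for w in all_w if w >= w_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
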