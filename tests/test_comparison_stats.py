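from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from actisleep import (
    apply_missing_strategy,
    build_paired_daily_table,
    extended_bland_altman,
    missed_night_report,
    participant_means,
    wilcoxon_signed_rank,
)
from actisleep.sleep_measures import MEASURE_NAMES, DailyMeasures, SleepMeasures
from oracles import exact_wilcoxon_pvalue

D0 = date(2024, 3, 1)


def _measures(tst=400.0, tib=480.0, waso=60.0, latency=20.0):
    return SleepMeasures(
        latency=latency, efficiency=100 * tst / tib, total_minutes_in_bed=tib,
        total_sleep_time=tst, waso=waso, n_awakenings=5,
        avg_awakening_len=waso / 5, movement_index=15.0,
        fragmentation_index=10.0, sleep_fragmentation_index=25.0,
    )


def _daily(pid, day_offset, **kwargs):
    return DailyMeasures(pid, D0 + timedelta(days=day_offset), _measures(**kwargs), 1)


def _table(values_by_method, participants=("A", "B"), n_days=3, missing=()):
    """Paired table where TST is shifted per method; `missing` drops
    (method, participant, day) cells."""
    daily = {}
    for method, shift in values_by_method.items():
        rows = []
        for pid in participants:
            for d in range(n_days):
                if (method, pid, d) in missing:
                    continue
                rows.append(_daily(pid, d, tst=400 + shift + 10 * d))
        daily[method] = rows
    log_days = {pid: [D0 + timedelta(days=d) for d in range(n_days)]
                for pid in participants}
    return build_paired_daily_table(daily, log_days)


class TestPairedTable:
    def test_missing_cells_mark_undetected_days(self):
        t = _table({"SL": 0, "TLD": -50}, missing={("TLD", "A", 1)})
        assert pd.isna(
            t.loc[("A", D0 + timedelta(days=1)), ("TLD", "total_sleep_time")]
        )
        assert not t[("SL", "total_sleep_time")].isna().any()

    def test_duplicate_day_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_paired_daily_table({"SL": [_daily("A", 0), _daily("A", 0)]})


class TestMissedNights:
    def test_no_missing_cells(self):
        t = _table({"SL": 0, "TLD": -50})
        rep = missed_night_report(t, "TLD")
        assert rep.n_missed_days == 0 and rep.n_affected_participants == 0

    def test_counting_structure(self):
        # 16 participants x 7 nights; two participants each miss one night
        parts = tuple(f"P{i:02d}" for i in range(16))
        t = _table({"SL": 0, "TLD": -50}, participants=parts, n_days=7,
                   missing={("TLD", "P00", 2), ("TLD", "P05", 4)})
        rep = missed_night_report(t, "TLD")
        assert rep.n_missed_days == 2
        assert rep.n_days == 112
        assert rep.fraction_participants_affected == pytest.approx(2 / 16)
        assert rep.mean_missed_per_affected == pytest.approx(1.0)


class TestMissingStrategy:
    def test_fully_observed_table_unchanged_by_both(self):
        t = _table({"SL": 0, "TLD": -50})
        assert apply_missing_strategy(t, "complete_case").equals(t)
        assert apply_missing_strategy(t, "zero_impute").equals(t)

    def test_complete_case_drops_zero_impute_fills(self):
        t = _table({"SL": 0, "TLD": -50}, missing={("TLD", "A", 1)})
        cc = apply_missing_strategy(t, "complete_case")
        zi = apply_missing_strategy(t, "zero_impute")
        assert len(cc) == len(t) - 1
        assert len(zi) == len(t)
        assert zi.loc[("A", D0 + timedelta(days=1)), ("TLD", "total_sleep_time")] == 0

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            apply_missing_strategy(_table({"SL": 0}), "drop_participants")


class TestParticipantMeans:
    def test_mean_over_observed_days(self):
        t = _table({"SL": 0, "TLD": 0})
        # TST per day: 400, 410, 420
        means = participant_means(t, "total_sleep_time", "SL")
        assert means["A"] == pytest.approx(410.0)

    def test_zero_imputed_day_drags_mean(self):
        rows = [_daily("A", 0, tst=400), _daily("A", 1, tst=440)]
        t = build_paired_daily_table(
            {"TLD": rows},
            log_days={"A": [D0 + timedelta(days=d) for d in range(3)]},
        )
        zi = apply_missing_strategy(t, "zero_impute")
        assert participant_means(zi, "total_sleep_time", "TLD")["A"] == pytest.approx(
            280.0
        )

    def test_unobserved_participant_excluded(self):
        t = _table({"SL": 0, "TLD": 0},
                   missing={("TLD", "B", 0), ("TLD", "B", 1), ("TLD", "B", 2)})
        means = participant_means(t, "total_sleep_time", "TLD")
        assert list(means.index) == ["A"]


class TestBlandAltman:
    def test_identical_methods_zero_bias_zero_width(self):
        t = _table({"SL": 0, "TLX": 0})
        r = extended_bland_altman(t, "total_sleep_time", "TLX", "SL")
        assert r.mean_bias == pytest.approx(0.0)
        assert r.loa_low == pytest.approx(0.0)
        assert r.loa_high == pytest.approx(0.0)

    def test_constant_offset_degenerate_loa(self):
        t = _table({"SL": 0, "TLD": -50})
        r = extended_bland_altman(t, "total_sleep_time", "TLD", "SL")
        assert r.mean_bias == pytest.approx(-50.0)
        assert r.loa_low == pytest.approx(-50.0)
        assert r.loa_high == pytest.approx(-50.0)

    def test_direction_swap_mirrors(self):
        rng = np.random.default_rng(5)
        rows_a, rows_b = [], []
        for i, pid in enumerate("ABCDEF"):
            for d in range(4):
                rows_a.append(_daily(pid, d, tst=400 + rng.normal(0, 20)))
                rows_b.append(_daily(pid, d, tst=380 + rng.normal(0, 20)))
        t = build_paired_daily_table({"M1": rows_a, "M2": rows_b})
        r12 = extended_bland_altman(t, "total_sleep_time", "M1", "M2")
        r21 = extended_bland_altman(t, "total_sleep_time", "M2", "M1")
        assert r12.mean_bias == pytest.approx(-r21.mean_bias)
        assert r12.loa_low == pytest.approx(-r21.loa_high)
        assert r12.loa_high == pytest.approx(-r21.loa_low)

    def test_single_subject_rejected(self):
        t = _table({"SL": 0, "TLD": -50}, participants=("A",))
        with pytest.raises(ValueError):
            extended_bland_altman(t, "total_sleep_time", "TLD", "SL")

    def test_variance_component_recovery(self):
        # d_ij = 5 + b_i + e_ij with sigma_b=3, sigma_w=4: LoA half-width
        # should approach 1.96*sqrt(9+16) = 9.8
        rng = np.random.default_rng(42)
        rows_a, rows_b = [], []
        for i in range(50):
            pid = f"S{i:02d}"
            b = rng.normal(0, 3)
            for d in range(5):
                e = rng.normal(0, 4)
                base = 400 + rng.normal(0, 30)
                rows_a.append(_daily(pid, d, tst=base + 5 + b + e))
                rows_b.append(_daily(pid, d, tst=base))
        t = build_paired_daily_table({"M1": rows_a, "M2": rows_b})
        r = extended_bland_altman(t, "total_sleep_time", "M1", "M2")
        assert r.mean_bias == pytest.approx(5.0, abs=0.8)
        half_width = (r.loa_high - r.loa_low) / 2
        assert half_width == pytest.approx(9.8, abs=1.0)
        assert r.between_subject_var == pytest.approx(9.0, abs=4.5)
        assert r.within_subject_var == pytest.approx(16.0, abs=3.0)


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0 and r.n_effective == 0
        assert r.method == "degenerate"

    def test_five_positive_untied_differences_exact(self):
        r = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2 / 32)

    def test_mixed_signs_match_enumeration(self):
        a = np.array([0.0, 0.0, 0.0, 0.0])
        b = np.array([1.0, -2.0, 3.0, -4.0])  # differences -1, 2, -3, 4
        r = wilcoxon_signed_rank(a, b)
        assert r.method == "exact"
        assert r.p_value == pytest.approx(exact_wilcoxon_pvalue([-1, 2, -3, 4]))

    @pytest.mark.parametrize("n", range(3, 13))
    def test_exact_p_matches_enumeration_all_small_n(self, n, rng):
        for _ in range(5):
            # untied non-zero differences via distinct magnitudes
            mags = rng.choice(np.arange(1, 200), size=n, replace=False).astype(float)
            signs = rng.choice([-1.0, 1.0], size=n)
            d = mags * signs
            r = wilcoxon_signed_rank(d, np.zeros(n))
            assert r.method == "exact"
            assert r.p_value == pytest.approx(exact_wilcoxon_pvalue(list(d)))

    def test_ties_fall_back_to_approximation(self):
        d = np.array([1.0, 1.0, 2.0, 3.0, -1.0, 4.0, 5.0, -2.0])
        r = wilcoxon_signed_rank(d, np.zeros(8))
        assert r.method == "approx"
        assert 0.0 <= r.p_value <= 1.0

    def test_type_one_error_conservative_under_null(self, rng):
        # exchange paired values with prob 1/2: rejection rate <= 0.05 + MC error
        n_part, n_sim = 12, 400
        base = rng.normal(50, 10, size=n_part)
        effect = rng.normal(0, 5, size=n_part)
        rejections = 0
        for _ in range(n_sim):
            flip = rng.random(n_part) < 0.5
            a = base + np.where(flip, effect, 0.0)
            b = base + np.where(flip, 0.0, effect)
            if wilcoxon_signed_rank(a, b).p_value <= 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_sim)
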