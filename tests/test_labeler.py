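"""Baseline estimation and AKI detection under both criteria sets."""

import numpy as np
import pandas as pd
import pytest
from conftest import T0, hours_to_times, random_trajectories
from oracles import brute_baseline, brute_refined_onset, brute_standard_onset

from wardaki import (
    LabelParams,
    compare_criteria,
    detect_aki_refined,
    detect_aki_standard,
    estimate_baseline_refined,
)
from wardaki.util import SCR_UMOL_PER_MGDL


def series(hour_value_pairs):
    hours = np.array([h for h, _ in hour_value_pairs], dtype=float)
    vals = np.array([v for _, v in hour_value_pairs], dtype=float)
    return hours_to_times(hours), vals


class TestBaseline:
    def test_transient_dip_is_excluded_from_baseline(self):
        # values 0.9 (30 h before) and 0.6 (6 h before): the 0.6 dip is
        # 0.3 below both the median and the most recent other value
        t, v = series([(0, 0.9), (24, 0.6)])
        est = estimate_baseline_refined(t, v, T0 + pd.Timedelta(hours=30))
        assert est.value == pytest.approx(0.9)
        assert [(float(x[1])) for x in est.excluded] == [0.6]

    def test_constant_series_is_its_own_baseline(self):
        t, v = series([(24 * d, 1.0) for d in range(7)])
        est = estimate_baseline_refined(t, v, T0 + pd.Timedelta(days=6, hours=1))
        assert est.value == 1.0 and est.excluded == [] and est.reason == "min_window"

    def test_exclusion_cascades_to_next_candidate(self):
        # window {1.0, 1.0, 0.5, 1.1}: 0.5 is rejected (median of others
        # 1.0, recent 1.1), the next-lowest candidate 1.0 is the baseline
        t, v = series([(0, 1.0), (20, 1.0), (40, 0.5), (60, 1.1)])
        est = estimate_baseline_refined(t, v, T0 + pd.Timedelta(hours=70))
        assert est.value == pytest.approx(1.0)
        assert len(est.excluded) == 1

    def test_empty_window_returns_none(self):
        t, v = series([(0, 1.0)])
        assert estimate_baseline_refined(t, v, T0) is None

    def test_all_excluded_falls_back_to_window_median(self):
        # both candidates sit >=0.3 below the median-and-recent of the rest
        t, v = series([(0, 1.2), (10, 1.2), (30, 0.7), (40, 0.75), (50, 1.25)])
        est = estimate_baseline_refined(
            t, v, T0 + pd.Timedelta(hours=55), LabelParams(exclusion_delta=0.45)
        )
        assert est.reason == "min_window"  # 0.7: median others ok -> kept
        est2 = estimate_baseline_refined(
            t[2:4], v[2:4], T0 + pd.Timedelta(hours=55)
        )
        assert est2.reason == "min_window"


class TestStandardDetector:
    def test_dip_and_return_fires_absolute_rule(self):
        t, v = series([(0, 0.9), (24, 0.6), (40, 0.9)])
        ev = detect_aki_standard(t, v, T0)
        assert ev is not None and ev.onset_scr == 0.9
        assert ev.criteria["abs48h"]

    def test_flat_series_never_fires(self):
        t, v = series([(24 * d, 1.2) for d in range(8)])
        assert detect_aki_standard(t, v, T0) is None

    def test_low_baseline_fires_relative_rule_below_min_increase(self):
        # 0.5 -> 0.76 over 4 days: ratio 1.52 fires although delta 0.26 < 0.3
        t, v = series([(0, 0.5), (96, 0.76)])
        ev = detect_aki_standard(t, v, T0)
        assert ev is not None and ev.criteria["rel7d"] and not ev.criteria["abs48h"]

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            detect_aki_standard(np.array([], dtype="datetime64[ns]"), np.array([]), T0)


class TestRefinedDetector:
    def test_worked_example_not_aki(self):
        # 0.9 -> 0.6 -> 0.9 within 48 h: the dip is excluded, so the rise
        # is judged against baseline 0.9 (delta 0)
        t, v = series([(0, 0.9), (24, 0.6), (40, 0.9)])
        ev, audit = detect_aki_refined(t, v, T0)
        assert ev is None
        assert audit[-1].n_excluded == 1 and audit[-1].baseline_value == 0.9

    def test_ratio_alone_insufficient_without_min_increase(self):
        t, v = series([(0, 0.4), (96, 0.65)])  # ratio 1.63 but delta 0.25
        ev, _ = detect_aki_refined(t, v, T0)
        assert ev is None

    def test_fires_when_both_thresholds_met(self):
        t, v = series([(0, 0.6), (5 * 24, 0.95)])  # delta 0.35, ratio 1.58
        ev, _ = detect_aki_refined(t, v, T0)
        assert ev is not None and ev.baseline_value == 0.6

    def test_recent_baseline_skips_ratio_requirement(self):
        # baseline within 48 h: absolute rise alone fires (1.0 -> 1.35)
        t, v = series([(0, 1.0), (30, 1.35)])
        ev, _ = detect_aki_refined(t, v, T0)
        assert ev is not None and ev.criteria["abs48h"] and not ev.criteria["rel7d"]


class TestProperties:
    TRAJ = random_trajectories(1500, seed=101)

    def test_refined_is_subset_of_standard(self):
        for hours, vals in self.TRAJ:
            t = hours_to_times(hours)
            ref, _ = detect_aki_refined(t, vals, T0)
            if ref is not None:
                assert detect_aki_standard(t, vals, T0) is not None

    def test_windowed_matches_brute_force_oracle(self):
        for hours, vals in self.TRAJ:
            t = hours_to_times(hours)
            std = detect_aki_standard(t, vals, T0)
            std_i = brute_standard_onset(hours, vals)
            assert (std is None) == (std_i is None)
            if std is not None:
                assert std.onset_scr == vals[std_i]
            ref, _ = detect_aki_refined(t, vals, T0)
            ref_i, ref_b = brute_refined_onset(hours, vals)
            assert (ref is None) == (ref_i is None)
            if ref is not None:
                assert ref.onset_scr == vals[ref_i]
                assert ref.baseline_value == pytest.approx(ref_b)

    def test_baseline_matches_oracle_at_every_measurement(self):
        for hours, vals in self.TRAJ[:400]:
            times = hours_to_times(hours)
            for i, h in enumerate(hours):
                est = estimate_baseline_refined(times, vals, pd.Timestamp(times[i]))
                oracle = brute_baseline(hours, vals, h)
                assert (est is None) == (oracle is None)
                if est is not None:
                    assert est.value == pytest.approx(oracle[0])
                    assert est.reason == oracle[2]

    def test_unit_equivalence_umol(self):
        params_umol = LabelParams().scaled(SCR_UMOL_PER_MGDL)
        for hours, vals in self.TRAJ[:500]:
            t = hours_to_times(hours)
            ref_mg, _ = detect_aki_refined(t, vals, T0)
            ref_um, _ = detect_aki_refined(t, vals * SCR_UMOL_PER_MGDL, T0,
                                           params_umol)
            assert (ref_mg is None) == (ref_um is None)
            if ref_mg is not None:
                assert ref_mg.onset_time == ref_um.onset_time

    def test_time_shift_leaves_labels_unchanged(self):
        shift = pd.Timedelta(days=365, hours=7)
        for hours, vals in self.TRAJ[:300]:
            t = hours_to_times(hours)
            a, _ = detect_aki_refined(t, vals, T0)
            b, _ = detect_aki_refined(t + shift.to_timedelta64(), vals, T0 + shift)
            assert (a is None) == (b is None)
            if a is not None:
                assert b.onset_time - a.onset_time == shift
                assert a.onset_scr == b.onset_scr

    def test_standard_detection_monotone_in_post_baseline_values(self):
        rng = np.random.default_rng(5)
        for hours, vals in self.TRAJ[:500]:
            t = hours_to_times(hours)
            ev = detect_aki_standard(t, vals, T0)
            if ev is None or ev.baseline_time is None:
                continue
            idxs = [i for i in range(len(vals))
                    if pd.Timestamp(t[i]) > ev.baseline_time]
            i = idxs[rng.integers(len(idxs))]
            bumped = vals.copy()
            bumped[i] += rng.uniform(0.05, 0.8)
            assert detect_aki_standard(t, bumped, T0) is not None

    def test_refined_detection_monotone_in_onset_value(self):
        # raising the onset measurement itself can never un-detect AKI;
        # raising other values can (the exclusion rule may then treat the
        # baseline as a transient dip — the intended declassification)
        for hours, vals in self.TRAJ[:500]:
            t = hours_to_times(hours)
            ev, _ = detect_aki_refined(t, vals, T0)
            if ev is None:
                continue
            i = int(np.where(t == ev.onset_time.to_datetime64())[0][0])
            bumped = vals.copy()
            bumped[i] += 0.5
            ev2, _ = detect_aki_refined(t, bumped, T0)
            assert ev2 is not None and ev2.onset_time <= ev.onset_time


class TestCompareCriteria:
    @staticmethod
    def _low_baseline_patient(rng):
        hours = np.arange(6) * 24.0
        b = rng.uniform(0.38, 0.48)
        vals = np.round(b + rng.normal(0, 0.02, 6), 2)
        vals[4] = round(min(vals[:4]) + 0.24, 2)  # crosses 1.5x, delta < 0.3
        return hours, vals

    @staticmethod
    def _true_aki_patient(rng):
        hours = np.arange(6) * 24.0
        b = rng.uniform(0.7, 1.0)
        vals = np.round(b + rng.normal(0, 0.02, 6), 2)
        vals[4] = round(max(1.5 * b, b + 0.3) + 0.15, 2)
        return hours, vals

    def test_planted_mixture_is_fully_recovered(self):
        rng = np.random.default_rng(9)
        patients = []
        for i in range(20):
            h, v = self._low_baseline_patient(rng)
            patients.append((f"L{i}", hours_to_times(h), v, T0))
        for i in range(10):
            h, v = self._true_aki_patient(rng)
            patients.append((f"A{i}", hours_to_times(h), v, T0))
        comp = compare_criteria(patients)
        assert comp.counts["standard_only"] == 20
        assert comp.counts["refined"] == 10
        assert comp.counts["low_baseline"] == 20

    def test_all_refined_cohort_has_no_standard_only(self):
        rng = np.random.default_rng(10)
        patients = [
            ("A%d" % i, hours_to_times(h), v, T0)
            for i, (h, v) in enumerate(self._true_aki_patient(rng) for _ in range(8))
        ]
        comp = compare_criteria(patients)
        assert comp.counts["standard_only"] == 0

    def test_worked_example_subclassified_as_pre_onset_decrease(self):
        t, v = series([(0, 0.9), (24, 0.6), (40, 0.9)])
        comp = compare_criteria([("wx", t, v, T0)])
        assert comp.counts["standard_only"] == 1
        assert comp.rows.iloc[0]["subclass"] == "pre_onset_decrease"
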