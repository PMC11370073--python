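"""Non-wear detection, daily summaries, valid-day/subject rules."""

from datetime import date, datetime, timedelta
from itertools import product

import numpy as np
import pandas as pd
import pytest

from actitraj import synth, wear
from actitraj.signal import extract_feature_table


def brute_force_nonwear(below: np.ndarray, min_windows: int):
    """Independent run-length scanner: list of (start, end) window runs."""
    runs, start = [], None
    for i, b in enumerate(list(below) + [False]):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if i - start >= min_windows:
                runs.append((start, i))
            start = None
    return runs


class TestDetectNonwear:
    def test_exact_30_min_run_is_interval(self):
        sds = np.full(120, 0.005)
        ivs = wear.detect_nonwear(sds)
        assert len(ivs) == 1
        assert ivs[0].duration_min == 30.0

    def test_29_75_min_run_is_wear(self):
        assert wear.detect_nonwear(np.full(119, 0.005)) == []

    def test_threshold_is_strict_below(self):
        # vm_sd exactly at 13 mg counts as wear
        assert wear.detect_nonwear(np.full(200, 0.013)) == []

    def test_empty_input(self):
        assert wear.detect_nonwear(np.array([])) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_scanner(self, seed):
        rng = np.random.default_rng(seed)
        sds = rng.choice([0.005, 0.05], size=2000, p=[0.6, 0.4])
        ivs = wear.detect_nonwear(sds)
        expected = brute_force_nonwear(sds < 0.013, 120)
        assert [(iv.start_window, iv.end_window) for iv in ivs] == expected

    def test_intervals_sorted_disjoint_and_long_enough(self):
        rng = np.random.default_rng(9)
        sds = rng.choice([0.001, 0.1], size=3000, p=[0.7, 0.3])
        ivs = wear.detect_nonwear(sds)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end_window <= b.start_window
        assert all(iv.duration_min >= 30 for iv in ivs)


def _day_frame(classes, start=datetime(2021, 5, 3, 0, 0)):
    return pd.DataFrame(
        {
            "subject_id": "S0",
            "window_start": [start + timedelta(seconds=15 * i) for i in range(len(classes))],
            "window_index": range(len(classes)),
            "predicted_class": classes,
        }
    )


class TestSummarizeDay:
    def test_480_min_all_sed_is_exactly_valid(self):
        summary = wear.summarize_day(_day_frame(["SED"] * 1920), [])
        assert summary.sedentary == 480.0
        assert summary.total_pa == 0.0
        assert summary.wear_minutes == 480.0
        assert summary.is_valid

    def test_all_windows_inside_nonwear(self):
        frame = _day_frame(["SED"] * 200)
        iv = wear.NonWearInterval(
            start=datetime(2021, 5, 3), end=datetime(2021, 5, 3, 1),
            start_window=0, end_window=200,
        )
        summary = wear.summarize_day(frame, [iv])
        assert summary.wear_minutes == 0.0 and not summary.is_valid
        assert summary.sedentary == summary.total_pa == 0.0

    def test_midnight_spanning_input_rejected(self):
        frame = _day_frame(["SED"] * 8, start=datetime(2021, 5, 3, 23, 59))
        with pytest.raises(ValueError, match="midnight"):
            wear.summarize_day(frame, [])

    def test_weekend_flag(self):
        sat = wear.summarize_day(_day_frame(["SED"] * 4, datetime(2021, 5, 8, 9)), [])
        mon = wear.summarize_day(_day_frame(["SED"] * 4, datetime(2021, 5, 3, 9)), [])
        assert sat.is_weekend and not mon.is_weekend

    def test_ground_truth_bouts_recovered_exactly(self):
        """With classifier replaced by ground-truth labels, summary minutes
        equal the planned bout minutes and non-wear is excluded."""
        plan = [("NONWEAR", 360.0), ("SED", 240.0), ("WALK", 60.0),
                ("L_ACT_G", 120.0), ("RUN", 30.0), ("MV_ACT_G", 30.0),
                ("SED", 240.0), ("NONWEAR", 360.0)]
        rec, bouts = synth.simulate_recording(plan, start_timestamp=datetime(2021, 5, 3), seed=2)
        feats = extract_feature_table(rec)
        # ground-truth labels per 15-s window from the bout log
        labels = []
        for f in feats:
            for b in bouts:
                if b.start <= f.window_start < b.end:
                    labels.append(b.label if b.label != "NONWEAR" else "SED")
                    break
        frame = pd.DataFrame(
            {
                "subject_id": "S0",
                "window_start": [f.window_start for f in feats],
                "window_index": [f.window_index for f in feats],
                "predicted_class": labels,
            }
        )
        nonwear = wear.detect_nonwear(
            np.array([f.vm_sd for f in feats]), start_time=rec.start_timestamp
        )
        summary = wear.summarize_day(frame, nonwear)
        assert summary.sedentary == 480.0
        assert summary.walk == 60.0 and summary.run == 30.0
        assert summary.lpa == 120.0 and summary.mv_act_g == 30.0
        assert summary.wear_minutes == 720.0
        assert summary.energetic_play == 120.0
        # within-day identity: behaviours + non-wear = full day
        nonwear_min = sum(iv.duration_min for iv in nonwear)
        assert summary.wear_minutes + nonwear_min == 24 * 60.0

    def test_29_min_nonwear_block_not_flagged(self):
        """A 29-min still block stays wear time (below the 30-min rule)."""
        plan = [("SED", 200.0), ("NONWEAR", 29.0), ("SED", 200.0)]
        rec, _ = synth.simulate_recording(plan, start_timestamp=datetime(2021, 5, 3), seed=3)
        feats = extract_feature_table(rec)
        nonwear = wear.detect_nonwear(
            np.array([f.vm_sd for f in feats]), start_time=rec.start_timestamp
        )
        assert nonwear == []


def _summary(is_valid, is_weekend, day):
    return wear.DailySummary(
        subject_id="S0", date=date(2021, 5, 3 + day), sedentary=400.0, lpa=100.0,
        walk=10.0, run=5.0, mv_act_g=10.0, wear_minutes=525.0,
        is_weekend=is_weekend, is_valid=is_valid,
    )


class TestSelectValidSubjects:
    def test_four_weekdays_no_weekend_excluded(self):
        days = [_summary(True, False, d) for d in range(4)]
        assert wear.select_valid_subjects({"S0": days}) == {"S0": False}

    def test_three_weekdays_plus_saturday_included(self):
        days = [_summary(True, False, d) for d in range(3)] + [_summary(True, True, 5)]
        assert wear.select_valid_subjects({"S0": days}) == {"S0": True}

    def test_exhaustive_truth_table(self):
        """All (weekday-count, weekend-count) combinations match the rule
        evaluated by brute force."""
        for n_week, n_wend in product(range(8), range(3)):
            days = [_summary(True, False, d) for d in range(n_week)]
            days += [_summary(True, True, 10 + d) for d in range(n_wend)]
            got = wear.select_valid_subjects({"S": days})["S"]
            expected = (n_week + n_wend >= 4) and (n_wend >= 1)
            assert got == expected, (n_week, n_wend)

    def test_invalid_days_do_not_count(self):
        days = [_summary(False, True, d) for d in range(6)]
        assert wear.select_valid_subjects({"S0": days}) == {"S0": False}

    def test_monotone_in_added_valid_days(self):
        rng = np.random.default_rng(4)
        days = [
            _summary(bool(rng.random() < 0.7), bool(rng.random() < 0.3), d)
            for d in range(6)
        ]
        before = wear.select_valid_subjects({"S": days})["S"]
        days_plus = days + [_summary(True, True, 20)]
        after = wear.select_valid_subjects({"S": days_plus})["S"]
        assert after >= before  # include never flips to exclude


class TestSplitByDay:
    def test_splits_at_midnight(self):
        start = datetime(2021, 5, 3, 23, 0)
        frame = pd.DataFrame(
            {
                "subject_id": "S0",
                "window_start": [start + timedelta(seconds=15 * i) for i in range(480)],
                "window_index": range(480),
                "predicted_class": ["SED"] * 480,
            }
        )
        parts = wear.split_by_day(frame)
        assert len(parts) == 2
        assert len(parts[0]) == 240  # one hour before midnight
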