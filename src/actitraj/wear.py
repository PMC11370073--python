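"""Non-wear detection, daily summaries and inclusion rules.

Non-wear is any maximal run of consecutive 15-s windows whose vector-
magnitude SD stays below 13 mg (0.013 g) for at least 30 consecutive
minutes; shorter low-variance runs count as wear (quiet sitting). Windows
inside non-wear intervals are excluded from both behaviour minutes and wear
time. A day is valid with >= 480 wear minutes; a subject-wave enters the
analysis with >= 4 valid days of which >= 1 is a weekend day.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .classify import map_to_intensity

__all__ = [
    "NonWearInterval",
    "DailySummary",
    "detect_nonwear",
    "summarize_day",
    "select_valid_subjects",
    "split_by_day",
]

SD_THRESHOLD_G = 0.013  # 13 mg
MIN_NONWEAR_MIN = 30.0
VALID_DAY_WEAR_MIN = 480.0
MIN_VALID_DAYS = 4
MIN_WEEKEND_DAYS = 1


@dataclass(frozen=True)
class NonWearInterval:
    """One detected non-wear interval (window-aligned, half-open)."""

    start: datetime
    end: datetime
    start_window: int
    end_window: int  # exclusive

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    def contains_window(self, index: int) -> bool:
        return self.start_window <= index < self.end_window


@dataclass(frozen=True)
class DailySummary:
    """Per-day behaviour minutes for one child.

    ``energetic_play = walk + run + mv_act_g`` and
    ``total_pa = lpa + energetic_play``; wear minutes equal
    ``sedentary + total_pa`` by construction (non-wear windows contribute to
    neither).
    """

    subject_id: str
    date: date
    sedentary: float
    lpa: float
    walk: float
    run: float
    mv_act_g: float
    wear_minutes: float
    is_weekend: bool
    is_valid: bool

    @property
    def energetic_play(self) -> float:
        return self.walk + self.run + self.mv_act_g

    @property
    def total_pa(self) -> float:
        return self.lpa + self.energetic_play

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "date": self.date.isoformat(),
            "sedentary": self.sedentary,
            "lpa": self.lpa,
            "walk": self.walk,
            "run": self.run,
            "mv_act_g": self.mv_act_g,
            "energetic_play": self.energetic_play,
            "total_pa": self.total_pa,
            "wear_minutes": self.wear_minutes,
            "is_weekend": self.is_weekend,
            "is_valid": self.is_valid,
        }


def detect_nonwear(
    window_sds: np.ndarray,
    window_s: float = 15.0,
    sd_threshold: float = SD_THRESHOLD_G,
    min_duration_min: float = MIN_NONWEAR_MIN,
    start_time: datetime | None = None,
) -> list[NonWearInterval]:
    """Detect non-wear from contiguous per-window VM standard deviations.

    A maximal run of consecutive windows with ``vm_sd < sd_threshold``
    becomes a non-wear interval when its span is at least
    ``min_duration_min`` (inclusive: exactly 30 min qualifies). Returns
    intervals sorted and non-overlapping; empty input yields an empty list.
    """
    sds = np.asarray(window_sds, dtype=float)
    if sds.size == 0:
        return []
    t0 = start_time or datetime(2000, 1, 1)
    min_windows = int(np.ceil(min_duration_min * 60.0 / window_s))
    below = sds < sd_threshold

    intervals: list[NonWearInterval] = []
    i = 0
    n = sds.size
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if j - i >= min_windows:
                intervals.append(
                    NonWearInterval(
                        start=t0 + timedelta(seconds=i * window_s),
                        end=t0 + timedelta(seconds=j * window_s),
                        start_window=i,
                        end_window=j,
                    )
                )
            i = j
        else:
            i += 1
    return intervals


def _window_in_nonwear(index: int, intervals: list[NonWearInterval]) -> bool:
    return any(iv.contains_window(index) for iv in intervals)


def summarize_day(
    predictions: pd.DataFrame,
    nonwear: list[NonWearInterval],
    window_s: float = 15.0,
    valid_wear_min: float = VALID_DAY_WEAR_MIN,
) -> DailySummary:
    """Aggregate one calendar day of per-window predictions.

    ``predictions`` needs columns ``subject_id``, ``window_start``
    (datetime), ``window_index`` and ``predicted_class``. All windows must
    fall on one calendar day (split recordings at midnight first). Windows
    inside non-wear intervals are excluded from behaviour minutes and wear
    time alike; each remaining window contributes ``window_s / 60`` minutes
    to its class.
    """
    if predictions.empty:
        raise ValueError("no windows supplied")
    days = pd.to_datetime(predictions["window_start"]).dt.date.unique()
    if len(days) > 1:
        raise ValueError(
            f"windows span {len(days)} calendar days; split at midnight first"
        )
    day = days[0]
    subject = predictions["subject_id"].iloc[0]
    mins_per_window = window_s / 60.0

    minutes = {"SED": 0.0, "L_ACT_G": 0.0, "MV_ACT_G": 0.0, "WALK": 0.0, "RUN": 0.0}
    worn = 0
    for _, row in predictions.iterrows():
        if _window_in_nonwear(int(row["window_index"]), nonwear):
            continue
        map_to_intensity(row["predicted_class"])  # validates the label
        minutes[row["predicted_class"]] += mins_per_window
        worn += 1

    wear_minutes = worn * mins_per_window
    return DailySummary(
        subject_id=subject,
        date=day,
        sedentary=minutes["SED"],
        lpa=minutes["L_ACT_G"],
        walk=minutes["WALK"],
        run=minutes["RUN"],
        mv_act_g=minutes["MV_ACT_G"],
        wear_minutes=wear_minutes,
        is_weekend=day.weekday() >= 5,
        is_valid=wear_minutes >= valid_wear_min,
    )


def split_by_day(predictions: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a per-window prediction table at calendar midnights."""
    if predictions.empty:
        return []
    dates = pd.to_datetime(predictions["window_start"]).dt.date
    return [g for _, g in predictions.groupby(dates, sort=True)]


def select_valid_subjects(
    summaries: dict[str, list[DailySummary]],
    min_days: int = MIN_VALID_DAYS,
    min_weekend: int = MIN_WEEKEND_DAYS,
) -> dict[str, bool]:
    """Apply the inclusion rule per subject(-wave).

    Include iff the subject has at least ``min_days`` valid days of which at
    least ``min_weekend`` are valid weekend days. The decision is monotone:
    adding a valid day can only flip exclude → include.
    """
    decisions = {}
    for key, days in summaries.items():
        valid = [d for d in days if d.is_valid]
        weekend_valid = [d for d in valid if d.is_weekend]
        decisions[key] = len(valid) >= min_days and len(weekend_valid) >= min_weekend
    return decisions


def summaries_frame(summaries: list[DailySummary]) -> pd.DataFrame:
    """Daily summary table in the documented CSV column layout."""
    return pd.DataFrame([s.as_dict() for s in summaries])
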