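"""Adherence to the physical-activity component of 24-h movement guidelines.

Three age-specific rules apply (Australian 24-hr Movement Guidelines):

* toddlers (age < 3): total physical activity (TPA) >= 180 min/day;
* preschoolers (3-5, not yet at school): TPA >= 180 min/day **including**
  >= 60 min/day of energetic play (MVPA);
* school-aged children: MVPA >= 60 min/day.

Five-year-olds follow school status, not age: a five-year-old already at
full-time school is scored against the school rule. All thresholds are
inclusive. Adherence is judged on the child's mean across valid days by
default; an all-days variant (every valid day must individually meet the
rule) is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .wear import DailySummary

__all__ = [
    "GuidelineRule",
    "AdherenceResult",
    "RULES",
    "TPA_THRESHOLD_MIN",
    "MVPA_THRESHOLD_MIN",
    "assign_rule",
    "mean_daily_behaviours",
    "meets_guideline",
    "energetic_play_deficit",
]

TPA_THRESHOLD_MIN = 180.0
MVPA_THRESHOLD_MIN = 60.0


@dataclass(frozen=True)
class GuidelineRule:
    """One age-specific guideline: thresholds that apply (None = no term)."""

    rule_id: str
    tpa_min: float | None
    mvpa_min: float | None

    def evaluate(self, mean_tpa: float, mean_mvpa: float) -> bool:
        ok = True
        if self.tpa_min is not None:
            ok = ok and mean_tpa >= self.tpa_min
        if self.mvpa_min is not None:
            ok = ok and mean_mvpa >= self.mvpa_min
        return ok


RULES: dict[str, GuidelineRule] = {
    "EY_TODDLER": GuidelineRule("EY_TODDLER", tpa_min=TPA_THRESHOLD_MIN, mvpa_min=None),
    "EY_PRESCHOOL": GuidelineRule(
        "EY_PRESCHOOL", tpa_min=TPA_THRESHOLD_MIN, mvpa_min=MVPA_THRESHOLD_MIN
    ),
    "CYP_SCHOOL": GuidelineRule("CYP_SCHOOL", tpa_min=None, mvpa_min=MVPA_THRESHOLD_MIN),
}


@dataclass(frozen=True)
class AdherenceResult:
    subject_id: str
    wave: int
    age_years: float
    rule_id: str
    mean_tpa: float
    mean_mvpa: float
    meets: bool


def assign_rule(age_years: float, school_status: bool) -> GuidelineRule:
    """Pick the guideline for a child of given decimal age and school status.

    School attendance dominates age; otherwise under-threes get the toddler
    rule and three-to-fives the preschool rule. Ages outside [1.5, 8] are
    rejected as outside the intended early-childhood range.
    """
    if not 1.5 <= age_years <= 8.0:
        raise ValueError(f"age_years must lie in [1.5, 8], got {age_years}")
    if school_status:
        return RULES["CYP_SCHOOL"]
    if age_years < 3.0:
        return RULES["EY_TODDLER"]
    return RULES["EY_PRESCHOOL"]


def mean_daily_behaviours(summaries: list[DailySummary]) -> dict[str, float]:
    """Unweighted arithmetic means over a child's valid days.

    Raises if no valid day is supplied — adherence is undefined without
    wear data.
    """
    valid = [s for s in summaries if s.is_valid]
    if not valid:
        raise ValueError("at least one valid day is required")
    n = len(valid)
    return {
        "sedentary": sum(s.sedentary for s in valid) / n,
        "lpa": sum(s.lpa for s in valid) / n,
        "walk": sum(s.walk for s in valid) / n,
        "run": sum(s.run for s in valid) / n,
        "mv_act_g": sum(s.mv_act_g for s in valid) / n,
        "energetic_play": sum(s.energetic_play for s in valid) / n,
        "total_pa": sum(s.total_pa for s in valid) / n,
        "wear_minutes": sum(s.wear_minutes for s in valid) / n,
        "n_valid_days": float(n),
    }


def meets_guideline(
    means: dict[str, float],
    rule: GuidelineRule,
    *,
    subject_id: str = "",
    wave: int = 1,
    age_years: float = 0.0,
    daily_values: list[tuple[float, float]] | None = None,
    all_days: bool = False,
) -> AdherenceResult:
    """Score adherence for one child against a guideline rule.

    Default: the rule is applied to the mean TPA/MVPA across valid days.
    With ``all_days=True`` (and ``daily_values`` as (tpa, mvpa) pairs) the
    child meets the guideline only if every day individually does.
    """
    mean_tpa = means["total_pa"]
    mean_mvpa = means["energetic_play"]
    if all_days:
        if not daily_values:
            raise ValueError("all_days scoring needs per-day (tpa, mvpa) values")
        meets = all(rule.evaluate(t, m) for t, m in daily_values)
    else:
        meets = rule.evaluate(mean_tpa, mean_mvpa)
    return AdherenceResult(
        subject_id=subject_id,
        wave=wave,
        age_years=age_years,
        rule_id=rule.rule_id,
        mean_tpa=mean_tpa,
        mean_mvpa=mean_mvpa,
        meets=meets,
    )


def energetic_play_deficit(mean_mvpa: float, recommendation: float = MVPA_THRESHOLD_MIN) -> float:
    """Extra daily energetic-play minutes needed to reach the recommendation.

    Clamped at zero: children already at or above the recommendation have
    no deficit.
    """
    if mean_mvpa < 0:
        raise ValueError("mean_mvpa must be >= 0")
    return max(0.0, recommendation - mean_mvpa)


def adherence_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Child-wave adherence table from a day-level cohort table.

    Means are taken over each child-wave's valid days; the applicable rule
    comes from age and school status. Returns one row per child-wave with
    the mean behaviours, the rule applied and the ``meets`` flag — the
    outcome format the logistic trajectory model consumes.
    """
    rows = []
    for (cid, wave), g in cohort.groupby(["child_id", "wave"], sort=True):
        valid = g[g["is_valid"]] if "is_valid" in g.columns else g
        if valid.empty:
            continue
        mean_tpa = float(valid["total_pa"].mean())
        mean_mvpa = float(valid["energetic_play"].mean())
        age = float(valid["age_years"].iloc[0])
        school = bool(valid["school_status"].iloc[0]) if "school_status" in valid.columns else False
        rule = assign_rule(age, school)
        row = {
            "child_id": cid, "wave": int(wave), "age_years": age,
            "sex": valid["sex"].iloc[0], "rule_id": rule.rule_id,
            "mean_tpa": mean_tpa, "mean_mvpa": mean_mvpa,
            "meets": int(rule.evaluate(mean_tpa, mean_mvpa)),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def adherence_frame(results: list[AdherenceResult]) -> pd.DataFrame:
    """Adherence table: subject, wave, age, rule, means, meets."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "wave": r.wave,
                "age_years": r.age_years,
                "rule_id": r.rule_id,
                "mean_tpa": r.mean_tpa,
                "mean_mvpa": r.mean_mvpa,
                "meets": r.meets,
            }
            for r in results
        ]
    )
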