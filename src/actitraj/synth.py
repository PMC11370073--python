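"""Synthetic data generation for every stage of the pipeline.

No raw recordings are distributed with the package, so all inputs are
simulated: class-conditional tri-axial signals for the five activity
classes, annotated training corpora with per-subject variation, multi-day
wear protocols with embedded non-wear, and two-wave day-level cohorts with
known spline-shaped age trajectories. Every generator is fully determined
by its seed.

Signal model
------------
Each axis is gravity baseline plus Gaussian noise; locomotion classes add a
sinusoidal component of class-specific frequency and amplitude on the
vertical axis, and the moderate-vigorous games class adds Bernoulli bursts
of intermittent high amplitude. This is the minimal model under which the
five classes are learnable (and confusable in controlled ways) from
window-level time/frequency features. Non-wear is emitted as an exactly
zero-variance 1 g signal, giving unambiguous ground truth for the non-wear
detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .signal import RawRecording, WindowFeatures, extract_features

__all__ = [
    "CLASS_LABELS",
    "NONWEAR",
    "SignalClassParams",
    "DEFAULT_CLASS_PARAMS",
    "LabelledWindow",
    "BoutRecord",
    "CohortSimParams",
    "CohortTruth",
    "default_total_pa_curve",
    "default_energetic_play_curve",
    "default_sedentary_curve",
    "simulate_window_signal",
    "simulate_annotated_corpus",
    "simulate_recording",
    "simulate_cohort",
]

#: The five activity classes, in the fixed tie-break order used throughout.
CLASS_LABELS: tuple[str, ...] = ("SED", "L_ACT_G", "MV_ACT_G", "WALK", "RUN")
NONWEAR = "NONWEAR"


@dataclass(frozen=True)
class SignalClassParams:
    """Parameters of the class-conditional signal generator.

    ``base_level`` is the gravity-dominated VM baseline (≈ 1 g for a worn,
    hip-mounted device). ``oscillation_freq``/``oscillation_amp`` describe
    the periodic locomotion component; ``burstiness`` is the per-second
    probability of an intermittent high-amplitude burst (used for the
    moderate-vigorous activities-and-games class).
    """

    class_label: str
    base_level: float = 1.0
    noise_sd: float = 0.02
    oscillation_freq: float = 0.0
    oscillation_amp: float = 0.0
    burstiness: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.oscillation_freq < 0:
            raise ValueError("oscillation_freq must be >= 0")
        if not 0.0 <= self.burstiness <= 1.0:
            raise ValueError("burstiness must lie in [0, 1]")


#: Defaults chosen so mean window VM SD is strictly ordered
#: SED < L_ACT_G < WALK < MV_ACT_G <= RUN, with overlapping tails that make
#: the classification problem non-trivial but solvable.
DEFAULT_CLASS_PARAMS: dict[str, SignalClassParams] = {
    "SED": SignalClassParams("SED", noise_sd=0.015),
    "L_ACT_G": SignalClassParams(
        "L_ACT_G", noise_sd=0.04, oscillation_freq=0.7, oscillation_amp=0.06
    ),
    "WALK": SignalClassParams(
        "WALK", noise_sd=0.07, oscillation_freq=2.0, oscillation_amp=0.28
    ),
    "MV_ACT_G": SignalClassParams(
        "MV_ACT_G",
        noise_sd=0.12,
        oscillation_freq=1.3,
        oscillation_amp=0.30,
        burstiness=0.35,
    ),
    "RUN": SignalClassParams(
        "RUN", noise_sd=0.10, oscillation_freq=3.0, oscillation_amp=0.60
    ),
}


@dataclass(frozen=True)
class LabelledWindow:
    """One 15-s feature window with its ground-truth class and subject."""

    features: WindowFeatures
    label: str
    subject_id: str


@dataclass(frozen=True)
class BoutRecord:
    """Ground-truth start/end of one planned activity (or non-wear) bout."""

    label: str
    start: datetime
    end: datetime


def _signal_from_params(
    params: SignalClassParams,
    n: int,
    sample_rate: float,
    rng: np.random.Generator,
    phase: float = 0.0,
) -> np.ndarray:
    """Generate n tri-axial samples under the class-conditional model."""
    t = np.arange(n) / sample_rate
    xyz = rng.normal(0.0, params.noise_sd, size=(n, 3)) if params.noise_sd > 0 else np.zeros((n, 3))
    # gravity baseline carried on the vertical axis
    xyz[:, 2] += params.base_level
    if params.oscillation_amp > 0 and params.oscillation_freq > 0:
        osc = params.oscillation_amp * np.sin(2 * np.pi * params.oscillation_freq * t + phase)
        xyz[:, 2] += osc
    if params.burstiness > 0:
        # one-second burst segments: Bernoulli(burstiness) per second,
        # each burst triples local amplitude via broadband noise
        spb = int(round(sample_rate))
        n_sec = int(np.ceil(n / spb))
        burst_on = rng.random(n_sec) < params.burstiness
        mask = np.repeat(burst_on, spb)[:n]
        xyz[mask, 2] += rng.normal(0.0, 3.0 * max(params.noise_sd, 0.05), size=int(mask.sum()))
    return xyz


def simulate_window_signal(
    params: SignalClassParams,
    duration_s: float,
    sample_rate: float,
    seed: int,
) -> np.ndarray:
    """Simulate a tri-axial signal segment of one activity class.

    Returns an array of shape (duration_s * sample_rate, 3) in g,
    deterministic for a given seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if params.oscillation_freq >= sample_rate / 2:
        raise ValueError("oscillation_freq must be below the Nyquist frequency")
    n = int(round(duration_s * sample_rate))
    rng = np.random.default_rng(seed)
    return _signal_from_params(params, n, sample_rate, rng)


def _subject_params(
    base: dict[str, SignalClassParams], rng: np.random.Generator
) -> dict[str, SignalClassParams]:
    """Per-subject variation: lognormal scaling of amplitude and noise.

    Mimics between-child differences in movement vigour so that
    leave-one-subject-out validation is a genuine generalisation test.
    """
    amp_scale = float(np.exp(rng.normal(0.0, 0.30)))
    noise_scale = float(np.exp(rng.normal(0.0, 0.30)))
    freq_shift = float(rng.normal(0.0, 0.15))
    out = {}
    for label, p in base.items():
        out[label] = replace(
            p,
            noise_sd=p.noise_sd * noise_scale,
            oscillation_amp=p.oscillation_amp * amp_scale,
            oscillation_freq=max(0.0, p.oscillation_freq * (1.0 + freq_shift))
            if p.oscillation_freq > 0
            else 0.0,
        )
    return out


def simulate_annotated_corpus(
    n_subjects: int = 31,
    session_s: float = 1200.0,
    class_mix: dict[str, float] | None = None,
    sample_rate: float = 30.0,
    seed: int = 0,
    window_s: float = 15.0,
    class_params: dict[str, SignalClassParams] | None = None,
) -> list[LabelledWindow]:
    """Simulate an annotated training corpus of labelled feature windows.

    Defaults emulate the scale of a free-living active-play annotation
    study: 31 children, 20-minute sessions, 15-s windows — about 2,480
    labelled instances. Windows carry subject ids so subject-level
    cross-validation is possible.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (subject-level CV needs >= 2)")
    if class_mix is None:
        class_mix = {"SED": 0.30, "L_ACT_G": 0.30, "MV_ACT_G": 0.15, "WALK": 0.15, "RUN": 0.10}
    labels = [l for l in CLASS_LABELS if class_mix.get(l, 0.0) > 0]
    probs = np.array([class_mix[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    base = class_params or DEFAULT_CLASS_PARAMS
    rng = np.random.default_rng(seed)

    windows_per_subject = int(session_s // window_s)
    n_win_samples = int(round(window_s * sample_rate))
    corpus: list[LabelledWindow] = []
    for s in range(n_subjects):
        sid = f"S{s:03d}"
        sparams = _subject_params(base, rng)
        drawn = rng.choice(len(labels), size=windows_per_subject, p=probs)
        for w, li in enumerate(drawn):
            label = labels[li]
            phase = rng.uniform(0, 2 * np.pi)
            xyz = _signal_from_params(sparams[label], n_win_samples, sample_rate, rng, phase)
            feats = extract_features(
                xyz, sample_rate, subject_id=sid, window_index=w,
                window_start=datetime(2021, 5, 3, 9, 0) + timedelta(seconds=w * window_s),
            )
            corpus.append(LabelledWindow(features=feats, label=label, subject_id=sid))
    return corpus


def simulate_recording(
    day_plan: Sequence[tuple[str, float]],
    sample_rate: float = 30.0,
    start_timestamp: datetime | None = None,
    seed: int = 0,
    subject_id: str = "S000",
    class_params: dict[str, SignalClassParams] | None = None,
) -> tuple[RawRecording, list[BoutRecord]]:
    """Simulate a multi-bout recording from a plan of (label, minutes).

    ``day_plan`` lists consecutive bouts as (class label or ``NONWEAR``,
    duration in minutes). Non-wear bouts are emitted as an exactly constant
    1 g signal (zero variance). Returns the recording and the ground-truth
    bout log with exact start/end timestamps.
    """
    if not day_plan:
        raise ValueError("day_plan must contain at least one bout")
    for label, minutes in day_plan:
        if minutes <= 0:
            raise ValueError(f"bout duration must be positive, got {minutes}")
        if label != NONWEAR and label not in CLASS_LABELS:
            raise ValueError(f"unknown bout label {label!r}")
    start = start_timestamp or datetime(2021, 5, 3, 0, 0)
    params = class_params or DEFAULT_CLASS_PARAMS
    rng = np.random.default_rng(seed)

    chunks: list[np.ndarray] = []
    bouts: list[BoutRecord] = []
    t = start
    for label, minutes in day_plan:
        n = int(round(minutes * 60 * sample_rate))
        if label == NONWEAR:
            xyz = np.zeros((n, 3))
            xyz[:, 2] = 1.0  # resting flat: gravity on one axis, zero variance
        else:
            xyz = _signal_from_params(params[label], n, sample_rate, rng, rng.uniform(0, 2 * np.pi))
        chunks.append(xyz)
        end = t + timedelta(minutes=minutes)
        bouts.append(BoutRecord(label=label, start=t, end=end))
        t = end
    rec = RawRecording(
        subject_id=subject_id,
        start_timestamp=start,
        sample_rate=sample_rate,
        samples=np.vstack(chunks),
    )
    return rec, bouts


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Knots of the generator's true mean curves. The default curves are
#: restricted-cubic-spline functions on these knots, so a trajectory model
#: fitted with the same knots contains the truth exactly — the clean
#: setting for parameter-recovery and CI-coverage checks.
GENERATOR_KNOTS: tuple[float, ...] = (2.4, 3.6, 5.0, 6.4)


def _rcs_curve(target: Callable[[np.ndarray], np.ndarray]) -> Callable[[np.ndarray], np.ndarray]:
    """Project a target shape onto the RCS span at the generator knots."""
    from .models import SplineSpec, rcs_basis

    spec = SplineSpec(knots=GENERATOR_KNOTS)
    grid = np.linspace(1.8, 7.8, 121)
    X = np.column_stack([np.ones(grid.size), rcs_basis(grid, spec)])
    coef, *_ = np.linalg.lstsq(X, target(grid), rcond=None)

    def curve(age: np.ndarray) -> np.ndarray:
        age = np.atleast_1d(np.asarray(age, dtype=float))
        Xa = np.column_stack([np.ones(age.size), rcs_basis(age, spec)])
        out = Xa @ coef
        return out if out.size > 1 else out[0]

    return curve


#: Total PA (min/day): rises from age 2, peaks near 5, then declines.
default_total_pa_curve = _rcs_curve(lambda a: 370.0 - 4.0 * (a - 5.0) ** 2)

#: Energetic play (min/day): monotone increasing over ages 2-7.
default_energetic_play_curve = _rcs_curve(lambda a: 10.0 + 8.0 * a)

#: Sedentary time (min/day): U-shaped with its minimum near age 5.
default_sedentary_curve = _rcs_curve(lambda a: 345.0 + 4.5 * (a - 5.0) ** 2)


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the two-wave day-level cohort generator.

    The true mean curves are functions of age in years returning min/day;
    day-level values add a sex offset, a child-level random intercept and
    i.i.d. residual noise. Wave 2 retains a child with probability
    ``1 - attrition_wave2``.
    """

    n_children: int = 500
    sex_ratio: float = 0.5
    age_range: tuple[float, float] = (2.0, 5.0)
    wave_gap_years: tuple[float, float] = (1.5, 2.5)
    total_pa_curve: Callable[[np.ndarray], np.ndarray] = default_total_pa_curve
    energetic_play_curve: Callable[[np.ndarray], np.ndarray] = default_energetic_play_curve
    sedentary_curve: Callable[[np.ndarray], np.ndarray] = default_sedentary_curve
    sex_offset: float = 10.0  # male minus female, min/day, applied to PA outcomes
    sex_offset_interaction: float = 0.0  # extra male slope per year of age
    random_intercept_sd: float = 20.0
    residual_sd: float = 30.0
    attrition_wave2: float = 0.6
    days_min: int = 4
    days_max: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sex_ratio", "attrition_wave2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if not self.days_min >= 1 or self.days_max < self.days_min:
            raise ValueError("need 1 <= days_min <= days_max")


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth generator parameters returned alongside the table."""

    params: CohortSimParams
    curves: dict[str, Callable[[np.ndarray], np.ndarray]] = field(default_factory=dict)

    def mean_outcome(self, outcome: str, age, sex: str = "female") -> np.ndarray:
        """True conditional mean for a child with zero random intercept."""
        age = np.asarray(age, dtype=float)
        mu = self.curves[outcome](age)
        if outcome != "sedentary" and sex == "male":
            mu = mu + self.params.sex_offset + self.params.sex_offset_interaction * age
        return mu


_SEASONS = ("summer", "autumn", "winter", "spring")
_WORK = ("not_working", "part_time", "full_time")
_DWELLING = ("house", "apartment")
_YARD = ("small", "medium", "large")


def simulate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a two-wave cohort of day-level movement summaries.

    Returns a day-level DataFrame (one row per child-wave-day) and the
    ground truth. Columns include child id, sex, wave, decimal age at wear,
    the outcome minutes (sedentary, lpa, energetic play, total PA and its
    walking/running/moderate-vigorous split), wear minutes (defined as
    sedentary + total PA so the within-day identity holds exactly), the
    covariates used for adjustment, and validity flags. Energetic play is
    split 30/12/58% into walking/running/moderate-vigorous components.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    truth = CohortTruth(
        params=p,
        curves={
            "total_pa": p.total_pa_curve,
            "energetic_play": p.energetic_play_curve,
            "sedentary": p.sedentary_curve,
        },
    )

    sexes = np.where(rng.random(p.n_children) < p.sex_ratio, "male", "female")
    age_w1 = rng.uniform(p.age_range[0], p.age_range[1], size=p.n_children)
    gaps = rng.uniform(p.wave_gap_years[0], p.wave_gap_years[1], size=p.n_children)
    intercepts = rng.normal(0.0, p.random_intercept_sd, size=p.n_children) if p.random_intercept_sd > 0 else np.zeros(p.n_children)
    retained = rng.random(p.n_children) >= p.attrition_wave2

    # wave-1 covariates, fixed per child
    work = rng.choice(_WORK, size=p.n_children, p=[0.25, 0.4, 0.35])
    dwelling = rng.choice(_DWELLING, size=p.n_children, p=[0.85, 0.15])
    yard = rng.choice(_YARD, size=p.n_children, p=[0.2, 0.45, 0.35])

    rows = []
    for i in range(p.n_children):
        cid = f"C{i:04d}"
        sex = str(sexes[i])
        for wave in (1, 2):
            if wave == 2 and not retained[i]:
                continue
            age = float(age_w1[i] if wave == 1 else age_w1[i] + gaps[i])
            n_days = int(rng.integers(p.days_min, p.days_max + 1))
            season = str(rng.choice(_SEASONS))
            covid = int(wave == 2 and rng.random() < 0.5)
            sex_term = (p.sex_offset + p.sex_offset_interaction * age) if sex == "male" else 0.0
            mu_tpa = float(p.total_pa_curve(np.array(age))) + sex_term
            mu_ep = float(p.energetic_play_curve(np.array(age))) + sex_term * 0.3
            mu_sed = float(p.sedentary_curve(np.array(age)))
            for d in range(n_days):
                eps = rng.normal(0.0, p.residual_sd, size=3) if p.residual_sd > 0 else np.zeros(3)
                tpa = max(mu_tpa + intercepts[i] + eps[0], 1.0)
                ep = float(np.clip(mu_ep + 0.4 * intercepts[i] + 0.5 * eps[1], 0.0, tpa))
                sed = max(mu_sed - 0.5 * intercepts[i] + eps[2], 1.0)
                lpa = tpa - ep
                walk, run, mv = 0.30 * ep, 0.12 * ep, 0.58 * ep
                wear = sed + tpa
                # weekday pattern: first n-2 days weekdays, rest weekend
                is_weekend = d >= n_days - 2 if n_days >= 5 else d == n_days - 1
                rows.append(
                    {
                        "child_id": cid, "sex": sex, "wave": wave,
                        "age_years": age, "day_index": d,
                        "sedentary": sed, "lpa": lpa, "walk": walk, "run": run,
                        "mv_act_g": mv, "energetic_play": ep, "total_pa": tpa,
                        "wear_minutes": wear,
                        "is_weekend": bool(is_weekend), "is_valid": bool(wear >= 480),
                        "maternal_work": str(work[i]), "dwelling": str(dwelling[i]),
                        "yard_size": str(yard[i]), "season": season,
                        "covid": covid, "school_status": wave == 2,
                    }
                )
    return pd.DataFrame(rows), truth
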