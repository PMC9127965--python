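"""Synthetic study data with the statistical structure the analysis assumes.

Three generators mirror the three kinds of study data:

* postprandial glucose curves — a fasting baseline plus a unimodal
  gamma-like excess pulse sampled on the study's 7-point grid, scaled so the
  noiseless incremental area matches a requested target;
* per-event glycemic-load observations — per food, draws from
  Normal(per-food mean, per-food SD) truncated at 0, using the bundled
  24-food table's printed dispersion, paired with the food's eGL score;
* subject profiles — characteristics drawn from the validation cohort's
  printed means and SDs, sex balanced, BMI recomputed from height/weight.

Everything is deterministic under a fixed seed.  The per-event generator
reproduces the study's *summary* statistics, not its physiology: within-food
dispersion is one Normal component (between-subject and measurement variance
are not separated) and no meal-composition effects exist beyond the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    DEFAULT_TIME_GRID,
    GLUCOSE_REF,
    RICE_REF,
    FoodGlycemicSummary,
    FoodRecord,
    GlucoseCurve,
    SubjectProfile,
    load_fixture_table1,
    load_fixture_table4,
)
from .core import incremental_auc

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "simulate_glucose_curve",
    "simulate_gl_events",
    "simulate_cohort",
    "generate_validation_dataset",
    "expected_event_correlation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults reproduce the validation study's conditions: 20 subjects, 8
    events per food on the bundled 24-food table, the 0/15/30/45/60/90/120
    min sampling grid and a fasting baseline of 92.8 +/- 4.78 mg/dL.  Curve
    shape (peak near 35 min, gamma-like rise/decay) and measurement noise
    are conventions, not study quantities.
    """

    seed: int = 0
    n_subjects: int = 20
    n_per_food: int = 8
    times_min: Sequence[float] = DEFAULT_TIME_GRID
    baseline_mean: float = 92.8
    baseline_sd: float = 4.78
    peak_time_min: float = 35.0
    pulse_shape: float = 2.0
    noise_sd_mg_dl: float = 3.0
    ref_iauc_mean: float = 4500.0
    ref_iauc_sd: float = 900.0
    gl_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_per_food < 2:
            raise ValueError("n_per_food must be >= 2")
        if self.peak_time_min <= 0 or self.pulse_shape <= 0:
            raise ValueError("pulse parameters must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class StudyBundle:
    """A complete synthetic study: cohort, raw curves and per-event GL/eGL
    records, consumable by the glycemic and validation machinery as-is."""

    config: SimulationConfig
    cohort: list[SubjectProfile]
    foods: list[FoodRecord]
    summaries: list[FoodGlycemicSummary]
    curves: list[GlucoseCurve]
    events: pd.DataFrame


def _unit_pulse(t: np.ndarray, peak_time: float, shape: float) -> np.ndarray:
    """Gamma-like excess-glucose pulse, 0 at t=0, peaking at 1 at
    ``peak_time`` and decaying toward 0 afterwards."""
    u = t / peak_time
    return u**shape * np.exp(shape * (1.0 - u))


def simulate_glucose_curve(
    config: SimulationConfig,
    target_iauc: float,
    rng: np.random.Generator,
    subject_id: str = "S01",
    food_id: str = GLUCOSE_REF,
    test_id: str = "1",
) -> GlucoseCurve:
    """One glucose curve whose noiseless IAUC equals ``target_iauc``.

    A baseline is drawn from the fasting-glucose distribution; the pulse is
    non-negative and zero at t=0, so the incremental area of the noiseless
    curve is exactly linear in its amplitude and the target is hit by direct
    scaling.  Gaussian measurement noise (``noise_sd_mg_dl``) is then added
    at every time point.
    """
    if target_iauc < 0:
        raise ValueError("target_iauc must be >= 0")
    t = np.asarray(config.times_min, dtype=float)
    pulse = _unit_pulse(t, config.peak_time_min, config.pulse_shape)
    unit_area = np.trapezoid(pulse, t)
    if unit_area <= 0:
        raise ValueError("pulse shape has no area on this time grid")
    baseline = rng.normal(config.baseline_mean, config.baseline_sd)
    values = baseline + (target_iauc / unit_area) * pulse
    if config.noise_sd_mg_dl > 0:
        values = values + rng.normal(0.0, config.noise_sd_mg_dl, size=len(t))
    values = np.maximum(values, 1.0)  # glucose concentrations are positive
    return GlucoseCurve(
        subject_id=subject_id,
        food_id=food_id,
        test_id=test_id,
        times_min=t,
        glucose_mg_dl=values,
    )


def _truncnorm(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_gl_events(
    config: SimulationConfig,
    table4: Sequence[tuple[FoodRecord, FoodGlycemicSummary]] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-event measured-GL observations paired with each food's eGL.

    For each food, ``n_per_food`` draws from Normal(gl_mean, gl_sd) truncated
    at ``gl_floor``; with the default 24 foods and 8 events per food this is
    the study's 192 events.  Events are assigned to distinct subject slots
    per food, round-robin style, so each food is consumed by different
    subjects.
    """
    if table4 is None:
        table4 = load_fixture_table4()
    if rng is None:
        rng = config.rng()
    rows = []
    for _, s in table4:
        draws = _truncnorm(rng, s.gl_mean, s.gl_sd, config.gl_floor, config.n_per_food)
        subjects = rng.choice(config.n_subjects, size=config.n_per_food, replace=False)
        for slot, gl in zip(subjects, draws):
            rows.append((s.food_id, f"S{slot + 1:02d}", float(gl), s.egl))
    return pd.DataFrame(rows, columns=["food_id", "subject_id", "measured_gl", "egl"])


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SubjectProfile]:
    """Synthetic subject profiles matching the validation cohort's printed
    characteristic distributions, sex balanced, BMI recomputed from the
    drawn height and weight.  Fasting glucose is truncated below 100 mg/dL
    (the study's inclusion criterion screened higher values out)."""
    if rng is None:
        rng = config.rng()
    validation, _ = load_fixture_table1()
    ch = dict(validation.characteristics)
    n = config.n_subjects
    profiles = []
    for i in range(n):
        height = rng.normal(*ch["height_cm"])
        weight = _truncnorm(rng, *ch["weight_kg"], 30.0, None)
        mean_fg, sd_fg = ch["fasting_glucose_mg_dl"]
        b = (99.9 - mean_fg) / sd_fg
        fasting = stats.truncnorm.rvs(-np.inf, b, loc=mean_fg, scale=sd_fg, random_state=rng)
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                sex="M" if i < (n + 1) // 2 else "F",
                age_y=float(rng.normal(*ch["age_y"])),
                height_cm=float(height),
                weight_kg=float(weight),
                bmi_kg_m2=float(weight / (height / 100.0) ** 2),
                skeletal_muscle_kg=float(_truncnorm(rng, *ch["skeletal_muscle_kg"], 5.0, None)),
                percent_body_fat=float(_truncnorm(rng, *ch["percent_body_fat"], 1.0, None)),
                waist_hip_ratio=float(rng.normal(*ch["waist_hip_ratio"])),
                basal_metabolism_kcal=float(rng.normal(*ch["basal_metabolism_kcal"])),
                fasting_glucose_mg_dl=float(fasting),
            )
        )
    return profiles


def simulate_study_curves(
    config: SimulationConfig,
    table4: Sequence[tuple[FoodRecord, FoodGlycemicSummary]],
    rng: np.random.Generator,
) -> list[GlucoseCurve]:
    """Raw curves for a full study: two glucose-reference and two rice
    tests per subject plus one curve per food-consumption event, with
    per-subject GI drawn from each food's printed GI distribution."""
    n = config.n_subjects
    ref_targets = _truncnorm(rng, config.ref_iauc_mean, config.ref_iauc_sd, 500.0, n)
    curves = []
    for i in range(n):
        sid = f"S{i + 1:02d}"
        for k in (1, 2):
            curves.append(
                simulate_glucose_curve(
                    config, ref_targets[i], rng, sid, GLUCOSE_REF, str(k)
                )
            )
        for k in (1, 2):
            curves.append(
                simulate_glucose_curve(
                    config, ref_targets[i] * 0.9, rng, sid, RICE_REF, str(k)
                )
            )
    for _, s in table4:
        subjects = rng.choice(n, size=config.n_per_food, replace=False)
        gis = _truncnorm(rng, s.gi_mean, s.gi_sd, 0.0, config.n_per_food)
        for slot, gi in zip(subjects, gis):
            curves.append(
                simulate_glucose_curve(
                    config,
                    gi / 100.0 * ref_targets[slot],
                    rng,
                    f"S{slot + 1:02d}",
                    s.food_id,
                    "1",
                )
            )
    return curves


def generate_validation_dataset(config: SimulationConfig) -> StudyBundle:
    """End-to-end synthetic study bundle.

    One seeded generator drives cohort, curves and events in a fixed order,
    so a fixed config yields byte-identical output.  The events table joins
    the per-event GL/eGL records with the consuming subject's attributes,
    ready for subgroup validation.
    """
    rng = config.rng()
    table4 = load_fixture_table4()
    cohort = simulate_cohort(config, rng)
    curves = simulate_study_curves(config, table4, rng)
    events = simulate_gl_events(config, table4, rng)
    profile_cols = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in cohort],
            "sex": [p.sex for p in cohort],
            "bmi_kg_m2": [p.bmi_kg_m2 for p in cohort],
            "percent_body_fat": [p.percent_body_fat for p in cohort],
        }
    )
    events = events.merge(profile_cols, on="subject_id", how="left")
    return StudyBundle(
        config=config,
        cohort=cohort,
        foods=[f for f, _ in table4],
        summaries=[s for _, s in table4],
        curves=curves,
        events=events,
    )


def expected_event_correlation(
    summaries: Sequence[FoodGlycemicSummary],
) -> float:
    """Analytic prediction of the event-level Pearson r between measured GL
    and eGL under the Normal per-food event model.

    Within-food dispersion attenuates the between-food correlation:
    ``r = cov(eGL, mean GL) / sqrt(var(eGL) * (var(mean GL) + mean(sd GL^2)))``
    (population moments over foods).  Truncation at 0 is ignored, so the
    prediction sits slightly below the simulated value for tables with
    low-GL foods.
    """
    egl = np.array([s.egl for s in summaries], dtype=float)
    m = np.array([s.gl_mean for s in summaries], dtype=float)
    v_within = float(np.mean([s.gl_sd**2 for s in summaries]))
    cov = float(np.cov(egl, m, ddof=0)[0, 1])
    return cov / np.sqrt(np.var(egl) * (np.var(m) + v_within))
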