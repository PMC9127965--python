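"""Glycemic computations: IAUC, GI, GL, eGL and classification.

The incremental area under the blood-glucose curve (IAUC) is the area above
the fasting baseline, ignoring excursions below it.  GI expresses a food's
IAUC as a percentage of the same subject's IAUC after a glucose solution;
GL scales GI by the available carbohydrate of one serving; eGL predicts GL
from the nutrient label alone (see :mod:`glyload.model`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import GLUCOSE_REF, FoodGlycemicSummary, FoodRecord, GlucoseCurve
from .model import NUTRIENT_COLUMNS, EglCoefficients, EstimatedGlycemicLoad

__all__ = [
    "GlycemicClassBands",
    "incremental_auc",
    "reference_iauc",
    "gi_per_subject",
    "food_gi_summary",
    "glycemic_load",
    "estimated_gl",
    "classify_gi",
    "classify_gl",
    "classification_grid",
    "grid_counts",
    "fit_egl_coefficients",
    "default_egl_coefficients",
    "round_half_away",
    "summarize_study",
]


@dataclass(frozen=True)
class GlycemicClassBands:
    """Cut points of the conventional low/medium/high bands.

    Defaults follow common usage: GI low <= 55, high >= 70; GL (per serving)
    low <= 10, high >= 20; boundaries are inclusive.
    """

    gi_low_max: float = 55.0
    gi_high_min: float = 70.0
    gl_low_max: float = 10.0
    gl_high_min: float = 20.0

    def __post_init__(self) -> None:
        if not (self.gi_low_max < self.gi_high_min and self.gl_low_max < self.gl_high_min):
            raise ValueError("band cut points must satisfy low_max < high_min")


_DEFAULT_BANDS = GlycemicClassBands()


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display rule
    for GI/GL/eGL values)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def incremental_auc(curve: GlucoseCurve) -> float:
    """Incremental area under a glucose curve, in mg*min/dL.

    The baseline is the glucose value at time 0.  Each segment contributes
    its trapezoidal area above baseline; segments crossing the baseline are
    split at the interpolated crossing and only the portion above baseline
    counts; segments entirely below baseline contribute nothing.  The result
    is therefore always >= 0.
    """
    if len(curve) < 2:
        raise ValueError("IAUC needs at least two time points")
    t = np.asarray(curve.times_min, dtype=float)
    d = np.asarray(curve.glucose_mg_dl, dtype=float) - curve.baseline
    area = 0.0
    for i in range(len(t) - 1):
        d1, d2 = d[i], d[i + 1]
        dt = t[i + 1] - t[i]
        if d1 >= 0 and d2 >= 0:
            area += (d1 + d2) / 2.0 * dt
        elif d1 >= 0 > d2:
            area += d1 * d1 / (d1 - d2) * dt / 2.0
        elif d2 >= 0 > d1:
            area += d2 * d2 / (d2 - d1) * dt / 2.0
        # both below baseline: no contribution
    return area


def reference_iauc(
    curves: Iterable[GlucoseCurve], reference_id: str = GLUCOSE_REF
) -> float:
    """Mean IAUC of one subject's reference-food tests.

    ``curves`` are the tests of a single subject; only those whose
    ``food_id`` equals ``reference_id`` (the glucose solution by default)
    enter the mean.  At least one is required; fewer than two triggers a
    warning because the protocol repeats the reference test.
    """
    refs = [c for c in curves if c.food_id == reference_id]
    if not refs:
        raise ValueError(f"no {reference_id} tests: GI undefined for this subject")
    subjects = {c.subject_id for c in refs}
    if len(subjects) > 1:
        raise ValueError(f"reference curves span multiple subjects: {sorted(subjects)}")
    if len(refs) < 2:
        warnings.warn(
            f"subject {refs[0].subject_id}: only one {reference_id} test "
            "(protocol repeats the reference)",
            stacklevel=2,
        )
    return float(np.mean([incremental_auc(c) for c in refs]))


def gi_per_subject(food_iauc: float, ref_iauc: float) -> float:
    """GI for one subject: 100 * food IAUC / reference IAUC."""
    if ref_iauc <= 0:
        raise ValueError(f"reference IAUC must be > 0, got {ref_iauc}")
    if food_iauc < 0:
        raise ValueError(f"food IAUC must be >= 0, got {food_iauc}")
    return 100.0 * food_iauc / ref_iauc


def food_gi_summary(per_subject_gis: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of per-subject GI values."""
    vals = np.asarray(per_subject_gis, dtype=float)
    if len(vals) < 2:
        raise ValueError("need >= 2 per-subject values for a mean +/- SD")
    return float(vals.mean()), float(vals.std(ddof=1))


def glycemic_load(gi: float, carbohydrate_g: float, fiber_g: float) -> float:
    """GL of one serving: GI * available carbohydrate / 100."""
    if gi < 0:
        raise ValueError(f"GI must be >= 0, got {gi}")
    available = carbohydrate_g - fiber_g
    if available < 0:
        raise ValueError(
            f"available carbohydrate is negative ({carbohydrate_g} - {fiber_g})"
        )
    return gi * available / 100.0


def estimated_gl(coeffs: EglCoefficients, food: FoodRecord) -> float:
    """eGL of one serving from its nutrient label:
    ``a + b*(carb - fiber) - c*fat - d*protein**2 - e*fiber**2``."""
    return float(
        coeffs.a
        + coeffs.b * food.available_carbohydrate_g
        - coeffs.c * food.fat_g
        - coeffs.d * food.protein_g**2
        - coeffs.e * food.fiber_g**2
    )


def classify_gi(gi: float, bands: GlycemicClassBands = _DEFAULT_BANDS) -> str:
    """Classify a GI value as ``low`` (<= 55), ``high`` (>= 70) or
    ``medium`` (in between), with configurable cut points."""
    if gi < 0:
        raise ValueError(f"GI must be >= 0, got {gi}")
    if gi <= bands.gi_low_max:
        return "low"
    if gi >= bands.gi_high_min:
        return "high"
    return "medium"


def classify_gl(gl: float, bands: GlycemicClassBands = _DEFAULT_BANDS) -> str:
    """Classify a per-serving GL as ``low`` (<= 10), ``high`` (>= 20) or
    ``medium`` (in between), with configurable cut points."""
    if gl < 0:
        raise ValueError(f"GL must be >= 0, got {gl}")
    if gl <= bands.gl_low_max:
        return "low"
    if gl >= bands.gl_high_min:
        return "high"
    return "medium"


_CLASSES = ("low", "medium", "high")


def classification_grid(
    summaries: Iterable[FoodGlycemicSummary],
) -> dict[tuple[str, str], list[str]]:
    """Cross-tabulate foods by (GL class, GI class).

    Returns a dict over all nine ``(gl_class, gi_class)`` cells, each holding
    the food_ids falling in that cell; cell sizes sum to the input length.
    """
    grid: dict[tuple[str, str], list[str]] = {
        (gl, gi): [] for gl in _CLASSES for gi in _CLASSES
    }
    for s in summaries:
        grid[(s.gl_class, s.gi_class)].append(s.food_id)
    return grid


def grid_counts(grid: dict[tuple[str, str], list[str]]) -> pd.DataFrame:
    """Render a classification grid as a 3x3 count table (GL rows, GI columns)."""
    return pd.DataFrame(
        [[len(grid[(gl, gi)]) for gi in _CLASSES] for gl in _CLASSES],
        index=pd.Index(_CLASSES, name="gl_class"),
        columns=pd.Index(_CLASSES, name="gi_class"),
    )


def fit_egl_coefficients(
    foods: Sequence[FoodRecord], printed_egl: Sequence[float]
) -> EglCoefficients:
    """Recover the eGL constants a..e by least squares on foods with known
    eGL scores (wrapper over :class:`glyload.model.EstimatedGlycemicLoad`)."""
    X = pd.DataFrame(
        {c: [getattr(f, c) for f in foods] for c in NUTRIENT_COLUMNS}
    )
    return EstimatedGlycemicLoad().fit(X, list(printed_egl)).coefficients_


@lru_cache(maxsize=1)
def default_egl_coefficients() -> EglCoefficients:
    """eGL constants recovered from the bundled 24-food table (the published
    scores; the original development-study constants are not public)."""
    from .data import load_fixture_table4

    foods, summaries = zip(*load_fixture_table4())
    return fit_egl_coefficients(foods, [s.egl for s in summaries])


def summarize_study(
    curves: Iterable[GlucoseCurve],
    foods: Sequence[FoodRecord],
    coeffs: EglCoefficients | None = None,
    bands: GlycemicClassBands = _DEFAULT_BANDS,
    reference_id: str = GLUCOSE_REF,
) -> list[FoodGlycemicSummary]:
    """Per-food glycemic summaries from raw glucose curves.

    For every subject the reference IAUC is the mean over their glucose
    reference tests; subjects without any reference test are excluded with a
    warning.  Each (subject, food) test yields a per-subject GI and, through
    the food's available carbohydrate, a per-subject GL; foods are then
    summarised as mean +/- SD with class labels on the means and the eGL
    score from the nutrient label.
    """
    if coeffs is None:
        coeffs = default_egl_coefficients()
    food_by_id = {f.food_id: f for f in foods}
    by_subject: dict[str, list[GlucoseCurve]] = {}
    for c in curves:
        by_subject.setdefault(c.subject_id, []).append(c)

    ref_by_subject: dict[str, float] = {}
    for subject_id, subject_curves in by_subject.items():
        try:
            ref_by_subject[subject_id] = reference_iauc(subject_curves, reference_id)
        except ValueError:
            warnings.warn(
                f"subject {subject_id} excluded: no {reference_id} tests",
                stacklevel=2,
            )

    per_food: dict[str, dict[str, list[float]]] = {}
    for subject_id, subject_curves in by_subject.items():
        if subject_id not in ref_by_subject:
            continue
        ref = ref_by_subject[subject_id]
        for c in subject_curves:
            if c.food_id not in food_by_id:
                continue
            food = food_by_id[c.food_id]
            iauc = incremental_auc(c)
            gi = gi_per_subject(iauc, ref)
            gl = glycemic_load(gi, food.carbohydrate_g, food.fiber_g)
            rec = per_food.setdefault(c.food_id, {"iauc": [], "gi": [], "gl": []})
            rec["iauc"].append(iauc)
            rec["gi"].append(gi)
            rec["gl"].append(gl)

    summaries = []
    for food_id, rec in per_food.items():
        gi_mean, gi_sd = food_gi_summary(rec["gi"])
        gl_mean, gl_sd = food_gi_summary(rec["gl"])
        iauc_mean, iauc_sd = food_gi_summary(rec["iauc"])
        summaries.append(
            FoodGlycemicSummary(
                food_id=food_id,
                iauc_mean=iauc_mean,
                iauc_sd=iauc_sd,
                gi_mean=gi_mean,
                gi_sd=gi_sd,
                gl_mean=gl_mean,
                gl_sd=gl_sd,
                egl=estimated_gl(coeffs, food_by_id[food_id]),
                gi_class=classify_gi(gi_mean, bands),
                gl_class=classify_gl(gl_mean, bands),
                n_subjects=len(rec["gi"]),
            )
        )
    return summaries
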