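"""Domain types, CSV input/output and the bundled study tables.

The package works on three kinds of records: nutrient labels of single
servings (:class:`FoodRecord`), postprandial blood-glucose time series
(:class:`GlucoseCurve`), and anthropometric subject profiles
(:class:`SubjectProfile`).  Two reference tables measured on a 20-subject
validation cohort are bundled as plain CSV resources so the whole pipeline
runs without external downloads: a 24-food table of nutrients with measured
IAUC/GI/GL and the eGL score, and a two-cohort characteristics table
(validation study vs. the earlier model-development study).
"""

from __future__ import annotations

import csv
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GLUCOSE_REF",
    "RICE_REF",
    "DEFAULT_TIME_GRID",
    "FoodRecord",
    "GlucoseCurve",
    "SubjectProfile",
    "CohortSummary",
    "FoodGlycemicSummary",
    "read_food_table",
    "write_food_table",
    "read_glucose_long",
    "write_glucose_long",
    "load_fixture_table4",
    "load_fixture_table1",
]

#: Reserved food ids for the reference tests anchoring the GI denominator.
GLUCOSE_REF = "GLUCOSE_REF"
RICE_REF = "RICE_REF"

#: Measurement schedule used throughout the study: fasting baseline at 0 min
#: and six post-consumption samples.
DEFAULT_TIME_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)

FOOD_TABLE_COLUMNS = (
    "food_id",
    "name",
    "category",
    "serving_g",
    "energy_kcal",
    "carbohydrate_g",
    "fiber_g",
    "protein_g",
    "fat_g",
)

GLUCOSE_LONG_COLUMNS = ("subject_id", "food_id", "test_id", "time_min", "glucose_mg_dl")


class FormatError(ValueError):
    """A CSV file does not have the expected layout."""


@dataclass
class FoodRecord:
    """Nutrient label of one serving of a food.

    Nutrient masses are grams per serving; ``energy_kcal`` is the labelled
    energy of the serving.  Available carbohydrate (total carbohydrate minus
    dietary fiber) is the quantity the glycemic-load formulas act on.
    """

    food_id: str
    name: str
    category: str
    serving_g: float
    energy_kcal: float
    carbohydrate_g: float
    fiber_g: float
    protein_g: float
    fat_g: float

    def __post_init__(self) -> None:
        for attr in ("carbohydrate_g", "fiber_g", "protein_g", "fat_g"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.food_id}: {attr} must be >= 0")
        if self.serving_g <= 0:
            raise ValueError(f"{self.food_id}: serving_g must be > 0")
        if self.fiber_g > self.carbohydrate_g:
            raise ValueError(
                f"{self.food_id}: fiber_g ({self.fiber_g}) exceeds "
                f"carbohydrate_g ({self.carbohydrate_g})"
            )

    @property
    def available_carbohydrate_g(self) -> float:
        """Total carbohydrate minus dietary fiber (g per serving)."""
        return self.carbohydrate_g - self.fiber_g


@dataclass
class GlucoseCurve:
    """Blood-glucose time series for one subject x one food test.

    ``times_min`` must start at 0 (the fasting baseline draw) and be strictly
    increasing; glucose concentrations are mg/dL.  ``test_id`` separates
    repeated tests of the same food (reference foods are consumed at least
    twice per subject).
    """

    subject_id: str
    food_id: str
    times_min: Sequence[float]
    glucose_mg_dl: Sequence[float]
    test_id: str = "1"

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times_min)
        g = tuple(float(x) for x in self.glucose_mg_dl)
        if len(t) != len(g):
            raise ValueError("times_min and glucose_mg_dl differ in length")
        if len(t) == 0:
            raise ValueError("empty glucose curve")
        if t[0] != 0:
            raise ValueError(f"first time point must be 0, got {t[0]}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times_min must be strictly increasing")
        if any(x <= 0 for x in g):
            raise ValueError("glucose values must be > 0")
        self.times_min = t
        self.glucose_mg_dl = g

    def __len__(self) -> int:
        return len(self.times_min)

    @property
    def baseline(self) -> float:
        """Fasting glucose, i.e. the value at time 0."""
        return self.glucose_mg_dl[0]


@dataclass
class SubjectProfile:
    """Anthropometrics of one study subject (body-composition analysis)."""

    subject_id: str
    sex: str
    age_y: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    bmi_kg_m2: float | None = None
    skeletal_muscle_kg: float | None = None
    percent_body_fat: float | None = None
    waist_hip_ratio: float | None = None
    basal_metabolism_kcal: float | None = None
    fasting_glucose_mg_dl: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if (
            self.bmi_kg_m2 is not None
            and self.height_cm is not None
            and self.weight_kg is not None
        ):
            implied = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(implied - self.bmi_kg_m2) > 0.2:
                raise ValueError(
                    f"{self.subject_id}: bmi_kg_m2 {self.bmi_kg_m2:.2f} inconsistent "
                    f"with height/weight (implies {implied:.2f})"
                )
        if self.fasting_glucose_mg_dl is not None and self.fasting_glucose_mg_dl >= 100:
            # Inclusion criterion for the study was normal fasting glucose.
            warnings.warn(
                f"{self.subject_id}: fasting glucose "
                f"{self.fasting_glucose_mg_dl} mg/dL >= 100 (outside inclusion range)",
                stacklevel=2,
            )


@dataclass
class CohortSummary:
    """Summary statistics of one cohort: subject characteristics and the
    nutrient content of its food-consumption events, each as (mean, sd)."""

    label: str
    n: int
    n_events: int
    men_pct: float
    characteristics: Mapping[str, tuple[float, float]]
    nutrients: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n <= 1:
            raise ValueError("cohort must have n > 1")
        for name, (_, sd) in {**dict(self.characteristics), **dict(self.nutrients)}.items():
            if sd < 0:
                raise ValueError(f"{name}: SD must be >= 0")


@dataclass
class FoodGlycemicSummary:
    """Per-food glycemic outcome: IAUC, GI and GL as mean +/- SD over the
    subjects who consumed the food, the eGL score from its label, and the
    conventional GI/GL class labels."""

    food_id: str
    iauc_mean: float
    iauc_sd: float
    gi_mean: float
    gi_sd: float
    gl_mean: float
    gl_sd: float
    egl: float
    gi_class: str
    gl_class: str
    n_subjects: int = 8

    def __post_init__(self) -> None:
        if min(self.iauc_mean, self.gi_mean, self.gl_mean) < 0:
            raise ValueError(f"{self.food_id}: IAUC/GI/GL means must be >= 0")
        if min(self.iauc_sd, self.gi_sd, self.gl_sd) < 0:
            raise ValueError(f"{self.food_id}: SDs must be >= 0")
        for attr in ("gi_class", "gl_class"):
            if getattr(self, attr) not in ("low", "medium", "high"):
                raise ValueError(f"{self.food_id}: {attr} must be low/medium/high")


# ---------------------------------------------------------------------------
# CSV input/output (UTF-8, comma separated, dot decimal, header required)


def _check_header(fieldnames: Sequence[str] | None, required: Sequence[str], path: str) -> None:
    present = set(fieldnames or ())
    for col in required:
        if col not in present:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_food_table(path) -> list[FoodRecord]:
    """Read a per-food nutrient table from CSV.

    Expects the header ``food_id,name,category,serving_g,energy_kcal,
    carbohydrate_g,fiber_g,protein_g,fat_g``.  Rows violating record
    invariants (e.g. fiber exceeding carbohydrate) raise ``ValueError``
    naming the offending row.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, FOOD_TABLE_COLUMNS, str(path))
        records = []
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    FoodRecord(
                        food_id=row["food_id"],
                        name=row["name"],
                        category=row["category"],
                        serving_g=float(row["serving_g"]),
                        energy_kcal=float(row["energy_kcal"]),
                        carbohydrate_g=float(row["carbohydrate_g"]),
                        fiber_g=float(row["fiber_g"]),
                        protein_g=float(row["protein_g"]),
                        fat_g=float(row["fat_g"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {i}: {exc}") from exc
    return records


def write_food_table(path, records: Iterable[FoodRecord]) -> None:
    """Write food records to CSV in the format :func:`read_food_table` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FOOD_TABLE_COLUMNS)
        for r in records:
            writer.writerow([getattr(r, c) for c in FOOD_TABLE_COLUMNS])


def read_glucose_long(path) -> list[GlucoseCurve]:
    """Read glucose measurements from a long CSV into per-test curves.

    Expects columns ``subject_id,food_id,test_id,time_min,glucose_mg_dl``.
    Rows sharing (subject_id, food_id, test_id) form one curve; times are
    sorted, and duplicated times within one test are rejected.
    """
    groups: "OrderedDict[tuple, list[tuple[float, float]]]" = OrderedDict()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, GLUCOSE_LONG_COLUMNS, str(path))
        for i, row in enumerate(reader, start=2):
            key = (row["subject_id"], row["food_id"], row["test_id"])
            t = float(row["time_min"])
            if t < 0:
                raise ValueError(f"{path} line {i}: negative time {t}")
            groups.setdefault(key, []).append((t, float(row["glucose_mg_dl"])))
    curves = []
    for (subject_id, food_id, test_id), points in groups.items():
        points.sort(key=lambda p: p[0])
        times = [p[0] for p in points]
        if len(set(times)) != len(times):
            raise ValueError(
                f"duplicate time points in test ({subject_id}, {food_id}, {test_id})"
            )
        curves.append(
            GlucoseCurve(
                subject_id=subject_id,
                food_id=food_id,
                test_id=test_id,
                times_min=times,
                glucose_mg_dl=[p[1] for p in points],
            )
        )
    return curves


def write_glucose_long(path, curves: Iterable[GlucoseCurve]) -> None:
    """Write curves to the long CSV format :func:`read_glucose_long` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(GLUCOSE_LONG_COLUMNS)
        for c in curves:
            for t, g in zip(c.times_min, c.glucose_mg_dl):
                writer.writerow([c.subject_id, c.food_id, c.test_id, t, g])


# ---------------------------------------------------------------------------
# Bundled study tables


def _fixture_path(name: str):
    return resources.files("glyload.fixtures").joinpath(name)


def load_fixture_table4() -> list[tuple[FoodRecord, FoodGlycemicSummary]]:
    """The bundled 24-food table: nutrient labels with the measured
    IAUC/GI/GL summaries and eGL scores of the validation study."""
    out = []
    with _fixture_path("table4_foods.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            food = FoodRecord(
                food_id=row["food_id"],
                name=row["name"],
                category=row["category"],
                serving_g=float(row["serving_g"]),
                energy_kcal=float(row["energy_kcal"]),
                carbohydrate_g=float(row["carbohydrate_g"]),
                fiber_g=float(row["fiber_g"]),
                protein_g=float(row["protein_g"]),
                fat_g=float(row["fat_g"]),
            )
            summary = FoodGlycemicSummary(
                food_id=row["food_id"],
                iauc_mean=float(row["iauc_mean"]),
                iauc_sd=float(row["iauc_sd"]),
                gi_mean=float(row["gi_mean"]),
                gi_sd=float(row["gi_sd"]),
                gl_mean=float(row["gl_mean"]),
                gl_sd=float(row["gl_sd"]),
                egl=float(row["egl"]),
                gi_class=row["gi_class"],
                gl_class=row["gl_class"],
                n_subjects=int(row["n_subjects"]),
            )
            out.append((food, summary))
    if len(out) != 24:
        raise RuntimeError(f"bundled food table has {len(out)} entries, expected 24")
    return out


def load_fixture_table1() -> tuple[CohortSummary, CohortSummary]:
    """The bundled cohort-characteristics table.

    Returns ``(validation, development)``: the 20-subject/192-event cohort of
    the validation study and the 34-subject/239-event cohort on which the eGL
    model was originally developed.
    """
    raw: dict[str, dict] = {
        "validation": {"meta": {}, "subject": {}, "nutrient": {}},
        "development": {"meta": {}, "subject": {}, "nutrient": {}},
    }
    with _fixture_path("table1_cohorts.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            section = raw[row["cohort"]][row["section"]]
            if row["section"] == "meta":
                section[row["name"]] = float(row["mean"])
            else:
                section[row["name"]] = (float(row["mean"]), float(row["sd"]))

    def build(label: str) -> CohortSummary:
        r = raw[label]
        return CohortSummary(
            label=label,
            n=int(r["meta"]["n"]),
            n_events=int(r["meta"]["n_events"]),
            men_pct=r["meta"]["men_pct"],
            characteristics=r["subject"],
            nutrients=r["nutrient"],
        )

    return build("validation"), build("development")
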