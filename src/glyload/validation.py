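"""External-validation statistics for the eGL prediction model.

A prediction model developed on one cohort is validated on another in three
steps: *transportability* (are the validation subjects and foods genuinely
different from the development ones?), *calibration* (do predicted and
observed outcomes agree, here via the Hosmer-Lemeshow chi-square over groups
ordered by predicted risk?) and *discrimination* (can the score separate
high-load from lower-load events, summarised by the area under the ROC
curve?).  Agreement between measured GL and eGL is quantified by Pearson
correlation and simple linear regression.

The binary outcome used for calibration and discrimination is an
interpretation, not a published definition: an event counts as positive when
its measured per-serving GL falls in the conventional high band (>= 20).
The threshold is an argument everywhere it is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "TransportabilityReport",
    "CalibrationResult",
    "DiscriminationResult",
    "AgreementResult",
    "StratumValidation",
    "transportability_compare",
    "logistic_fit",
    "hosmer_lemeshow",
    "auroc",
    "agreement",
    "subgroup_validation",
    "HIGH_GL_THRESHOLD",
    "BUILTIN_STRATA",
]

#: Default dichotomization: an event is "high glycemic load" at GL >= 20.
HIGH_GL_THRESHOLD = 20.0


@dataclass
class TransportabilityReport:
    """Per-characteristic comparison of two cohorts from summary statistics."""

    cohort_a: str
    cohort_b: str
    rows: pd.DataFrame  # name, mean_a, sd_a, mean_b, sd_b, test, statistic, p_value

    def p_value(self, name: str) -> float:
        return float(self.rows.set_index("name").loc[name, "p_value"])


@dataclass
class CalibrationResult:
    """Hosmer-Lemeshow goodness of fit for one stratum."""

    stratum: str
    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame  # per group: n, observed, expected

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be >= 0")


@dataclass
class DiscriminationResult:
    """AUROC (C-statistic) with its 95% confidence interval."""

    stratum: str
    auroc: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auroc <= self.ci_high <= 1):
            raise ValueError("require 0 <= ci_low <= auroc <= ci_high <= 1")


@dataclass
class AgreementResult:
    """Pearson correlation and simple regression of measured on estimated GL."""

    pearson_r: float
    r_p_value: float
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass
class StratumValidation:
    """Calibration + discrimination for one subject stratum; either result is
    None when the stratum has a single outcome class (not estimable)."""

    stratum: str
    calibration: CalibrationResult | None
    discrimination: DiscriminationResult | None
    note: str = ""


# ---------------------------------------------------------------------------


def transportability_compare(cohort_a, cohort_b, welch: bool = False) -> TransportabilityReport:
    """Compare two cohorts characteristic by characteristic.

    Continuous characteristics (and per-event nutrient summaries) use a
    two-sample t-test reconstructed from (mean, SD, n) — pooled-variance by
    default, Welch with ``welch=True``.  The sex split uses a chi-square test
    on the 2x2 count table.  All p-values are two-sided.
    """
    rows = []

    m_a = round(cohort_a.n * cohort_a.men_pct / 100.0)
    m_b = round(cohort_b.n * cohort_b.men_pct / 100.0)
    table = np.array([[m_a, cohort_a.n - m_a], [m_b, cohort_b.n - m_b]])
    if np.all(table.sum(axis=0) > 0):
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:  # degenerate: a sex absent from both cohorts
        chi2, p = 0.0, 1.0
    rows.append(
        ("men_pct", cohort_a.men_pct, np.nan, cohort_b.men_pct, np.nan, "chi-square", chi2, p)
    )

    def t_rows(items_a, items_b, n_a, n_b):
        for name, (mean_a, sd_a) in items_a.items():
            if name not in items_b:
                warnings.warn(f"{name}: absent from cohort {cohort_b.label}, skipped")
                continue
            mean_b, sd_b = items_b[name]
            if not (np.isfinite(sd_a) and np.isfinite(sd_b)):
                warnings.warn(f"{name}: missing SD, skipped")
                continue
            t, p = stats.ttest_ind_from_stats(
                mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=not welch
            )
            rows.append((name, mean_a, sd_a, mean_b, sd_b, "t", float(t), float(p)))

    t_rows(dict(cohort_a.characteristics), dict(cohort_b.characteristics), cohort_a.n, cohort_b.n)
    t_rows(dict(cohort_a.nutrients), dict(cohort_b.nutrients), cohort_a.n_events, cohort_b.n_events)

    frame = pd.DataFrame(
        rows,
        columns=["name", "mean_a", "sd_a", "mean_b", "sd_b", "test", "statistic", "p_value"],
    )
    return TransportabilityReport(cohort_a.label, cohort_b.label, frame)


def logistic_fit(
    scores: Sequence[float], outcomes: Sequence[int]
) -> tuple[float, float, np.ndarray]:
    """Maximum-likelihood logistic regression of a binary outcome on a score.

    Fitted by Newton iterations (iteratively reweighted least squares).
    Returns ``(intercept, slope, predicted probabilities)``.  Raises
    ``ValueError`` on a single outcome class, n < 10, complete separation or
    non-convergence.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("scores and outcomes differ in length")
    if len(x) < 10:
        raise ValueError(f"need n >= 10 for a stable logistic fit, got {len(x)}")
    if not (set(np.unique(y)) <= {0.0, 1.0}):
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(method="newton", disp=0, tol=1e-10, maxiter=100)
    except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError) as exc:
        raise ValueError(f"complete separation or singular fit: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ValueError("logistic regression did not converge")
    intercept, slope = res.params
    return float(intercept), float(slope), np.asarray(res.predict(X))


def hosmer_lemeshow(
    outcomes: Sequence[int],
    probabilities: Sequence[float],
    groups: int = 10,
    stratum: str = "overall",
) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit test over deciles of predicted risk.

    Subjects are sorted by predicted probability and split into ``groups``
    near-equal bins.  For each bin the observed and expected event and
    non-event counts contribute ``(O-E)**2 / E``; the statistic is referred
    to a chi-square distribution with ``groups - 2`` degrees of freedom.
    Bins whose expected event (or non-event) count is zero are merged into
    their neighbour, with a warning, reducing the degrees of freedom.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("outcomes and probabilities differ in length")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if groups < 3:
        raise ValueError("need at least 3 groups for df = groups - 2 >= 1")
    if len(p) < 2 * groups:
        raise ValueError(f"need n >= 2*groups = {2 * groups}, got {len(p)}")

    order = np.argsort(p, kind="stable")
    bins = [
        (len(idx), float(y[idx].sum()), float(p[idx].sum()))
        for idx in np.array_split(order, groups)
    ]
    # merge bins with an expected count of zero for either outcome
    merged = [bins[0]]
    for n_i, o_i, e_i in bins[1:]:
        n_p, o_p, e_p = merged[-1]
        if min(e_p, n_p - e_p) == 0 or min(e_i, n_i - e_i) == 0:
            merged[-1] = (n_p + n_i, o_p + o_i, e_p + e_i)
        else:
            merged.append((n_i, o_i, e_i))
    if len(merged) < len(bins):
        warnings.warn(
            f"merged {len(bins) - len(merged)} risk bins with zero expected counts",
            stacklevel=2,
        )
    if len(merged) < 3:
        raise ValueError("fewer than 3 risk bins after merging; test undefined")

    chi2 = 0.0
    for n_i, o_i, e_i in merged:
        chi2 += (o_i - e_i) ** 2 / e_i
        chi2 += ((n_i - o_i) - (n_i - e_i)) ** 2 / (n_i - e_i)
    df = len(merged) - 2
    p_value = float(stats.chi2.sf(chi2, df))
    table = pd.DataFrame(merged, columns=["n", "observed", "expected"])
    return CalibrationResult(stratum, float(chi2), df, p_value, table)


def auroc(
    scores: Sequence[float], outcomes: Sequence[int], stratum: str = "overall"
) -> DiscriminationResult:
    """AUROC as the Mann-Whitney concordance probability, ties counting 1/2,
    with a 95% CI from the Hanley-McNeil standard-error formula (clipped to
    [0, 1])."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(x)  # midranks handle ties
    a = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    se = np.sqrt(
        (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    )
    lo = float(np.clip(a - 1.959963984540054 * se, 0.0, 1.0))
    hi = float(np.clip(a + 1.959963984540054 * se, 0.0, 1.0))
    return DiscriminationResult(stratum, float(a), min(lo, float(a)), max(hi, float(a)))


def agreement(
    measured_gl: Sequence[float], estimated_gl: Sequence[float]
) -> AgreementResult:
    """Pearson correlation and OLS line ``measured = intercept + slope * estimated``."""
    y = np.asarray(measured_gl, dtype=float)
    x = np.asarray(estimated_gl, dtype=float)
    if len(x) != len(y):
        raise ValueError("measured and estimated GL differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return AgreementResult(
        pearson_r=float(r),
        r_p_value=float(p),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(r) ** 2,
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Subgroup validation


def _bodyfat_band(row) -> str:
    # Above-average percent body fat: > 25% for men, > 32% for women.
    cut = 25.0 if row["sex"] == "M" else 32.0
    return "above average" if row["percent_body_fat"] > cut else "average"


BUILTIN_STRATA: dict[str, Callable[[pd.Series], str]] = {
    "gender": lambda row: "men" if row["sex"] == "M" else "women",
    "bmi": lambda row: "bmi<=23" if row["bmi_kg_m2"] <= 23 else "bmi>23",
    "bodyfat": _bodyfat_band,
}


def subgroup_validation(
    events: pd.DataFrame,
    strata: Sequence[str] = ("gender", "bmi", "bodyfat"),
    threshold: float = HIGH_GL_THRESHOLD,
    groups: int = 10,
) -> list[StratumValidation]:
    """Calibration and discrimination overall and within subject strata.

    ``events`` holds one row per food-consumption event with columns
    ``measured_gl`` and ``egl`` plus whatever subject attributes the strata
    need (``sex``, ``bmi_kg_m2``, ``percent_body_fat`` for the built-ins).
    Within each stratum the outcome ``measured_gl >= threshold`` is regressed
    on eGL by logistic regression; the predicted probabilities feed the
    Hosmer-Lemeshow test and the raw eGL score feeds the AUROC.  Strata with
    a single outcome class (or too few events) are reported as not estimable
    rather than raising.
    """
    labels: list[tuple[str, pd.DataFrame]] = [("overall", events)]
    for name in strata:
        if name not in BUILTIN_STRATA:
            raise ValueError(f"unknown stratum {name!r}; choose from {sorted(BUILTIN_STRATA)}")
        fn = BUILTIN_STRATA[name]
        assigned = events.apply(fn, axis=1)
        for value in sorted(assigned.unique()):
            labels.append((f"{name}: {value}", events[assigned == value]))

    out = []
    for label, sub in labels:
        y = (sub["measured_gl"] >= threshold).astype(int).to_numpy()
        x = sub["egl"].to_numpy(dtype=float)
        g = min(groups, len(sub) // 2) if len(sub) else 0
        try:
            _, _, probs = logistic_fit(x, y)
            cal = hosmer_lemeshow(y, probs, groups=g, stratum=label)
            disc = auroc(x, y, stratum=label)
            out.append(StratumValidation(label, cal, disc))
        except ValueError as exc:
            out.append(StratumValidation(label, None, None, note=f"not estimable: {exc}"))
    return out
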