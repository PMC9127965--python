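"""Transportability, calibration, discrimination and agreement statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glyload.data import CohortSummary
from glyload.validation import (
    agreement,
    auroc,
    hosmer_lemeshow,
    logistic_fit,
    subgroup_validation,
    transportability_compare,
)


def small_cohort(label="a", mean=10.0, sd=2.0, n=20):
    return CohortSummary(
        label=label, n=n, n_events=5 * n, men_pct=50,
        characteristics={"height_cm": (mean, sd)},
        nutrients={"fat_g": (mean, sd)},
    )


class TestTransportability:
    def test_table1_significance_pattern(self, cohorts):
        report = transportability_compare(*cohorts)
        for name in ("available_carbohydrate_g", "protein_g", "fiber_g"):
            assert report.p_value(name) < 0.001, name
        for name in ("fat_g", "height_cm", "weight_kg", "bmi_kg_m2"):
            assert report.p_value(name) > 0.05, name

    def test_height_p_value_recomputed_from_summaries(self, cohorts):
        report = transportability_compare(*cohorts)
        assert report.p_value("height_cm") == pytest.approx(0.841, abs=0.01)

    def test_identical_cohorts_give_p_one(self):
        report = transportability_compare(small_cohort("a"), small_cohort("b"))
        assert report.p_value("height_cm") == pytest.approx(1.0)
        assert report.p_value("fat_g") == pytest.approx(1.0)

    def test_welch_runs_and_differs_from_pooled(self, cohorts):
        pooled = transportability_compare(*cohorts)
        welch = transportability_compare(*cohorts, welch=True)
        assert welch.p_value("weight_kg") != pooled.p_value("weight_kg")

    def test_missing_characteristic_skipped_with_warning(self):
        a = small_cohort("a")
        b = CohortSummary(
            label="b", n=20, n_events=100, men_pct=50,
            characteristics={}, nutrients={"fat_g": (10.0, 2.0)},
        )
        with pytest.warns(UserWarning, match="absent"):
            report = transportability_compare(a, b)
        assert "height_cm" not in set(report.rows["name"])


class TestLogisticFit:
    def _se(self, x, probs):
        X = np.column_stack([np.ones_like(x), x])
        cov = np.linalg.inv((X * (probs * (1 - probs))[:, None]).T @ X)
        return np.sqrt(np.diag(cov))

    def test_parameter_recovery(self, rng):
        b0, b1, n = -2.0, 0.15, 2000
        x = rng.uniform(0, 40, n)
        y = rng.random(n) < 1 / (1 + np.exp(-(b0 + b1 * x)))
        intercept, slope, probs = logistic_fit(x, y.astype(int))
        se0, se1 = self._se(x, probs)
        assert abs(intercept - b0) < 3 * se0
        assert abs(slope - b1) < 3 * se1

    def test_null_slope_near_zero(self, rng):
        n = 4000
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.4).astype(int)
        _, slope, probs = logistic_fit(x, y)
        _, se1 = self._se(x, probs)
        assert abs(slope) < 3 * se1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            logistic_fit(np.arange(20.0), np.zeros(20, dtype=int))

    def test_complete_separation_rejected(self):
        x = np.arange(30.0)
        y = (x > 14).astype(int)
        with pytest.raises(ValueError, match="separation|converge"):
            logistic_fit(x, y)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            logistic_fit([1.0, 2.0], [0, 1])


class TestHosmerLemeshow:
    def test_perfectly_calibrated_bins(self):
        # ten blocks of eleven subjects at p = k/11: each block's expected
        # event count (11 * k/11 = k) is hit exactly by the observed count
        probs, outcomes = [], []
        for k in range(1, 11):
            probs += [k / 11.0] * 11
            outcomes += [1] * k + [0] * (11 - k)
        result = hosmer_lemeshow(outcomes, probs, groups=10)
        assert result.chi2 == pytest.approx(0, abs=1e-9)
        assert result.p_value == pytest.approx(1.0)
        assert result.df == 8

    def test_expected_events_sum_to_probability_sum(self, rng):
        p = rng.uniform(0.05, 0.95, 200)
        y = (rng.random(200) < p).astype(int)
        result = hosmer_lemeshow(y, p)
        assert result.table["expected"].sum() == pytest.approx(p.sum(), abs=1e-9)
        assert result.table["n"].sum() == 200

    def test_invariant_to_relabeling_within_bins(self, rng):
        # permuting outcomes among the subjects of one risk bin must not
        # change the statistic (bins = deciles of sorted predicted risk)
        p = rng.uniform(0.05, 0.95, 300)
        y = (rng.random(300) < p).astype(int)
        base = hosmer_lemeshow(y, p, groups=10).chi2
        y2 = y.copy()
        for bin_idx in np.array_split(np.argsort(p, kind="stable"), 10):
            y2[bin_idx] = y2[rng.permutation(bin_idx)]
        assert hosmer_lemeshow(y2, p, groups=10).chi2 == pytest.approx(base)

    def test_miscalibrated_probabilities_rejected_with_power(self, rng):
        # outcomes from p, model claims p**2: strong miscalibration at n=2000
        rejections = 0
        for _ in range(50):
            p = rng.uniform(0.2, 0.9, 2000)
            y = (rng.random(2000) < p).astype(int)
            rejections += hosmer_lemeshow(y, p**2).p_value < 0.05
        assert rejections > 40  # > 80%

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="strictly in"):
            hosmer_lemeshow([0, 1] * 20, [0.0] + [0.5] * 39)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            hosmer_lemeshow([0, 1] * 5, [0.5] * 10, groups=10)


class TestAuroc:
    def test_perfect_separation(self):
        r = auroc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auroc == 1.0
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_four_pair_example(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.1}: 3 of 4 pairs concordant
        r = auroc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert r.auroc == pytest.approx(0.75)

    def test_equals_brute_force_concordance(self, rng):
        for _ in range(25):
            n = rng.integers(10, 51)
            scores = rng.choice(np.arange(8.0), size=n)  # ties likely
            y = (rng.random(n) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            pos = scores[y == 1]
            neg = scores[y == 0]
            pairs = pos[:, None] - neg[None, :]
            expected = (np.sum(pairs > 0) + 0.5 * np.sum(pairs == 0)) / pairs.size
            assert auroc(scores, y).auroc == pytest.approx(expected)

    def test_uninformative_score_near_half(self, rng):
        n = 2000
        scores = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(int)
        r = auroc(scores, y)
        se = (r.ci_high - r.auroc) / 1.96
        assert abs(r.auroc - 0.5) < 3 * max(se, 1e-6)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            auroc([1.0, 2.0], [1, 1])

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300)
        y = (rng.random(300) < 0.3).astype(int)
        assert auroc(scores, y).auroc == pytest.approx(roc_auc_score(y, scores))


class TestAgreement:
    def test_exact_line(self):
        x = np.arange(1.0, 11.0)
        res = agreement(2 * x, x)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_three_point_example(self):
        res = agreement([1, 2, 4], [1, 2, 3])
        assert res.pearson_r == pytest.approx(0.981980506, abs=1e-6)

    def test_slope_sd_ratio_equals_r(self, rng):
        x = rng.normal(10, 3, 50)
        y = 0.8 * x + rng.normal(0, 2, 50)
        res = agreement(y, x)
        assert res.slope * np.std(x, ddof=1) / np.std(y, ddof=1) == pytest.approx(
            res.pearson_r, abs=1e-12
        )
        assert res.r_squared == pytest.approx(res.pearson_r**2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            agreement([1, 1, 1], [1, 2, 3])

    def test_table4_per_food_means_match_printed_line(self, table4):
        summaries = [s for _, s in table4]
        res = agreement([s.gl_mean for s in summaries], [s.egl for s in summaries])
        assert res.slope == pytest.approx(1.64, abs=0.05)
        assert res.intercept == pytest.approx(-9.27, abs=0.5)
        assert res.n == 24


def make_events(rng, n=400, signal=True):
    sex = rng.choice(["M", "F"], size=n)
    egl = rng.normal(18, 6, n)
    noise = rng.normal(0, 8, n)
    gl = egl + noise if signal else rng.normal(18, 8, n)
    return pd.DataFrame(
        {
            "food_id": [f"f{i % 24}" for i in range(n)],
            "subject_id": [f"S{i % 20:02d}" for i in range(n)],
            "measured_gl": gl,
            "egl": egl,
            "sex": sex,
            "bmi_kg_m2": rng.normal(21.8, 1.9, n),
            "percent_body_fat": rng.normal(22, 7, n),
        }
    )


class TestSubgroupValidation:
    def test_overall_matches_direct_calls(self, rng):
        events = make_events(rng)
        results = subgroup_validation(events, strata=())
        assert [r.stratum for r in results] == ["overall"]
        y = (events["measured_gl"] >= 20).astype(int).to_numpy()
        x = events["egl"].to_numpy()
        _, _, probs = logistic_fit(x, y)
        direct_cal = hosmer_lemeshow(y, probs)
        direct_disc = auroc(x, y)
        assert results[0].calibration.chi2 == pytest.approx(direct_cal.chi2)
        assert results[0].discrimination.auroc == pytest.approx(direct_disc.auroc)

    def test_bmi_bands_partition_events(self, rng):
        events = make_events(rng)
        results = subgroup_validation(events, strata=("bmi",))
        by_label = {r.stratum: r for r in results}
        n_low = (events["bmi_kg_m2"] <= 23).sum()
        n_high = (events["bmi_kg_m2"] > 23).sum()
        assert n_low + n_high == len(events)
        assert by_label["bmi: bmi<=23"].calibration.table["n"].sum() == n_low

    def test_identical_score_distributions_give_similar_aurocs(self, rng):
        events = make_events(rng, n=1000)
        results = subgroup_validation(events, strata=("gender",))
        aurocs = [r.discrimination.auroc for r in results if r.stratum.startswith("gender")]
        assert len(aurocs) == 2
        assert abs(aurocs[0] - aurocs[1]) < 0.1

    def test_single_class_stratum_reported_not_raised(self, rng):
        events = make_events(rng, n=60)
        events.loc[events["sex"] == "M", "measured_gl"] = 5.0  # all below threshold
        results = subgroup_validation(events, strata=("gender",))
        men = next(r for r in results if r.stratum == "gender: men")
        assert men.calibration is None and men.discrimination is None
        assert "not estimable" in men.note

    def test_unknown_stratum_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown stratum"):
            subgroup_validation(make_events(rng), strata=("zodiac",))
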