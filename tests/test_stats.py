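"""Group-comparison statistics: LMM, t-test, effect sizes, report."""

import math

import numpy as np
import pandas as pd
import pytest

from digiphen.features import Feature
from digiphen.stats import (
    GroupComparisonResult,
    Method,
    VarianceComponents,
    build_report,
    cohens_d,
    fit_group_lmm,
    fit_interaction_lmm,
    format_report,
    lmm_effect_size,
    ttest_aggregate,
)

COLUMNS = ["feature_id", "participant_id", "group", "time_index", "value", "units"]


def long_frame(
    rng,
    n_per_group=10,
    n_obs=5,
    diff=0.0,
    intercept_sd=1.0,
    resid_sd=1.0,
    base=10.0,
    slope_adhd=0.0,
    slope_comp=0.0,
    feature=Feature.QUESTIONNAIRE_LATENCY,
):
    """Hierarchical repeated-measures data; ``diff`` is comparison − ADHD."""
    rows = []
    for gname, gdiff, slope in (("ADHD", 0.0, slope_adhd), ("COMPARISON", diff, slope_comp)):
        for i in range(n_per_group):
            pid = f"{gname[0]}{i:02d}"
            intercept = rng.normal(0.0, intercept_sd)
            for t in range(n_obs):
                day = t * 14.0
                value = base + gdiff + intercept + slope * day + rng.normal(0.0, resid_sd)
                rows.append((int(feature), pid, gname, day, value, "hours"))
    return pd.DataFrame(rows, columns=COLUMNS)


class TestEffectSize:
    def test_direct_substitution(self):
        vc = VarianceComponents(diff=2.0, var_intercept_part=1.0, var_residual=3.0)
        assert lmm_effect_size(vc) == pytest.approx(1.0)

    def test_zero_difference(self):
        assert lmm_effect_size(VarianceComponents(diff=0.0, var_residual=5.0)) == 0.0

    def test_all_components_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            lmm_effect_size(VarianceComponents(diff=1.0))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(diff=1.0, var_residual=-0.1)

    def test_matches_brute_force_formula(self, rng):
        for _ in range(200):
            parts = rng.gamma(1.0, 2.0, size=5)
            diff = rng.normal(0, 5)
            vc = VarianceComponents(diff, *parts)
            assert lmm_effect_size(vc) == pytest.approx(
                abs(diff) / math.sqrt(parts.sum()), rel=1e-12
            )


class TestCohensD:
    def test_hand_computation(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)

    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([2, 2, 2], [2, 2, 2])

    def test_matches_textbook_formula(self, rng):
        for _ in range(200):
            a = rng.normal(0, 3, size=rng.integers(2, 30))
            b = rng.normal(1, 2, size=rng.integers(2, 30))
            sp = math.sqrt(
                ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                / (len(a) + len(b) - 2)
            )
            assert cohens_d(a, b) == pytest.approx(abs(a.mean() - b.mean()) / sp, rel=1e-12)


class TestTTestAggregate:
    def _frame(self, a, b):
        rows = [(2, f"A{i}", "ADHD", np.nan, v, "hours") for i, v in enumerate(a)]
        rows += [(2, f"C{i}", "COMPARISON", np.nan, v, "hours") for i, v in enumerate(b)]
        return pd.DataFrame(rows, columns=COLUMNS)

    def test_hand_example(self):
        res = ttest_aggregate(self._frame([1, 2, 3], [3, 4, 5]))
        assert res.effect_size_d == pytest.approx(2.0)
        assert res.method is Method.TTEST
        assert res.z_score < 0  # ADHD-minus-comparison sign, ADHD lower here

    def test_identical_groups(self):
        res = ttest_aggregate(self._frame([1, 2, 3], [1, 2, 3]))
        assert res.z_score == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_repeated_measures_rejected(self):
        frame = self._frame([1, 2, 3], [3, 4, 5])
        frame.loc[1, "participant_id"] = "A0"
        with pytest.raises(ValueError, match="one value per participant"):
            ttest_aggregate(frame)


class TestGroupLmm:
    def test_recovers_group_difference(self, rng):
        frame = long_frame(rng, n_per_group=20, n_obs=10, diff=-3.0, intercept_sd=1.0, resid_sd=1.0)
        res = fit_group_lmm(frame)
        vc = res.variance_components
        assert vc.diff == pytest.approx(-3.0, abs=1.0)
        assert res.z_score < 0  # ADHD higher -> negative comparison coefficient
        assert res.p_value < 0.01
        assert vc.var_intercept_part == pytest.approx(1.0, abs=0.8)
        assert vc.var_residual == pytest.approx(1.0, abs=0.3)
        assert res.effect_size_d == pytest.approx(
            abs(vc.diff) / math.sqrt(vc.total_variance), rel=1e-12
        )

    def test_null_difference_modest_z(self, rng):
        res = fit_group_lmm(long_frame(rng, diff=0.0))
        assert abs(res.z_score) < 4.0
        assert res.method is Method.LMM

    def test_constant_data_falls_back_with_zero_effect(self):
        rng = np.random.default_rng(0)
        frame = long_frame(rng, intercept_sd=0.0, resid_sd=0.0)
        res = fit_group_lmm(frame)
        assert res.fallback
        assert res.effect_size_d == 0.0
        assert res.mean_adhd == pytest.approx(res.mean_comp)

    def test_descriptives_match_flat_recomputation(self, rng):
        frame = long_frame(rng, diff=2.0)
        res = fit_group_lmm(frame)
        adhd = frame.loc[frame["group"] == "ADHD", "value"]
        assert res.mean_adhd == pytest.approx(adhd.mean())
        assert res.sd_adhd == pytest.approx(adhd.std(ddof=1))

    def test_too_few_participants_rejected(self, rng):
        frame = long_frame(rng, n_per_group=1)
        with pytest.raises(ValueError, match=">= 2 participants"):
            fit_group_lmm(frame)


class TestInteractionLmm:
    def test_adhd_slope_gives_negative_interaction(self, rng):
        frame = long_frame(rng, n_per_group=10, slope_adhd=0.2, slope_comp=0.0)
        res = fit_interaction_lmm(frame)
        assert res.interaction_coef < 0
        assert res.day_coef == pytest.approx(0.2, abs=0.05)

    def test_no_trend_day_term_near_zero(self, rng):
        frame = long_frame(rng, n_per_group=15, n_obs=8)
        res = fit_interaction_lmm(frame)
        assert res.day_coef == pytest.approx(0.0, abs=0.05)

    def test_requires_time_index(self, rng):
        frame = long_frame(rng)
        frame["time_index"] = np.nan
        with pytest.raises(ValueError, match="time_index"):
            fit_interaction_lmm(frame)


class TestReport:
    def _result(self, feature, p):
        return GroupComparisonResult(
            feature_id=feature, mean_adhd=1.0, sd_adhd=0.5, mean_comp=2.0, sd_comp=0.5,
            p_value=p, z_score=1.0, effect_size_d=0.4,
            method=Method.LMM, n_obs=10, n_participants=4,
        )

    def test_ten_rows_and_significance_flag(self):
        results = {f: self._result(f, 0.04 if int(f) % 2 else 0.5) for f in Feature}
        report = build_report(results)
        assert len(report) == 10
        assert list(report["feature"]) == list(range(1, 11))
        assert (report["significant"] == (report["p_value"] < 0.05)).all()

    def test_missing_feature_gets_na_row(self):
        results = {f: self._result(f, 0.2) for f in Feature if f is not Feature.AMBIENT_LIGHT_SD}
        report = build_report(results)
        row = report[report["feature"] == 7].iloc[0]
        assert math.isnan(row["p_value"])
        assert "NA" in format_report(report)

    def test_column_schema(self):
        report = build_report({})
        assert list(report.columns[:10]) == [
            "feature", "name", "units", "adhd_mean", "adhd_sd",
            "comparison_mean", "comparison_sd", "p_value", "z_score", "effect_size_d",
        ]

    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            self._result(Feature.QUESTIONNAIRE_LATENCY, 1.5)
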