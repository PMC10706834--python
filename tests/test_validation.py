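"""Deviation/RSD metrics, dynamic range, LOD/LOQ rules, precision, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salmoquant import datasets
from salmoquant.errors import InputError
from salmoquant.validation import (
    determine_lod,
    determine_loq,
    dynamic_range_fit,
    one_way_anova,
    precision_summary,
    relative_deviation,
    rsd,
)


class TestRelativeDeviation:
    @pytest.mark.parametrize(
        "measured,actual,expected",
        [
            (58.65, 60, -2.25),   # published verification level
            (0.15171, 0.1, 51.71),  # published trace level (unrounded mean)
            (41.32, 40, 3.30),
        ],
    )
    def test_published_values(self, measured, actual, expected):
        assert relative_deviation(measured, actual) == pytest.approx(
            expected, abs=0.005
        )

    def test_exact_measurement_is_zero(self):
        assert relative_deviation(37.2, 37.2) == 0.0

    def test_zero_actual_rejected(self):
        with pytest.raises(InputError):
            relative_deviation(1.0, 0.0)

    def test_sign_follows_measured_minus_actual(self, rng):
        for _ in range(50):
            m, a = rng.uniform(0.1, 100, size=2)
            assert math.copysign(1, relative_deviation(m, a)) == math.copysign(
                1, m - a
            ) or m == a


class TestRsd:
    def test_published_k_column(self):
        assert rsd([0.44, 0.41, 0.43, 0.44, 0.44]) == pytest.approx(3.02, abs=0.005)

    def test_constant_vector_is_zero(self):
        assert rsd([7.7] * 6) == 0.0

    def test_hand_arithmetic(self):
        assert rsd([1, 2, 3]) == pytest.approx(50.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            rsd([1.0])
        with pytest.raises(InputError):
            rsd([-1.0, 1.0])


class TestDynamicRangeFit:
    def test_perfect_recovery_line(self):
        x = [1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90]
        slope, intercept, r2 = dynamic_range_fit(x, x)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        slope, intercept, r2 = dynamic_range_fit([10, 90], [12, 95])
        assert slope == pytest.approx((95 - 12) / 80)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS coefficients equal the closed-form normal equations to 1e-10."""
        x = np.array([1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90], dtype=float)
        y = x + rng.normal(0, 2, size=x.size)
        slope, intercept, r2 = dynamic_range_fit(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert intercept == pytest.approx(beta[0], abs=1e-10)
        assert slope == pytest.approx(beta[1], abs=1e-10)
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)

    def test_degenerate_x_rejected(self):
        with pytest.raises(InputError):
            dynamic_range_fit([5, 5, 5], [1, 2, 3])


PUBLISHED_RATES = [(0.05, 0.0), (0.1, 75.0), (0.2, 100.0), (0.5, 100.0),
                   (0.8, 100.0), (1.0, 100.0), (5.0, 100.0)]
PUBLISHED_DEVIATIONS = [(0.2, 81.89), (0.5, -25.52), (0.8, -4.52),
                        (1.0, 15.28), (5.0, 10.10)]


class TestLodLoq:
    def test_published_detection_rates_give_lod_02(self):
        assert determine_lod(PUBLISHED_RATES) == 0.2

    def test_all_levels_detected_returns_lowest(self):
        assert determine_lod([(0.1, 100.0), (1.0, 100.0)]) == 0.1

    def test_no_stable_level_is_undefined(self):
        assert determine_lod([(0.1, 75.0), (1.0, 99.0)]) is None

    def test_published_deviations_give_loq_08(self):
        """The 0.5% failure below 0.8% does not block the answer."""
        assert determine_loq(PUBLISHED_DEVIATIONS) == 0.8

    def test_failure_above_a_passing_level_does_block(self):
        levels = [(0.2, 10.0), (0.5, 5.0), (1.0, -40.0), (5.0, 3.0)]
        assert determine_loq(levels) == 5.0

    def test_all_pass_returns_lowest(self):
        assert determine_loq([(0.1, 2.0), (1.0, -3.0)]) == 0.1

    def test_all_fail_is_undefined(self):
        assert determine_loq([(0.1, 60.0), (1.0, -80.0)]) is None

    def test_adding_a_passing_level_above_answer_is_neutral(self):
        base = determine_loq(PUBLISHED_DEVIATIONS)
        extended = PUBLISHED_DEVIATIONS + [(10.0, 1.0)]
        assert determine_loq(extended) == base
        rates = determine_lod(PUBLISHED_RATES)
        assert determine_lod(PUBLISHED_RATES + [(10.0, 100.0)]) == rates

    def test_unsorted_levels_rejected(self):
        with pytest.raises(InputError):
            determine_lod([(1.0, 100.0), (0.1, 100.0)])


class TestOneWayAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_decomposition(self):
        """Groups {0,1} and {2,3}: SSB 4, SSW 1, F 8 on (1, 2) df."""
        res = one_way_anova([[0.0, 1.0], [2.0, 3.0]])
        assert res.f_statistic == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)
        assert res.p_value == pytest.approx(float(stats.f.sf(8.0, 1, 2)))

    def test_agrees_with_scipy_f_oneway(self, rng):
        groups = [rng.normal(i * 0.3, 1.0, size=8) for i in range(4)]
        res = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_within_variance_flagged_degenerate(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert math.isinf(res.f_statistic)
        assert res.p_value == 0.0
        assert res.degenerate

    def test_invariant_to_shift_and_scale(self, rng):
        groups = [rng.normal(i, 1.0, size=6) for i in range(3)]
        base = one_way_anova(groups)
        moved = one_way_anova([np.asarray(g) * 3.7 + 11.0 for g in groups])
        assert moved.f_statistic == pytest.approx(base.f_statistic, rel=1e-9)
        assert moved.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_type_i_error_rate_is_nominal(self):
        """Null treatment data: rejection rate at alpha=0.05 in [0.03, 0.07]."""
        rng = np.random.default_rng(12345)
        rejections = 0
        n_runs = 2000
        for _ in range(n_runs):
            groups = rng.normal(70.0, 1.5, size=(3, 4))
            if one_way_anova(list(groups)).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_runs <= 0.07

    def test_too_small_inputs_rejected(self):
        with pytest.raises(InputError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(InputError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestPrecisionSummary:
    def _data(self, rng, levels=(10, 30, 50), runs=6, reps=6, noise=0.02):
        rows = []
        for level in levels:
            for run in range(runs):
                run_shift = rng.normal(0, noise * level)
                for _ in range(reps):
                    rows.append(
                        {
                            "level": level,
                            "run": f"run{run}",
                            "value": level + run_shift + rng.normal(0, noise * level),
                        }
                    )
        return pd.DataFrame(rows)

    def test_per_level_rows_plus_average(self, rng):
        out = precision_summary(self._data(rng))
        assert list(out["level"]) == [10, 30, 50, "average"]
        body = out.iloc[:-1]
        avg = out.iloc[-1]
        assert avg["repeatability_rsd_pct"] == pytest.approx(
            body["repeatability_rsd_pct"].mean()
        )

    def test_noise_free_data_has_zero_rsds(self):
        df = pd.DataFrame(
            {"level": [10] * 8, "run": ["a"] * 4 + ["b"] * 4, "value": [10.0] * 8}
        )
        out = precision_summary(df)
        assert out["repeatability_rsd_pct"].iloc[0] == 0.0
        assert out["reproducibility_rsd_pct"].iloc[0] == 0.0

    def test_reproducibility_sees_between_run_shifts(self, rng):
        """Pure between-run shifts inflate reproducibility, not repeatability."""
        rows = []
        for run, shift in (("a", -1.0), ("b", 1.0)):
            for _ in range(4):
                rows.append({"level": 50, "run": run, "value": 50 + shift})
        out = precision_summary(pd.DataFrame(rows))
        assert out["repeatability_rsd_pct"].iloc[0] == pytest.approx(0.0)
        assert out["reproducibility_rsd_pct"].iloc[0] > 0.0

    def test_missing_columns_rejected(self):
        with pytest.raises(InputError):
            precision_summary(pd.DataFrame({"level": [1], "value": [1.0]}))


def test_published_sensitivity_table_reproduces_decision_inputs():
    """The bundled low-fraction series feeds the LOD/LOQ rules directly."""
    tab = datasets.sensitivity_table()
    rates = list(zip(tab["trout_mass_fraction_pct"], tab["detection_rate_pct"]))
    assert determine_lod(rates) == 0.2
    quantified = tab[tab["trout_mass_fraction_pct"] >= 0.2]
    devs = list(zip(quantified["trout_mass_fraction_pct"], quantified["deviation_pct"]))
    assert determine_loq(devs) == 0.8
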