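"""Evaluation statistics: error %, acceptability, RMSE, Spearman, Bland-Altman."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fetalrri import (
    DegenerateInputError,
    acceptability,
    bland_altman,
    error_percentage,
    error_vs_ga,
    evaluate_predictions,
    format_error_pct,
    rmse,
    spearman,
    validation_table,
)


class TestErrorPercentage:
    @pytest.mark.parametrize(
        "predicted, actual, printed",
        [(434.0, 445.0, "2.5"), (410.0, 502.0, "18")],
    )
    def test_validation_worked_examples(self, predicted, actual, printed):
        assert format_error_pct(float(error_percentage(predicted, actual))) == printed

    def test_identity_zero(self):
        assert error_percentage(412.0, 412.0) == 0.0

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(DegenerateInputError):
            error_percentage(400.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(min_value=1.0, max_value=1e3),
        st.floats(min_value=1.0, max_value=1e3),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, predicted, actual, c):
        base = float(error_percentage(predicted, actual))
        scaled = float(error_percentage(c * predicted, c * actual))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestAcceptability:
    def test_validation_cohort_rejects_three(self):
        df = validation_table()
        err = error_percentage(df["predicted_frri_ms"].to_numpy(), df["actual_frri_ms"].to_numpy())
        accepted, rejected = acceptability(err, df["subject"].tolist())
        assert accepted == 11
        assert rejected == [4, 5, 13]

    def test_boundary_inclusive(self):
        accepted, rejected = acceptability([5.0, 5.0001])
        assert accepted == 1 and rejected == [1]

    def test_empty(self):
        assert acceptability([]) == (0, [])


class TestRMSE:
    def test_identical(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_analytic(self):
        assert rmse([0.0, 0.0], [3.0, -4.0]) == pytest.approx(np.sqrt(12.5))

    def test_length_mismatch(self):
        with pytest.raises(Exception):
            rmse([1.0], [1.0, 2.0])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**3 + 1)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_data_matches_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0, 9.0, 10.0])
        r, _ = spearman(x, y)
        # independent oracle: Pearson correlation of average ranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(r_oracle)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=50))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(x), y**3)  # strictly monotone transforms
        assert r2 == pytest.approx(r1)


class TestBlandAltman:
    def test_identical_vectors(self):
        mean, upper, lower, _ = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (mean, upper, lower) == (0.0, 0.0, 0.0)

    def test_unit_sd_limits(self):
        mean, upper, lower, _ = bland_altman([0.0, 0.0, 0.0], [-1.0, 0.0, 1.0])
        assert mean == 0.0
        assert upper == pytest.approx(1.96)
        assert lower == pytest.approx(-1.96)

    def test_gaussian_coverage(self):
        rng = np.random.default_rng(1)
        actual = np.full(1000, 412.0)
        predicted = actual + rng.normal(0, 8, 1000)
        *_, pct_within = bland_altman(actual, predicted)
        assert 93.0 <= pct_within <= 97.0

    def test_limits_widen_monotonically_with_noise(self):
        rng = np.random.default_rng(2)
        actual = np.full(300, 412.0)
        widths = []
        for sd in (2.0, 6.0, 18.0):
            _, upper, lower, _ = bland_altman(actual, actual + rng.normal(0, sd, 300))
            assert lower <= 0.0 <= upper or lower <= upper
            widths.append(upper - lower)
        assert widths[0] < widths[1] < widths[2]


class TestErrorVsGA:
    def _result(self, errors, ga):
        actual = 400.0 + np.arange(len(errors), dtype=float)  # non-degenerate
        predicted = actual * (1 + np.asarray(errors) / 100.0)
        return evaluate_predictions(list(range(len(errors))), ga, actual, predicted)

    def test_errors_equal_ga_perfect_correlation(self):
        ga = np.linspace(20, 40, 30)
        r, _ = error_vs_ga(self._result(ga.copy(), ga))
        assert r == pytest.approx(1.0)

    def test_constant_errors_undefined(self):
        # doubling every value gives an exactly constant 100 % error
        with pytest.raises(DegenerateInputError):
            error_vs_ga(self._result(np.full(20, 100.0), np.linspace(20, 40, 20)))

    def test_independent_errors_near_zero(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            errors = np.abs(rng.normal(0, 3, 150))
            ga = rng.uniform(19, 40, 150)
            r, p = error_vs_ga(self._result(errors, ga))
            if abs(r) < 0.15 and p > 0.05:
                hits += 1
        assert hits >= 8


def test_evaluate_predictions_assembles_consistent_result():
    rng = np.random.default_rng(4)
    actual = rng.normal(412, 24, 40)
    predicted = actual + rng.normal(0, 12, 40)
    res = evaluate_predictions([f"S{i}" for i in range(40)], rng.uniform(19, 40, 40), actual, predicted)
    assert res.n == 40
    assert res.ba_lower_ms <= res.ba_mean_diff_ms <= res.ba_upper_ms
    assert 0 <= res.pct_within_limits <= 100
    assert np.all(res.error_pct >= 0)
    assert res.rmse_ms == pytest.approx(rmse(actual, predicted))
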