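import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from kappaml import (
    IntervalEstimate,
    KappamlError,
    OGModelParams,
    PairedRatings,
    bootstrap_ci,
    ci_kappa_lipschitz,
    ci_kappa_monotone,
    ci_r_normal,
    simulate_disagreement_counts,
    simulate_ratings,
    var_r_ml,
)


class TestVariance:
    @pytest.mark.parametrize(
        "r, n, expected",
        [(0.0, 50, 0.0), (1.0, 100, 0.01), (0.5, 100, 0.0075)],
    )
    def test_closed_form(self, r, n, expected):
        assert var_r_ml(r, n) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(KappamlError):
            var_r_ml(1.5, 10)
        with pytest.raises(KappamlError):
            var_r_ml(0.5, 0)

    @pytest.mark.parametrize("r", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("n_cases", [50, 500])
    def test_matches_simulated_variance(self, r, n_cases):
        """Empirical Var(r_ML) agrees with r(2-r)/N within 3 MC errors."""
        reps = 20000
        nd = simulate_disagreement_counts(
            OGModelParams(r=r), n_cases, reps, seed=1000 + int(r * 10) + n_cases
        )
        rml = 2.0 * nd / n_cases
        sample_var = rml.var(ddof=1)
        centred = rml - rml.mean()
        se_var = np.sqrt(
            (np.mean(centred**4) - sample_var**2) / reps
        )
        assert abs(sample_var - var_r_ml(r, n_cases)) < 3 * se_var


class TestNormalInterval:
    def test_zero_estimate_degenerates_to_point(self):
        ci = ci_r_normal(0.0, 100)
        assert (ci.lower, ci.point, ci.upper) == (0.0, 0.0, 0.0)
        assert ci.degenerate

    def test_half_width_matches_normal_quantile(self):
        ci = ci_r_normal(0.5, 100, level=0.95)
        expected = stats.norm.ppf(0.975) * np.sqrt(0.0075)
        assert ci.upper - ci.point == pytest.approx(expected, abs=1e-12)
        assert ci.point - ci.lower == pytest.approx(expected, abs=1e-12)

    def test_bounds_clipped_to_unit_interval(self):
        ci = ci_r_normal(0.98, 30, level=0.99)
        assert ci.upper == 1.0
        assert ci.lower >= 0.0

    def test_out_of_model_estimate_clipped_before_plugin(self):
        assert ci_r_normal(1.4, 100).point == 1.0

    def test_coverage_near_nominal(self):
        """95% interval for r covers the truth ~95% of the time."""
        r, n_cases, sims = 0.5, 100, 10000
        nd = simulate_disagreement_counts(
            OGModelParams(r=r), n_cases, sims, seed=77
        )
        covered = 0
        for count in np.bincount(nd, minlength=n_cases + 1).nonzero()[0]:
            ci = ci_r_normal(2.0 * count / n_cases, n_cases)
            if ci.lower <= r <= ci.upper:
                covered += np.sum(nd == count)
        assert 0.93 <= covered / sims <= 0.97


class TestKappaIntervals:
    def test_lipschitz_substitution(self):
        r_int = IntervalEstimate(0.5, 0.4, 0.6, 0.95, "normal_r")
        ci = ci_kappa_lipschitz(r_int)
        assert ci.point == pytest.approx(2 / 3, abs=1e-12)
        assert ci.lower == pytest.approx(2 / 3 - 0.2, abs=1e-12)
        assert ci.upper == pytest.approx(2 / 3 + 0.2, abs=1e-12)

    def test_monotone_image(self):
        r_int = IntervalEstimate(0.5, 0.4, 0.6, 0.95, "normal_r")
        ci = ci_kappa_monotone(r_int)
        assert ci.lower == pytest.approx(0.4 / 0.7, abs=1e-12)
        assert ci.upper == pytest.approx(0.6 / 0.8, abs=1e-12)

    def test_full_range_maps_to_full_range(self):
        r_int = IntervalEstimate(0.5, 0.0, 1.0, 0.95, "normal_r")
        ci = ci_kappa_monotone(r_int)
        assert (ci.lower, ci.upper) == (0.0, 1.0)

    def test_degenerate_r_interval_maps_to_point(self):
        r_int = IntervalEstimate(0.3, 0.3, 0.3, 0.95, "normal_r")
        for ci in (ci_kappa_lipschitz(r_int), ci_kappa_monotone(r_int)):
            assert ci.lower == ci.point == ci.upper
            assert ci.degenerate

    @given(
        r0=st.floats(0.0, 1.0),
        delta=st.floats(0.0, 0.5),
        n=st.sampled_from([2, 3, 5]),
    )
    def test_monotone_interval_inside_lipschitz(self, r0, delta, n):
        r_int = IntervalEstimate(
            r0, max(0.0, r0 - delta), min(1.0, r0 + delta), 0.95, "normal_r"
        )
        lip = ci_kappa_lipschitz(r_int, n)
        mono = ci_kappa_monotone(r_int, n)
        assert lip.lower <= mono.lower + 1e-12
        assert mono.upper <= lip.upper + 1e-12
        assert mono.width <= (n / (n - 1)) * r_int.width + 1e-12


class TestBootstrap:
    def test_deterministic_given_seed(self, binary_example):
        a = bootstrap_ci(binary_example, "ml", n_boot=500, seed=9)
        b = bootstrap_ci(binary_example, "ml", n_boot=500, seed=9)
        assert a == b

    def test_all_agree_input_degenerates(self):
        ratings = PairedRatings.from_sequences(list("++--"), list("++--"))
        ci = bootstrap_ci(ratings, "ml", seed=1)
        assert (ci.lower, ci.point, ci.upper) == (1.0, 1.0, 1.0)
        assert ci.degenerate

    @pytest.mark.parametrize("estimator", ["cohen", "gwet", "ml"])
    def test_interval_contains_point(self, estimator):
        params = OGModelParams(r=0.4, q=0.3)
        ratings = simulate_ratings(params, 120, seed=5)
        ci = bootstrap_ci(ratings, estimator, n_boot=400, seed=11)
        assert ci.lower <= ci.point <= ci.upper
        assert -1.0 <= ci.lower and ci.upper <= 1.0

    def test_width_shrinks_like_root_n(self):
        params = OGModelParams(r=0.5, q=0.2)
        widths = []
        for n_cases, seed in [(50, 21), (200, 22), (800, 23)]:
            ratings = simulate_ratings(params, n_cases, seed=seed)
            widths.append(
                bootstrap_ci(ratings, "ml", n_boot=1000, seed=seed).width
            )
        # each 4x increase in N should roughly halve the width
        assert widths[1] < widths[0] and widths[2] < widths[1]
        assert 0.3 < widths[1] / widths[0] < 0.8
        assert 0.3 < widths[2] / widths[1] < 0.8

    def test_invalid_arguments(self, binary_example):
        with pytest.raises(KappamlError):
            bootstrap_ci(binary_example, "acme", seed=0)
        with pytest.raises(KappamlError):
            bootstrap_ci(binary_example, "ml", n_boot=10, seed=0)


def test_interval_must_contain_point():
    with pytest.raises(KappamlError):
        IntervalEstimate(0.9, 0.1, 0.5, 0.95, "normal_r")
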