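import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from voe import (
    DegenerateVariableError,
    MEDraw,
    MERanges,
    VoeError,
    add_classical_error,
    corrupt_cohort,
    draw_me_params,
    misclassify_binary,
    perturb_ordinal,
    variance_of_error,
)


class TestVarianceOfError:
    @pytest.mark.parametrize(
        "var_x, rho, expected",
        [(1.0, 0.8, 0.5625), (4.0, 0.5, 12.0), (2.7, 1.0, 0.0)],
    )
    def test_closed_form(self, var_x, rho, expected):
        assert variance_of_error(var_x, rho) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("rho", [0.0, -0.2, 1.5])
    def test_rho_domain(self, rho):
        with pytest.raises(VoeError):
            variance_of_error(1.0, rho)

    @given(
        var_x=st.floats(0.1, 100),
        rho1=st.floats(0.1, 0.99),
        rho2=st.floats(0.1, 0.99),
    )
    def test_decreasing_in_rho_and_linear_in_var(self, var_x, rho1, rho2):
        lo, hi = sorted((rho1, rho2))
        if hi - lo > 1e-6:
            assert variance_of_error(var_x, lo) > variance_of_error(var_x, hi)
        assert variance_of_error(2 * var_x, rho1) == pytest.approx(
            2 * variance_of_error(var_x, rho1), rel=1e-9
        )


class TestClassicalError:
    def test_perfect_measurement_is_identity(self, rng):
        x = rng.normal(size=500)
        np.testing.assert_array_equal(add_classical_error(x, 1.0, rng), x)

    def test_mean_correlation_matches_target(self, rng):
        # over replicates, mean empirical corr(X, Z) is within 2 SE of rho
        n, M = 10_000, 100
        for rho in (0.73, 0.8, 0.9):
            x = rng.normal(size=n)
            corrs = [
                np.corrcoef(x, add_classical_error(x, rho, rng))[0, 1]
                for _ in range(M)
            ]
            se = np.std(corrs, ddof=1) / np.sqrt(M)
            assert abs(np.mean(corrs) - rho) < 2 * se + 1e-4

    def test_attenuation_law(self, rng):
        # slope of y ~ Z is beta * rho^2 (regression dilution), rho = 0.8
        n, beta, rho = 200_000, 0.7, 0.8
        x = rng.normal(size=n)
        y = beta * x + rng.normal(size=n)
        z = add_classical_error(x, rho, rng)
        slope = np.polyfit(z, y, 1)[0]
        assert slope == pytest.approx(beta * rho**2, rel=0.05)

    def test_constant_column_errors(self, rng):
        with pytest.raises(DegenerateVariableError):
            add_classical_error(np.ones(50), 0.9, rng)


class TestMisclassify:
    def test_perfect_rates_identity(self, rng):
        x = (rng.random(300) < 0.4).astype(int)
        np.testing.assert_array_equal(misclassify_binary(x, 1.0, 1.0, rng), x)

    def test_transition_counts_binomial(self, rng):
        # among true ones, observed ones ~ Binomial(n1, sens)
        n, sens = 50_000, 0.7
        x = np.ones(n, dtype=int)
        kept = misclassify_binary(x, sens, 0.9, rng).sum()
        assert abs(kept - n * sens) < 4 * np.sqrt(n * sens * (1 - sens))

    def test_zeros_flip_at_one_minus_specificity(self, rng):
        n, spec = 50_000, 0.73
        z = misclassify_binary(np.zeros(n, dtype=int), 0.85, spec, rng)
        assert z.mean() == pytest.approx(1 - spec, abs=0.01)

    def test_non_binary_rejected(self, rng):
        with pytest.raises(TypeError):
            misclassify_binary(np.array([0, 1, 2]), 0.9, 0.9, rng)


class TestPerturbOrdinal:
    def test_perfect_measurement_is_identity(self, rng):
        x = rng.integers(1, 5, size=2000)
        np.testing.assert_array_equal(perturb_ordinal(x, 1.0, rng), x)

    def test_marginals_approximately_preserved(self, rng):
        n, L = 200_000, 4
        x = rng.integers(1, L + 1, size=n)
        z = perturb_ordinal(x, 0.8, rng)
        for lev in range(1, L + 1):
            assert (z == lev).mean() == pytest.approx((x == lev).mean(), abs=0.02)

    def test_spearman_decreases_with_rho(self, rng):
        x = rng.integers(1, 5, size=100_000)
        rhos = [1.0, 0.8, 0.6]
        corrs = [stats.spearmanr(x, perturb_ordinal(x, r, rng)).statistic for r in rhos]
        assert corrs[0] > corrs[1] > corrs[2]

    def test_too_few_levels_rejected(self, rng):
        with pytest.raises(TypeError):
            perturb_ordinal(np.array([0, 1, 0, 1]), 0.9, rng)

    def test_unobserved_level_rejected(self, rng):
        x = np.array([1, 1, 3, 3, 3, 1])
        with pytest.raises(DegenerateVariableError):
            perturb_ordinal(x, 0.9, rng, levels=np.array([1, 2, 3]))


class TestDrawParams:
    def test_degenerate_ranges_hit_bounds(self, rng):
        r = MERanges(0.8, 0.8, 0.7, 0.7, 0.9, 0.9)
        draw = draw_me_params(r, rng)
        assert (draw.rho, draw.sensitivity, draw.specificity) == (0.8, 0.7, 0.9)

    def test_uniform_mean_and_support(self, rng):
        r = MERanges()
        draws = [draw_me_params(r, rng) for _ in range(10_000)]
        rhos = np.array([d.rho for d in draws])
        assert rhos.mean() == pytest.approx((0.73 + 0.9) / 2, abs=0.005)
        assert rhos.min() >= 0.73 and rhos.max() <= 0.9
        assert all(0.56 <= d.sensitivity <= 0.85 for d in draws)
        assert all(0.73 <= d.specificity <= 0.98 for d in draws)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(VoeError):
            MERanges(rho_low=0.9, rho_high=0.8)


class TestCorruptCohort:
    def test_exposure_only_leaves_adjustments(self, small_cohort, rng):
        draw = MEDraw(0.8, 0.7, 0.9)
        out = corrupt_cohort(small_cohort, draw, "exposure_only", rng)
        for name in small_cohort.adjustment_vars:
            np.testing.assert_array_equal(out.data[name], small_cohort.data[name])
        assert not np.array_equal(
            out.data[small_cohort.exposure], small_cohort.data[small_cohort.exposure]
        )

    def test_adjustment_only_leaves_exposure(self, small_cohort, rng):
        out = corrupt_cohort(small_cohort, MEDraw(0.8, 0.7, 0.9), "adjustment_only", rng)
        np.testing.assert_array_equal(
            out.data[small_cohort.exposure], small_cohort.data[small_cohort.exposure]
        )

    def test_error_free_and_outcome_untouched(self, small_cohort, rng):
        out = corrupt_cohort(small_cohort, MEDraw(0.8, 0.7, 0.9), "both", rng)
        for name in ("age", "sex", "time", "event"):
            np.testing.assert_array_equal(out.data[name], small_cohort.data[name])

    def test_no_error_draw_is_identity(self, small_cohort, rng):
        out = corrupt_cohort(small_cohort, MEDraw(1.0, 1.0, 1.0), "both", rng)
        assert out.data.equals(small_cohort.data)

    def test_invalid_scenario(self, small_cohort, rng):
        with pytest.raises(VoeError):
            corrupt_cohort(small_cohort, MEDraw(0.8, 0.7, 0.9), "everything", rng)
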