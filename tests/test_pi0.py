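"""Unit and property tests for the pi0(x) regression core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from covfdr import (
    BootstrapConfig,
    DesignMatrix,
    LambdaGrid,
    PValueSet,
    bootstrap_pi0,
    estimate_pi0,
    exceedance_indicators,
    fit_pi0_lambda,
    smooth_lambda_profile,
    storey_pi0,
)


class TestExceedanceIndicators:
    @pytest.mark.parametrize(
        "p, lam, expected",
        [
            ([0.96, 0.50, 0.01], 0.95, [1, 0, 0]),
            ([0.5, 0.4], 0.5, [0, 0]),  # strict inequality at the threshold
            ([1.0, 1.0], 0.95, [1, 1]),
        ],
    )
    def test_examples(self, p, lam, expected):
        np.testing.assert_array_equal(
            exceedance_indicators(np.array(p), lam), expected
        )

    @pytest.mark.parametrize("lam", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_threshold(self, lam):
        with pytest.raises(ValueError, match="lambda"):
            exceedance_indicators(np.array([0.1, 0.9]), lam)


class TestPValueSet:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            PValueSet(np.array([0.1, 1.7]))

    def test_rejects_nan_and_short(self):
        with pytest.raises(ValueError, match="non-finite"):
            PValueSet(np.array([0.1, np.nan]))
        with pytest.raises(ValueError, match="at least 2"):
            PValueSet(np.array([0.5]))

    def test_auto_ids(self):
        ps = PValueSet(np.array([0.1, 0.2]))
        assert list(ps.feature_id) == ["feature_0", "feature_1"]


class TestDesignMatrix:
    def test_requires_intercept_first(self):
        with pytest.raises(ValueError, match="intercept"):
            DesignMatrix(np.arange(6.0).reshape(3, 2))

    def test_rank_reported(self, rng):
        x = rng.uniform(size=50)
        Z = np.column_stack([np.ones(50), x, 2 * x])  # collinear
        assert DesignMatrix(Z).rank == 2


class TestFitPi0Lambda:
    def test_intercept_only_is_sample_mean(self, rng):
        Y = np.zeros(100)
        Y[:80] = 1.0
        Z = np.ones((100, 1))
        for method in ("logistic", "linear"):
            out = fit_pi0_lambda(Y, Z, 0.2, method=method)
            np.testing.assert_allclose(out, 1.0)  # (0.8 / 0.8) capped at 1

    def test_intercept_only_linear_matches_threshold_estimator(self, rng):
        """Supplement-style reduction: the no-covariate linear fit equals
        (m - R) / ((1 - lambda) m) at every lambda."""
        for _ in range(50):
            m = rng.integers(5, 200)
            p = rng.uniform(size=m)
            lam = rng.uniform(0.05, 0.95)
            Y = exceedance_indicators(p, lam)
            fitted = fit_pi0_lambda(Y, np.ones((m, 1)), lam, method="linear")
            expected = min(np.sum(p > lam) / ((1 - lam) * m), 1.0)
            np.testing.assert_allclose(fitted, expected, rtol=0, atol=1e-12)

    def test_logistic_linear_agree_at_saturation(self, rng):
        p = rng.uniform(size=500)
        Z = np.ones((500, 1))
        for lam in (0.1, 0.5, 0.9):
            Y = exceedance_indicators(p, lam)
            a = fit_pi0_lambda(Y, Z, lam, method="logistic")
            b = fit_pi0_lambda(Y, Z, lam, method="linear")
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_logistic_parameter_recovery(self, rng):
        """Generating-model oracle: with Y from a known logistic curve the
        fitted E(Y|x)/(1-lambda) tracks the truth within 0.02."""
        m = 50_000
        x = rng.uniform(size=m)
        Z = np.column_stack([np.ones(m), x])
        prob = expit(2.0 - 3.0 * x)
        Y = (rng.uniform(size=m) < prob).astype(float)
        lam = 0.5
        fitted = fit_pi0_lambda(Y, Z, lam, method="logistic")
        truth = np.clip(prob / (1 - lam), 0, 1)
        assert np.max(np.abs(fitted - truth)) < 0.02

    def test_matches_statsmodels_glm(self, rng):
        """Independent oracle: the IRLS coefficients agree with statsmodels'
        binomial GLM fit on the same data."""
        import statsmodels.api as sm

        m = 400
        x = rng.uniform(size=m)
        Z = np.column_stack([np.ones(m), x])
        Y = (rng.uniform(size=m) < expit(1.0 - 2.0 * x)).astype(float)
        ours = fit_pi0_lambda(Y, Z, 0.3, method="logistic")
        glm = sm.GLM(Y, Z, family=sm.families.Binomial()).fit()
        theirs = np.clip(glm.fittedvalues / 0.7, 0, 1)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_degenerate_indicator_vectors(self):
        Z = np.column_stack([np.ones(10), np.arange(10.0)])
        np.testing.assert_allclose(
            fit_pi0_lambda(np.ones(10), Z, 0.5, method="logistic"), 1.0
        )
        np.testing.assert_allclose(
            fit_pi0_lambda(np.zeros(10), Z, 0.5, method="logistic"), 0.0
        )


class TestSmoothLambdaProfile:
    def test_preserves_constants(self):
        grid = LambdaGrid()
        prof = np.full((5, len(grid)), 0.7)
        np.testing.assert_allclose(smooth_lambda_profile(prof, grid), 0.7, atol=1e-8)

    def test_preserves_linear_profiles(self):
        """Linear functions lie in the smoothing-spline penalty null space."""
        grid = LambdaGrid()
        prof = (0.5 + (0.9 - 0.5) * (grid.values - 0.05) / 0.9)[None, :]
        out = smooth_lambda_profile(prof, grid)
        np.testing.assert_allclose(out, 0.9, atol=1e-8)

    def test_clips_into_unit_interval(self):
        grid = LambdaGrid()
        prof = (1.0 + 0.1 * grid.values)[None, :]  # raw smooth > 1 at 0.95
        assert smooth_lambda_profile(prof, grid) == pytest.approx(1.0)

    def test_is_a_fixed_linear_map(self, rng):
        """Smoothing the average profile equals averaging smoothed profiles."""
        grid = LambdaGrid()
        prof = rng.uniform(size=(40, len(grid)))
        smoothed = smooth_lambda_profile(prof, grid)
        avg_then_smooth = smooth_lambda_profile(prof.mean(0)[None, :], grid)
        np.testing.assert_allclose(smoothed.mean(), avg_then_smooth[0], atol=1e-10)

    def test_grid_too_short(self):
        with pytest.raises(ValueError, match="df"):
            smooth_lambda_profile(np.ones((2, 3)), np.array([0.1, 0.5, 0.9]), df=3)


class TestEstimatePi0:
    def test_all_large_pvalues_give_pi0_one(self, rng):
        p = rng.uniform(0.96, 1.0, size=100)
        x = rng.uniform(size=100)
        fit = estimate_pi0(p, np.column_stack([np.ones(100), x]))
        np.testing.assert_allclose(fit.pi0, 1.0)

    def test_global_null_mean_near_one(self, uniform_pvalues):
        p, x = uniform_pvalues
        Z = np.column_stack([np.ones(p.size), x])
        fit = estimate_pi0(p, Z)
        assert 0.9 <= fit.pi0.mean() <= 1.0

    def test_profile_and_estimates_in_unit_interval(self, rng):
        p = rng.beta(0.5, 1.0, size=300)
        Z = np.column_stack([np.ones(300), rng.normal(size=300)])
        for method in ("logistic", "linear"):
            fit = estimate_pi0(p, Z, method=method)
            assert fit.profile.estimates.min() >= 0.0
            assert fit.profile.estimates.max() <= 1.0
            assert fit.pi0.min() >= 0.0 and fit.pi0.max() <= 1.0

    def test_intercept_only_linear_single_lambda_reduction(self, rng):
        """With smoothing reduced to a single threshold the pipeline returns
        the scalar threshold estimator replicated m times."""
        p = rng.uniform(size=200)
        lam = 0.5
        Y = exceedance_indicators(p, lam)
        fitted = fit_pi0_lambda(Y, np.ones((200, 1)), lam, method="linear")
        np.testing.assert_allclose(fitted, storey_pi0(p, lam), atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=150)
        x = rng.uniform(size=150)
        Z = np.column_stack([np.ones(150), x])
        perm = rng.permutation(150)
        a = estimate_pi0(p, Z).pi0
        b = estimate_pi0(p[perm], Z[perm]).pi0
        np.testing.assert_allclose(a[perm], b, atol=1e-9)


class TestStoreyPi0:
    def test_direct_evaluation(self):
        assert storey_pi0(np.array([0.1, 0.2, 0.6, 0.8]), 0.5) == pytest.approx(1.0)

    def test_floor_when_no_exceedances(self):
        p = np.full(50, 0.01)
        assert storey_pi0(p, 0.5) == pytest.approx(1 / 50)

    def test_uniform_null_expectation(self, rng):
        p = rng.uniform(size=10_000)
        assert storey_pi0(p, 0.5) == pytest.approx(1.0, abs=0.03)


class TestBootstrap:
    def test_seeded_determinism(self, rng):
        p = rng.uniform(size=120)
        Z = np.column_stack([np.ones(120), rng.uniform(size=120)])
        cfg = BootstrapConfig(B=20, alpha=0.1, seed=99)
        a = bootstrap_pi0(p, Z, cfg=cfg)
        b = bootstrap_pi0(p, Z, cfg=cfg)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_degenerate_pvalues_give_unit_bounds(self):
        p = np.full(40, 0.99)
        lo, hi = bootstrap_pi0(p, None, cfg=BootstrapConfig(B=10, seed=3))
        np.testing.assert_allclose(lo, 1.0)
        np.testing.assert_allclose(hi, 1.0)

    def test_pointwise_coverage_scenario_I(self):
        """Coverage oracle: under a flat pi0=0.9 truth, 90% intervals should
        cover 0.9 for most features over repeated small simulations."""
        rng = np.random.default_rng(11)
        covered = total = 0
        for _ in range(20):
            m = 200
            x = rng.uniform(size=m)
            null = rng.uniform(size=m) < 0.9
            p = np.where(null, rng.uniform(size=m), rng.beta(1, 20, size=m))
            Z = np.column_stack([np.ones(m), x])
            lo, hi = bootstrap_pi0(
                p, Z, cfg=BootstrapConfig(B=40, alpha=0.10, seed=int(rng.integers(2**31)))
            )
            covered += int(np.sum((lo <= 0.9) & (0.9 <= hi)))
            total += m
        # nominal 90%, generous Monte-Carlo margin for small m and B
        assert covered / total >= 0.7


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    data=st.data(),
    m=st.integers(min_value=10, max_value=80),
)
def test_storey_reduction_property(data, m):
    """Intercept-only + linear method reproduces the threshold estimator at
    every lambda on arbitrary p-value vectors."""
    p = np.array(
        data.draw(
            st.lists(
                st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=m,
                max_size=m,
            )
        )
    )
    lam = data.draw(st.floats(min_value=0.05, max_value=0.95))
    Y = exceedance_indicators(p, lam)
    fitted = fit_pi0_lambda(Y, np.ones((m, 1)), lam, method="linear")
    expected = np.clip(np.sum(p > lam) / ((1 - lam) * m), 0.0, 1.0)
    np.testing.assert_allclose(fitted, expected, atol=1e-12)
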