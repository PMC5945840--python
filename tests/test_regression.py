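"""OLS baseline and scale-dependent DFA regression."""

import numpy as np
import pytest

from dfareg import (
    CollinearityError,
    DFARegression,
    InvalidDataError,
    ScaleGrid,
    ols_fit,
)

import oracles


@pytest.fixture
def exact_relation(rng):
    x1 = rng.standard_normal(256).cumsum()
    x2 = rng.standard_normal(256)
    y = 1.0 + x1 + 2.0 * x2
    return y, x1, x2


class TestOlsFit:
    def test_exact_linear_relation(self, exact_relation):
        y, x1, x2 = exact_relation
        fit = ols_fit(y, x1, x2)
        assert fit.beta0 == pytest.approx(1.0, abs=1e-8)
        assert fit.beta1 == pytest.approx(1.0, abs=1e-10)
        assert fit.beta2 == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_lstsq_oracle(self, rng):
        x1 = rng.standard_normal(200)
        x2 = rng.standard_normal(200)
        y = 0.5 - x1 + 3 * x2 + rng.standard_normal(200)
        fit = ols_fit(y, x1, x2)
        X = np.column_stack([np.ones(200), x1, x2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.beta1 == pytest.approx(beta[1], rel=1e-10)
        assert fit.beta2 == pytest.approx(beta[2], rel=1e-10)
        # classical sandwich-free variance with the N-3 divisor
        resid = y - X @ beta
        s2 = resid @ resid / (200 - 3)
        cov = s2 * np.linalg.inv(X.T @ X)
        assert fit.var1 == pytest.approx(cov[1, 1], rel=1e-8)
        assert fit.var2 == pytest.approx(cov[2, 2], rel=1e-8)

    def test_centered_regressor_has_zero_elasticity(self, rng):
        x1 = rng.standard_normal(100) + 5
        x2 = rng.standard_normal(100)
        x2 -= x2.mean()
        y = 2 + x1 + 4 * x2 + 0.1 * rng.standard_normal(100)
        fit = ols_fit(y, x1, x2)
        assert fit.eta2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_response_flags_eta(self, rng):
        x1 = rng.standard_normal(100)
        x2 = rng.standard_normal(100)
        y = x1 + x2
        y -= y.mean()
        fit = ols_fit(y, x1, x2)
        assert not fit.eta_defined
        assert np.isnan(fit.eta1)

    def test_residuals_zero_mean(self, rng):
        x1, x2 = rng.standard_normal((2, 150))
        y = x1 - x2 + rng.standard_normal(150)
        assert abs(ols_fit(y, x1, x2).residuals.mean()) < 1e-10

    def test_collinear_regressors_rejected(self, rng):
        x1 = rng.standard_normal(50)
        with pytest.raises(CollinearityError):
            ols_fit(rng.standard_normal(50), x1, 2 * x1)


class TestDfaFit:
    def test_exact_relation_recovered_at_every_scale(self, exact_relation):
        y, x1, x2 = exact_relation
        res = DFARegression(y, x1, x2).fit(ScaleGrid([8, 16, 32, 64]))
        assert res.usable.all()
        np.testing.assert_allclose(res.beta1, 1.0, atol=1e-8)
        np.testing.assert_allclose(res.beta2, 2.0, atol=1e-8)
        np.testing.assert_allclose(res.r_squared, 1.0, atol=1e-8)

    def test_coefficients_match_composed_oracle(self, rng):
        x1 = rng.standard_normal(256)
        x2 = 0.4 * x1 + rng.standard_normal(256)
        y = 1 + x1 + 2 * x2 + rng.standard_normal(256)
        res = DFARegression(y, x1, x2).fit(ScaleGrid([16, 32]))
        for i, n in enumerate([16, 32]):
            b1, b2 = oracles.dfa_betas_loop(y, x1, x2, n)
            assert res.beta1[i] == pytest.approx(b1, rel=1e-10)
            assert res.beta2[i] == pytest.approx(b2, rel=1e-10)

    def test_internal_consistency_of_r_squared(self, rng):
        x1, x2 = rng.standard_normal((2, 300))
        y = x1 + 2 * x2 + rng.standard_normal(300)
        res = DFARegression(y, x1, x2).fit(ScaleGrid([10, 30, 60]))
        np.testing.assert_allclose(
            res.r_squared,
            1 - res.residual_fluct / res.fluctuations["y"],
            rtol=1e-12,
        )

    def test_scaling_regressor_scales_coefficient_inversely(self, rng):
        x1, x2 = rng.standard_normal((2, 256))
        y = x1 + 2 * x2 + 0.5 * rng.standard_normal(256)
        grid = ScaleGrid([8, 16, 32])
        base = DFARegression(y, x1, x2).fit(grid)
        scaled = DFARegression(y, 4.0 * x1, x2).fit(grid)
        np.testing.assert_allclose(scaled.beta1, base.beta1 / 4.0, rtol=1e-9)
        np.testing.assert_allclose(scaled.beta2, base.beta2, rtol=1e-9)

    def test_location_shift_leaves_coefficients_unchanged(self, rng):
        x1, x2 = rng.standard_normal((2, 256))
        y = x1 + 2 * x2 + 0.5 * rng.standard_normal(256)
        grid = ScaleGrid([8, 16, 32])
        base = DFARegression(y, x1, x2).fit(grid)
        shifted = DFARegression(y + 3, x1 - 7, x2 + 100).fit(grid)
        np.testing.assert_allclose(shifted.beta1, base.beta1, rtol=1e-8)
        np.testing.assert_allclose(shifted.beta2, base.beta2, rtol=1e-8)

    def test_beta_star_invariant_to_regressor_rescaling(self, rng):
        x1, x2 = rng.standard_normal((2, 256))
        y = x1 + 2 * x2 + 0.5 * rng.standard_normal(256)
        grid = ScaleGrid([8, 16, 32])
        base = DFARegression(y, x1, x2).fit(grid)
        scaled = DFARegression(y, 5.0 * x1, 0.2 * x2).fit(grid)
        np.testing.assert_allclose(scaled.beta_star1, base.beta_star1, rtol=1e-9)
        np.testing.assert_allclose(scaled.beta_star2, base.beta_star2, rtol=1e-9)

    def test_collinear_regressors_flagged_not_dropped(self, rng):
        x1 = rng.standard_normal(128)
        y = rng.standard_normal(128)
        res = DFARegression(y, x1, 3.0 * x1).fit(ScaleGrid([8, 16]))
        assert not res.usable.any()
        assert np.isnan(res.beta1).all()
        assert len(res.beta1) == 2

    def test_variances_positive_on_noisy_data(self, rng):
        x1, x2 = rng.standard_normal((2, 400))
        y = x1 + x2 + rng.standard_normal(400)
        res = DFARegression(y, x1, x2).fit(ScaleGrid([10, 20, 50]))
        assert np.all(res.var1[res.usable] > 0)
        assert np.all(res.var2[res.usable] > 0)

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(InvalidDataError):
            DFARegression(
                rng.standard_normal(100),
                rng.standard_normal(100),
                rng.standard_normal(99),
            )

    def test_from_dataframe_round_trip(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            rng.standard_normal((200, 3)), columns=["resp", "a", "b"]
        )
        m = DFARegression.from_dataframe(df, y="resp", x1="a", x2="b")
        np.testing.assert_array_equal(m.y, df["resp"].to_numpy())

    def test_summary_schema(self, rng):
        x1, x2 = rng.standard_normal((2, 200))
        y = x1 + x2
        table = DFARegression(y, x1, x2).fit(ScaleGrid([10, 20])).summary()
        assert list(table.columns) == [
            "scale", "beta1", "beta2", "var1", "var2", "r_squared",
            "beta_star1", "beta_star2", "eta1", "eta2", "usable",
        ]


class TestAverageOverScales:
    def test_single_scale_is_identity(self, rng):
        x1, x2 = rng.standard_normal((2, 200))
        y = x1 + 2 * x2 + rng.standard_normal(200)
        res = DFARegression(y, x1, x2).fit(ScaleGrid([16]))
        assert res.average_over_scales() == (res.beta1[0], res.beta2[0])

    def test_zero_noise_gives_exact_pair(self, exact_relation):
        y, x1, x2 = exact_relation
        res = DFARegression(y, x1, x2).fit(ScaleGrid([8, 16, 32]))
        b1, b2 = res.average_over_scales()
        assert b1 == pytest.approx(1.0, abs=1e-8)
        assert b2 == pytest.approx(2.0, abs=1e-8)

    def test_matches_direct_mean(self, rng):
        x1, x2 = rng.standard_normal((2, 300))
        y = x1 + 2 * x2 + rng.standard_normal(300)
        res = DFARegression(y, x1, x2).fit(ScaleGrid([10, 20, 40, 70]))
        b1, b2 = res.average_over_scales(15, 50)
        sel = (res.scales >= 15) & (res.scales <= 50)
        assert b1 == pytest.approx(res.beta1[sel].mean())
        assert b2 == pytest.approx(res.beta2[sel].mean())

    def test_empty_range_raises(self, rng):
        x1, x2 = rng.standard_normal((2, 200))
        res = DFARegression(x1 + x2, x1, x2).fit(ScaleGrid([10, 20]))
        with pytest.raises(ValueError):
            res.average_over_scales(25, 30)
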