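"""Fitting and residual extraction."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sncp import (
    ARMAOrder,
    ARMAParams,
    ContractError,
    InvalidInputError,
    compute_residuals,
    compute_residuals_svr,
    fit_arma_qmle,
    simulate_arma,
)
from sncp.arma import reconstruct_series


class TestResidualRecursion:
    @pytest.mark.parametrize(
        "y, phi, theta, expected",
        [
            ([1.0, 0.0, 0.0], [0.5], [], [1.0, -0.5, 0.0]),
            ([1.0, 1.0], [0.0], [0.5], [1.0, 0.5]),
            ([2.0, -1.0, 3.0], [], [], [2.0, -1.0, 3.0]),  # order (0,0): identity
        ],
    )
    def test_hand_recursion(self, y, phi, theta, expected):
        params = ARMAParams(phi, theta, 1.0)
        res = compute_residuals(y, params)
        npt.assert_allclose(res.values, expected, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        params = ARMAParams([0.5], [], 1.0)
        with pytest.raises(ContractError):
            compute_residuals([1.0, 2.0, 3.0], params, ARMAOrder(2, 0))

    def test_nonfinite_series_rejected(self):
        params = ARMAParams([0.5], [], 1.0)
        with pytest.raises(InvalidInputError):
            compute_residuals([1.0, np.nan, 2.0], params)

    @given(
        phi=st.floats(-0.6, 0.6),
        theta=st.floats(-0.6, 0.6),
        data=st.lists(st.floats(-5, 5), min_size=5, max_size=40),
    )
    @settings(max_examples=50, deadline=None)
    def test_reconstruction_identity(self, phi, theta, data):
        """Re-substituting the residuals into the model recursion (zero
        pre-sample values) reproduces the input series."""
        params = ARMAParams([phi], [theta], 1.0)
        y = np.asarray(data)
        res = compute_residuals(y, params)
        npt.assert_allclose(reconstruct_series(res, params), y, atol=1e-9)

    def test_ar_residual_is_local_in_time(self, rng):
        """For q = 0 the residual at t depends only on y up to t: perturbing
        a later observation leaves earlier residuals untouched."""
        y = rng.standard_normal(50)
        params = ARMAParams([0.4, -0.2], [], 1.0)
        base = compute_residuals(y, params).values
        y2 = y.copy()
        y2[30] += 10.0
        pert = compute_residuals(y2, params).values
        npt.assert_array_equal(base[:30], pert[:30])
        assert pert[30] != base[30]


class TestQMLEFit:
    def test_ar1_recovery(self):
        y = simulate_arma(ARMAParams([0.5], [], 1.0), n=5000, seed=7)
        fit = fit_arma_qmle(y, ARMAOrder(1, 0))
        assert fit.converged
        assert abs(fit.params.phi[0] - 0.5) < 0.05
        assert abs(fit.params.sigma2 - 1.0) < 0.1

    def test_white_noise_has_no_ar_structure(self, rng):
        y = rng.standard_normal(5000)
        fit = fit_arma_qmle(y, ARMAOrder(1, 0))
        assert abs(fit.params.phi[0]) < 0.05

    def test_order_zero_reduces_to_variance(self, rng):
        y = rng.standard_normal(200) * 2.0 + 1.0
        fit = fit_arma_qmle(y, ARMAOrder(0, 0))
        assert fit.params.phi.size == 0 and fit.params.theta.size == 0
        assert fit.params.sigma2 == pytest.approx(np.var(y, ddof=1))
        assert fit.n_used == 200

    def test_arma11_css_close_to_exact_mle(self):
        """The conditional-sum-of-squares route and the exact state-space
        MLE are asymptotically equivalent; on one realization they should
        land close together."""
        y = simulate_arma(ARMAParams([0.3], [0.3], 1.0), n=500, seed=2)
        css = fit_arma_qmle(y, ARMAOrder(1, 1), method="css")
        exact = fit_arma_qmle(y, ARMAOrder(1, 1), method="exact")
        assert css.params.phi[0] == pytest.approx(exact.params.phi[0], abs=0.05)
        assert css.params.theta[0] == pytest.approx(exact.params.theta[0], abs=0.05)

    def test_ar1_sampling_distribution(self):
        """Over 200 independent AR(1) paths (n=1000, phi=0.5) the estimator
        is unbiased to within 0.02 with sampling sd below 0.05."""
        rng = np.random.default_rng(99)
        params = ARMAParams([0.5], [], 1.0)
        est = [
            fit_arma_qmle(
                simulate_arma(params, n=1000, seed=rng), ARMAOrder(1, 0)
            ).params.phi[0]
            for _ in range(200)
        ]
        assert abs(np.mean(est) - 0.5) < 0.02
        assert np.std(est) < 0.05

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidInputError, match="length"):
            fit_arma_qmle(np.ones(15) + np.arange(15) * 0.1, ARMAOrder(1, 1))

    def test_nonfinite_series_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_arma_qmle([1.0, np.inf] * 20, ARMAOrder(1, 0))


class TestStationarityFlags:
    def test_flags_not_silently_enforced(self):
        explosive = ARMAParams([1.2], [], 1.0)  # constructible, just flagged
        assert not explosive.is_stationary()
        assert explosive.is_invertible()
        assert ARMAParams([0.5], [0.4], 1.0).is_stationary()
        assert not ARMAParams([], [-1.5], 1.0).is_invertible()


class TestSVRBackend:
    def test_agrees_with_qmle_on_linear_data(self):
        y = simulate_arma(ARMAParams([0.5], [], 1.0), n=400, seed=3)
        qmle = compute_residuals(
            y, fit_arma_qmle(y, ARMAOrder(1, 0)).params
        ).values
        svr = compute_residuals_svr(y, ARMAOrder(1, 0)).values
        assert np.var(svr) == pytest.approx(np.var(qmle), rel=0.2)
        assert len(svr) == len(y)

    def test_constant_series_fits_nearly_exactly(self):
        y = np.full(60, 3.0)
        res = compute_residuals_svr(y, ARMAOrder(1, 0))
        assert np.max(np.abs(res.values[5:])) < 0.15  # epsilon-tube tolerance

    def test_order_zero_is_identity(self, rng):
        y = rng.standard_normal(30)
        res = compute_residuals_svr(y, ARMAOrder(0, 0))
        npt.assert_array_equal(res.values, y)
        assert res.source == "svr"

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_residuals_svr(np.arange(5.0), ARMAOrder(2, 0))
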