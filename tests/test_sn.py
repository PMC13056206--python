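"""The self-normalized statistic: hand values, oracle equality, invariances."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import literal_gn
from sncp import (
    ARMAOrder,
    ARMAParams,
    ChangePointDGP,
    ContractError,
    InvalidInputError,
    TrimWindow,
    compute_Gn,
    compute_Tn,
    partial_sum_process,
    run_sn_test,
    segment_mean,
    simulate_changepoint,
    sn_profile,
)

finite_arrays = st.lists(
    st.floats(-100.0, 100.0), min_size=14, max_size=60
).map(np.asarray)


class TestSegments:
    @pytest.mark.parametrize(
        "j, k, expected", [(1, 2, 1.5), (3, 4, 3.5), (2, 2, 2.0)]
    )
    def test_segment_mean(self, j, k, expected):
        assert segment_mean(np.array([1.0, 2, 3, 4]), j, k) == expected

    def test_reversed_indices_raise(self):
        with pytest.raises(ContractError):
            segment_mean(np.array([1.0, 2, 3]), 3, 2)

    def test_partial_sum_hand_value(self):
        s = partial_sum_process(np.array([1.0, 2, 3, 4]), 1, 4)
        npt.assert_allclose(s, [-1.5, -2.0, -1.5, 0.0])

    def test_constant_segment_gives_zeros(self):
        npt.assert_allclose(partial_sum_process(np.array([3.0, 3, 3]), 1, 3), 0.0)

    @given(finite_arrays)
    @settings(max_examples=50, deadline=None)
    def test_terminal_partial_sum_is_zero(self, e):
        """The last centered partial sum of any segment vanishes: the sum of
        deviations from the segment mean is identically zero."""
        s = partial_sum_process(e, 1, len(e))
        assert abs(s[-1]) < 1e-8 * max(1.0, np.abs(e).sum())


class TestGn:
    def test_hand_evaluation(self):
        # segments (1,2) and (3,4): numerator 4*|1.5-3.5| = 8,
        # normalizer sqrt(0.5/4), hence 8 / 0.3535... = 22.6274...
        assert compute_Gn(np.array([1.0, 2, 3, 4]), 2) == pytest.approx(
            22.62741699796952, rel=1e-12
        )

    def test_zero_numerator(self):
        assert compute_Gn(np.array([1.0, -1, 1, -1]), 2) == 0.0

    def test_degenerate_normalizer_is_infinite(self):
        with pytest.warns(UserWarning, match="degenerate"):
            g = compute_Gn(np.array([1.0, 1, 2, 2]), 2)
        assert g == np.inf

    def test_k_out_of_range(self):
        with pytest.raises(ContractError):
            compute_Gn(np.array([1.0, 2, 3]), 3)


class TestProfile:
    def test_matches_literal_oracle_on_random_inputs(self):
        """The O(n) prefix-sum profile equals the literal per-k formula
        transcription, including on integer-valued residuals."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = int(rng.integers(14, 80))
            if trial % 2:
                e = rng.integers(-5, 6, size=n).astype(float)
            else:
                e = rng.standard_normal(n)
            prof = sn_profile(e)
            oracle = np.array([literal_gn(e, k) for k in prof.k_values])
            npt.assert_allclose(prof.gn_values, oracle, rtol=1e-8, atol=1e-10)

    @given(finite_arrays, st.floats(0.01, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, e, c):
        """G_n(c * eps, k) = G_n(eps, k) for every c > 0: numerator and
        normalizer scale identically."""
        a = sn_profile(e).gn_values
        b = sn_profile(c * e).gn_values
        npt.assert_allclose(a, b, rtol=1e-7, atol=1e-9)

    @given(finite_arrays, st.floats(-50.0, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_location_invariance(self, e, shift):
        """Adding a constant to every residual leaves the profile unchanged:
        both the mean difference and the centered sums kill the level."""
        a = sn_profile(e).gn_values
        b = sn_profile(e + shift).gn_values
        npt.assert_allclose(a, b, rtol=1e-6, atol=1e-8)

    @given(finite_arrays)
    @settings(max_examples=40, deadline=None)
    def test_nonnegative(self, e):
        assert np.all(sn_profile(e).gn_values >= 0.0)


class TestTn:
    def test_singleton_window(self, rng):
        e = rng.standard_normal(20)
        trim = TrimWindow(0.48, 0.52)
        res = compute_Tn(e, trim)
        assert res.k_hat == 10
        assert res.statistic == pytest.approx(compute_Gn(e, 10))

    def test_too_short_series_names_minimum(self):
        with pytest.raises(InvalidInputError, match="need n >="):
            compute_Tn(np.arange(3.0))

    def test_k_hat_is_first_argmax(self):
        # two segments of constants produce an infinite plateau; the
        # reported k_hat must be the smallest maximizer
        e = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(UserWarning):
            res = compute_Tn(e, TrimWindow(0.2, 0.8))
        assert res.statistic == np.inf
        assert res.k_hat == res.profile.k_values[np.isinf(res.profile.gn_values)][0]

    def test_statistic_is_profile_maximum(self, rng):
        res = compute_Tn(rng.standard_normal(100))
        assert res.statistic == res.profile.gn_values.max()
        assert res.k_hat == res.profile.k_values[np.argmax(res.profile.gn_values)]

    def test_locates_strong_mean_shift(self, rng):
        hits = 0
        for _ in range(100):
            e = rng.standard_normal(200)
            e[100:] += 3.0
            if abs(compute_Tn(e).k_hat - 100) <= 10:
                hits += 1
        assert hits >= 90


@pytest.fixture(scope="module")
def break_series():
    p = ARMAParams([0.3], [], 1.0)
    dgp = ChangePointDGP(order=ARMAOrder(1, 0), baseline=p, post_break=p,
                         break_fraction=0.5, mean_shift=2.0)
    return simulate_changepoint(dgp, 300, seed=42).values


class TestEndToEnd:
    def test_detects_break_and_locates_it(self, break_series):
        res = run_sn_test(break_series, ARMAOrder(1, 0),
                          calibration_reps=500, calibration_seed=1)
        assert res.reject is True
        assert res.p_value < 0.05
        assert abs(res.k_hat - 150) <= 20
        assert res.residual_source == "qmle"
        assert res.statistic == res.profile.gn_values.max()

    def test_deterministic_given_seeds(self, break_series):
        a = run_sn_test(break_series, ARMAOrder(1, 0),
                        calibration_reps=500, calibration_seed=1)
        b = run_sn_test(break_series, ARMAOrder(1, 0),
                        calibration_reps=500, calibration_seed=1)
        assert a.statistic == b.statistic
        assert a.critical_value == b.critical_value
        assert a.p_value == b.p_value
        assert a.k_hat == b.k_hat

    def test_no_calibration_leaves_decision_unset(self, break_series):
        res = run_sn_test(break_series, ARMAOrder(1, 0), calibration=None)
        assert res.reject is None and res.critical_value is None
        assert res.statistic > 0

    def test_result_serializes(self, break_series):
        res = run_sn_test(break_series, ARMAOrder(1, 0),
                          calibration_reps=500, calibration_seed=1)
        d = res.to_dict(include_profile=True)
        assert d["reject"] is True
        assert d["fit"]["converged"] is True
        assert len(d["profile"]["k"]) == len(res.profile.k_values)
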