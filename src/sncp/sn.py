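"""The self-normalized change-point statistic.

For residuals eps_1..eps_n, segment means and centered partial sums are

    mean(j, k)  = (k - j + 1)^{-1} sum_{t=j}^{k} eps_t,
    S_t(j, k)   = sum_{h=j}^{t} (eps_h - mean(j, k)),   t = j..k,

and for each candidate break index k the self-normalized statistic is

    G_n(k) = n * |mean(1, k) - mean(k+1, n)|
             / sqrt( n^{-1} * ( sum_{t<=k} S_t(1, k)^2
                              + sum_{t>k}  S_t(k+1, n)^2 ) ).

The test statistic is T_n = max G_n(k) over the trimmed candidate window
k in [ceil(n*tau1), floor(n*tau2)], and the change-point estimate k_hat is
the smallest maximizer.  The denominator is a data-driven functional of
within-segment partial sums, so no long-run variance estimate (and hence no
bandwidth choice) is needed: under the null both numerator and denominator
scale with the same long-run variance, which cancels.

Complexity: with prefix sums of the residual cumulative sums, every G_n(k)
costs O(1) after O(n) setup, so the whole profile is O(n).  The literal
per-k transcription (:func:`compute_Gn`) is retained both as the defining
formula and as the oracle the optimized path is tested against.

Indexing convention: all public indices (j, k, k_hat) are 1-based and
segments are inclusive on both ends; k_hat is the last index of the
pre-break segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .arma import ARMAOrder, FitResult, ResidualSeries
from .exceptions import ContractError, InvalidInputError

__all__ = [
    "TrimWindow",
    "SNProfile",
    "SNTestResult",
    "segment_mean",
    "partial_sum_process",
    "compute_Gn",
    "candidate_indices",
    "sn_profile",
    "compute_Tn",
    "run_sn_test",
]


@dataclass(frozen=True)
class TrimWindow:
    """Trimming fractions (tau1, tau2) restricting the candidate search to
    [n*tau1, n*tau2]; the defaults 0.15/0.85 keep at least 15% of the sample
    in each segment."""

    tau1: float = 0.15
    tau2: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 < self.tau1 < self.tau2 < 1.0:
            raise ContractError("require 0 < tau1 < tau2 < 1")


@dataclass(frozen=True)
class SNProfile:
    """G_n(k) evaluated on the trimmed candidate grid."""

    k_values: np.ndarray
    gn_values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.k_values) != len(self.gn_values):
            raise ContractError("profile arrays must have equal length")


@dataclass
class SNTestResult:
    """Everything a test run produces: the statistic, the estimated break
    index, the full profile, and (when calibrated) the critical value,
    p-value and decision."""

    statistic: float
    k_hat: int
    profile: SNProfile
    n: int
    trim: TrimWindow
    residual_source: str
    critical_value: Optional[float] = None
    p_value: Optional[float] = None
    alpha: Optional[float] = None
    reject: Optional[bool] = None
    fit: Optional[FitResult] = None

    def to_dict(self, include_profile: bool = False) -> dict:
        d = {
            "statistic": self.statistic,
            "k_hat": int(self.k_hat),
            "k_hat_fraction": self.k_hat / self.n,
            "n": self.n,
            "tau1": self.trim.tau1,
            "tau2": self.trim.tau2,
            "residual_source": self.residual_source,
            "critical_value": self.critical_value,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "reject": self.reject,
        }
        if self.fit is not None:
            d["fit"] = {
                "phi": self.fit.params.phi.tolist(),
                "theta": self.fit.params.theta.tolist(),
                "sigma2": self.fit.params.sigma2,
                "loglik": self.fit.loglik,
                "converged": self.fit.converged,
            }
        if include_profile:
            d["profile"] = {
                "k": self.profile.k_values.tolist(),
                "gn": self.profile.gn_values.tolist(),
            }
        return d


def _resid_values(resid) -> np.ndarray:
    if isinstance(resid, ResidualSeries):
        return resid.values
    return np.asarray(resid, dtype=float)


def segment_mean(resid, j: int, k: int) -> float:
    """Arithmetic mean of eps_j..eps_k (1-based, inclusive)."""
    e = _resid_values(resid)
    n = len(e)
    if not (1 <= j <= k <= n):
        raise ContractError(f"require 1 <= j <= k <= n, got j={j}, k={k}, n={n}")
    return float(np.mean(e[j - 1 : k]))


def partial_sum_process(resid, j: int, k: int) -> np.ndarray:
    """S_t(j, k) for t = j..k: cumulative sums of within-segment-centered
    residuals.  The final entry is zero to machine precision by
    construction."""
    e = _resid_values(resid)
    n = len(e)
    if not (1 <= j <= k <= n):
        raise ContractError(f"require 1 <= j <= k <= n, got j={j}, k={k}, n={n}")
    seg = e[j - 1 : k]
    return np.cumsum(seg - seg.mean())


def compute_Gn(resid, k: int) -> float:
    """Literal transcription of the defining formula for a single k.

    Degenerate-denominator convention: if the self-normalizer is exactly
    zero while the numerator is positive (both segments internally
    constant but with different levels), the statistic is +inf — perfect
    within-segment constancy is infinitely strong evidence; if numerator
    and denominator are both zero, G_n(k) = 0.
    """
    e = _resid_values(resid)
    n = len(e)
    if not (1 <= k < n):
        raise ContractError(f"require 1 <= k < n, got k={k}, n={n}")
    num = n * abs(segment_mean(e, 1, k) - segment_mean(e, k + 1, n))
    s1 = partial_sum_process(e, 1, k)
    s2 = partial_sum_process(e, k + 1, n)
    den = np.sqrt((np.sum(s1**2) + np.sum(s2**2)) / n)
    if den == 0.0:
        if num > 0.0:
            warnings.warn("degenerate self-normalizer: G_n(k) = +inf", stacklevel=2)
            return float("inf")
        return 0.0
    return float(num / den)


def candidate_indices(n: int, trim: TrimWindow = TrimWindow()) -> np.ndarray:
    """Trimmed candidate grid ceil(n*tau1)..floor(n*tau2), further restricted
    so each candidate leaves at least 2 observations per segment."""
    lo = max(int(np.ceil(n * trim.tau1)), 2)
    hi = min(int(np.floor(n * trim.tau2)), n - 2)
    if lo > hi:
        min_n = int(np.ceil(max(2.0 / trim.tau1, 2.0 / (1.0 - trim.tau2), 4.0)))
        raise InvalidInputError(
            f"series of length {n} too short for trimming "
            f"({trim.tau1}, {trim.tau2}); need n >= {min_n}"
        )
    return np.arange(lo, hi + 1)


def _gn_values(e: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Vectorized G_n(k) on the grid ``ks`` via prefix-sum algebra.

    With C_t = sum_{h<=t} eps_h, the left-segment sum of squares expands to
      sum_{t<=k} (C_t - (t/k) C_k)^2
        = P2_k - 2 (C_k / k) PT_k + (C_k / k)^2 Q_k,
    where P2, PT, Q are prefix sums of C_t^2, t*C_t and t^2; the right
    segment expands analogously with suffix sums.  Every term is O(1) per k.
    """
    n = len(e)
    C = np.cumsum(e)
    t = np.arange(1, n + 1, dtype=float)
    P2 = np.cumsum(C * C)
    PT = np.cumsum(t * C)
    PC = np.cumsum(C)
    Q = np.cumsum(t * t)

    kf = ks.astype(float)
    Ck = C[ks - 1]
    Cn = C[-1]
    m = n - kf

    left = P2[ks - 1] - 2.0 * (Ck / kf) * PT[ks - 1] + (Ck / kf) ** 2 * Q[ks - 1]

    # right segment: sum_{t>k} ((C_t - C_k) - ((t-k)/m) (C_n - C_k))^2
    b = (Cn - Ck) / m
    sC2 = P2[-1] - P2[ks - 1]
    sC = PC[-1] - PC[ks - 1]
    stC = PT[-1] - PT[ks - 1]
    sum_d2 = sC2 - 2.0 * Ck * sC + m * Ck**2
    sum_md = (stC - kf * sC) - Ck * m * (m + 1.0) / 2.0
    sum_m2 = m * (m + 1.0) * (2.0 * m + 1.0) / 6.0
    right = sum_d2 - 2.0 * b * sum_md + b * b * sum_m2

    ssq = np.clip(left + right, 0.0, None)  # guard tiny negative round-off
    num = n * np.abs(Ck / kf - (Cn - Ck) / m)
    den = np.sqrt(ssq / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        gn = np.where(den > 0.0, num / den, np.where(num > 0.0, np.inf, 0.0))
    if np.any(np.isinf(gn)):
        warnings.warn("degenerate self-normalizer: G_n(k) = +inf for some k",
                      stacklevel=2)
    return gn


def sn_profile(resid, trim: TrimWindow = TrimWindow()) -> SNProfile:
    """G_n(k) for every candidate k in the trimmed window (O(n) total)."""
    e = _resid_values(resid)
    ks = candidate_indices(len(e), trim)
    return SNProfile(k_values=ks, gn_values=_gn_values(e, ks))


def compute_Tn(resid, trim: TrimWindow = TrimWindow()) -> SNTestResult:
    """T_n = max_k G_n(k) and k_hat = smallest maximizer over the trimmed
    window; calibration fields are left unset."""
    e = _resid_values(resid)
    source = resid.source if isinstance(resid, ResidualSeries) else "user-supplied"
    profile = sn_profile(e, trim)
    i = int(np.argmax(profile.gn_values))  # argmax returns the first maximum
    return SNTestResult(
        statistic=float(profile.gn_values[i]),
        k_hat=int(profile.k_values[i]),
        profile=profile,
        n=len(e),
        trim=trim,
        residual_source=source,
    )


def run_sn_test(
    series,
    order: ARMAOrder,
    trim: TrimWindow = TrimWindow(),
    alpha: float = 0.05,
    calibration="auto",
    residual_backend: str = "qmle",
    fit_method: str = "css",
    calibration_reps: int = 10000,
    calibration_seed: int = 987654321,
    demean: bool = False,
    svr_config=None,
) -> SNTestResult:
    """End-to-end test: fit -> recursive residuals -> T_n, k_hat -> critical
    value and p-value -> decision.

    ``calibration`` may be a :class:`~sncp.calibration.NullSampleSet`, the
    string ``"auto"`` (finite-sample null Monte Carlo at this series' length,
    ``calibration_reps`` draws, i.i.d.-residual proxy), or ``None`` to skip
    calibration.  Everything is deterministic given the seeds.
    """
    from . import calibration as cal
    from .arma import compute_residuals, compute_residuals_svr, fit_arma_qmle

    y = np.asarray(series, dtype=float)
    if demean:
        y = y - y.mean()

    fit = None
    if residual_backend == "qmle":
        fit = fit_arma_qmle(y, order, method=fit_method)
        resid = compute_residuals(y, fit.params, order)
    elif residual_backend == "svr":
        resid = compute_residuals_svr(y, order, svr_config)
    else:
        raise InvalidInputError(f"unknown residual backend {residual_backend!r}")

    result = compute_Tn(resid, trim)
    result.fit = fit
    result.alpha = alpha

    if calibration is None:
        return result
    if isinstance(calibration, str) and calibration == "auto":
        nullset = cal.simulate_null_Tn(
            n=len(y), reps=calibration_reps, trim=trim, seed=calibration_seed
        )
    else:
        nullset = calibration
    result.critical_value = cal.critical_value(nullset, alpha)
    result.p_value = cal.p_value(result.statistic, nullset)
    result.reject = bool(result.statistic > result.critical_value)
    return result
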