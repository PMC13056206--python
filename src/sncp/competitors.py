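"""Benchmark residual-based CUSUM tests (a likelihood-score statistic and
a maximum-type statistic) used for size/power comparison.

Both statistics are built from the centered cumulative sums

    A(k) = sum_{t<=k} (y_t - eps_t) eps_t - (k/n) sum_{t<=n} (y_t - eps_t) eps_t,
    B(k) = sum_{t<=k} eps_t^2        - (k/n) sum_{t<=n} eps_t^2,

with variance estimators

    tau1_sq = n^{-1} sum (y_t - eps_t)^2 eps_t^2,
    tau2_sq = n^{-1} sum eps_t^4 - (n^{-1} sum eps_t^2)^2,

and are maximized over all k = 1..n (untrimmed):

    T_ls  = max_k { |A(k)|^2 / (n tau1_sq) + |B(k)|^2 / (n tau2_sq) },
    T_max = max_k max{ |A(k)| / (sqrt(n) tau1), |B(k)| / (sqrt(n) tau2) }.

The normalizations (n tau^2)^{-1} |.|^2 and (sqrt(n) tau)^{-1} |.| are the
only scalings under which both statistics are bounded in probability under
the null; A(n) = B(n) = 0 holds exactly by construction.

Critical values are self-calibrated by Monte Carlo under the same protocol
as the self-normalized test so that comparisons are internally fair.  Note
the competitors need a genuinely fitted model: if the residuals equal the
series (order (0, 0)), the fitted part y - eps is identically zero, tau1_sq
degenerates, and the statistics are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arma import ARMAOrder, ARMAParams, ResidualSeries, compute_residuals, fit_arma_qmle
from .calibration import NullSampleSet
from .exceptions import ContractError, DegenerateInputError, InvalidInputError
from .sn import TrimWindow

__all__ = [
    "CompetitorResult",
    "variance_estimators",
    "compute_T_ls",
    "compute_T_max",
    "competitor_statistics",
    "calibrate_competitor",
]


@dataclass(frozen=True)
class CompetitorResult:
    t_ls: float
    t_max: float
    tau1_sq: float
    tau2_sq: float
    k_at_max_ls: int
    k_at_max_max: int


def _values(resid) -> np.ndarray:
    if isinstance(resid, ResidualSeries):
        return resid.values
    return np.asarray(resid, dtype=float)


def variance_estimators(series, resid) -> tuple[float, float]:
    """(tau1_sq, tau2_sq) as defined above."""
    y = np.asarray(series, dtype=float)
    e = _values(resid)
    if len(y) != len(e):
        raise ContractError("series and residuals must have equal length")
    n = len(y)
    fitted = y - e
    tau1_sq = float(np.sum(fitted**2 * e**2) / n)
    tau2_sq = float(np.mean(e**4) - np.mean(e**2) ** 2)
    return tau1_sq, max(tau2_sq, 0.0)


def _cusum_terms(y: np.ndarray, e: np.ndarray):
    n = len(y)
    c = (y - e) * e
    d = e * e
    k = np.arange(1, n + 1)
    A = np.cumsum(c) - k / n * np.sum(c)
    B = np.cumsum(d) - k / n * np.sum(d)
    return A, B


def competitor_statistics(series, resid) -> CompetitorResult:
    """Both benchmark statistics in one pass (they share A, B, tau's)."""
    y = np.asarray(series, dtype=float)
    e = _values(resid)
    tau1_sq, tau2_sq = variance_estimators(y, e)
    if tau1_sq <= 0.0 or tau2_sq <= 0.0:
        raise DegenerateInputError(
            f"degenerate variance estimators (tau1_sq={tau1_sq}, "
            f"tau2_sq={tau2_sq}); the statistics are undefined"
        )
    n = len(y)
    A, B = _cusum_terms(y, e)
    ls = A**2 / (n * tau1_sq) + B**2 / (n * tau2_sq)
    mx = np.maximum(np.abs(A) / (np.sqrt(n) * np.sqrt(tau1_sq)),
                    np.abs(B) / (np.sqrt(n) * np.sqrt(tau2_sq)))
    i_ls = int(np.argmax(ls))
    i_mx = int(np.argmax(mx))
    return CompetitorResult(
        t_ls=float(ls[i_ls]),
        t_max=float(mx[i_mx]),
        tau1_sq=tau1_sq,
        tau2_sq=tau2_sq,
        k_at_max_ls=i_ls + 1,
        k_at_max_max=i_mx + 1,
    )


def compute_T_ls(series, resid) -> float:
    return competitor_statistics(series, resid).t_ls


def compute_T_max(series, resid) -> float:
    return competitor_statistics(series, resid).t_max


def calibrate_competitor(
    statistic_id: str,
    n: int,
    reps: int,
    seed: int,
    order: ARMAOrder,
    params: ARMAParams,
    fit_method: str = "css",
) -> NullSampleSet:
    """Null Monte Carlo for a competitor statistic.

    Simulates stationary ARMA paths under ``params``, refits the stated
    order, extracts recursive residuals and evaluates the statistic.  A
    fitted model is required (see module docstring), so unlike the
    self-normalized calibration there is no residual-proxy shortcut.
    """
    if statistic_id not in ("ls", "max"):
        raise InvalidInputError("statistic_id must be 'ls' or 'max'")
    if reps < 100:
        raise InvalidInputError("reps must be at least 100")
    if order.p == 0 and order.q == 0:
        raise DegenerateInputError(
            "competitor statistics are undefined for order (0, 0): "
            "y - eps is identically zero"
        )
    from .dgp import simulate_arma

    rng = np.random.default_rng(seed)
    samples = np.empty(reps)
    for r in range(reps):
        y = simulate_arma(params, order, n=n, seed=rng)
        fit = fit_arma_qmle(y, order, method=fit_method)
        e = compute_residuals(y, fit.params, order)
        res = competitor_statistics(y, e)
        samples[r] = res.t_ls if statistic_id == "ls" else res.t_max
    return NullSampleSet(samples, "finite_sample", n, reps, TrimWindow(),
                         seed, statistic_id)
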