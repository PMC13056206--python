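"""ARMA(p, q) fitting by Gaussian quasi-maximum likelihood and the recursive
residuals the change-point statistics are defined on.

The model is the zero-mean stationary ARMA(p, q)

    y_t = sum_i phi_i y_{t-i} + eps_t + sum_j theta_j eps_{t-j},

with i.i.d. mean-zero innovations of variance sigma^2.  Residuals are always
computed by the *conditional* forward recursion

    eps_hat_t = y_t - sum_i phi_i y_{t-i} - sum_j theta_j eps_hat_{t-j},

with pre-sample values y_t = eps_hat_t = 0 for t <= 0.  No backcasting or
Kalman smoothing is applied to the residual pass: the self-normalized test
statistic is defined on exactly these recursively computed residuals.

Two estimation backends share one surface:

``method="css"`` (default)
    Gaussian QMLE via conditional sum of squares — minimizes the sum of the
    squared recursion residuals above.  Pure AR orders reduce to a
    closed-form least-squares solve on a zero-padded lag matrix; orders with
    an MA part are minimized numerically (Nelder–Mead) with a stationarity/
    invertibility barrier.

``method="exact"``
    Exact Gaussian MLE through ``statsmodels`` ARIMA (state-space), kept as
    an independent route; its parameter estimates feed the same conditional
    residual recursion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .exceptions import ContractError, InvalidInputError

__all__ = [
    "ARMAOrder",
    "ARMAParams",
    "FitResult",
    "ResidualSeries",
    "SVRConfig",
    "fit_arma_qmle",
    "compute_residuals",
    "compute_residuals_svr",
]


@dataclass(frozen=True)
class ARMAOrder:
    """AR and MA orders (p, q); p = q = 0 means pure noise."""

    p: int
    q: int

    def __post_init__(self) -> None:
        if int(self.p) != self.p or int(self.q) != self.q:
            raise ContractError("ARMA orders must be integers")
        if self.p < 0 or self.q < 0:
            raise ContractError("ARMA orders must be non-negative")
        object.__setattr__(self, "p", int(self.p))
        object.__setattr__(self, "q", int(self.q))

    @property
    def n_params(self) -> int:
        return self.p + self.q + 1  # + innovation variance


def _roots_outside_unit_circle(coefs: np.ndarray) -> bool:
    """True iff all roots of 1 + c_1 z + ... + c_m z^m lie strictly outside
    the unit circle (vacuously true for an empty/zero coefficient vector)."""
    coefs = np.asarray(coefs, dtype=float)
    if coefs.size == 0 or not np.any(coefs):
        return True
    poly = np.concatenate([coefs[::-1], [1.0]])  # highest degree first
    roots = np.roots(poly)
    if roots.size == 0:
        return True
    return bool(np.min(np.abs(roots)) > 1.0)


@dataclass(frozen=True)
class ARMAParams:
    """Parameter vector (phi_1..phi_p, theta_1..theta_q, sigma^2).

    Stationarity and invertibility are *checkable*, not silently enforced:
    use :meth:`is_stationary` / :meth:`is_invertible`.
    """

    phi: np.ndarray
    theta: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.phi is None or np.size(self.phi) == 0:
            phi = np.empty(0)
        if self.theta is None or np.size(self.theta) == 0:
            theta = np.empty(0)
        if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(theta))):
            raise InvalidInputError("ARMA coefficients must be finite")
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise InvalidInputError("sigma2 must be a positive real")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "sigma2", float(self.sigma2))

    @property
    def order(self) -> ARMAOrder:
        return ARMAOrder(len(self.phi), len(self.theta))

    def is_stationary(self) -> bool:
        """All roots of the AR polynomial 1 - sum phi_i z^i outside |z|=1."""
        return _roots_outside_unit_circle(-self.phi)

    def is_invertible(self) -> bool:
        """All roots of the MA polynomial 1 + sum theta_j z^j outside |z|=1."""
        return _roots_outside_unit_circle(self.theta)

    def replace(self, **kwargs) -> "ARMAParams":
        d = {"phi": self.phi, "theta": self.theta, "sigma2": self.sigma2}
        d.update(kwargs)
        return ARMAParams(**d)


@dataclass(frozen=True)
class FitResult:
    params: ARMAParams
    order: ARMAOrder
    loglik: float
    converged: bool
    n_used: int


@dataclass(frozen=True)
class ResidualSeries:
    """Estimated residuals eps_hat_1..eps_hat_n with a provenance tag."""

    values: np.ndarray
    source: str = "qmle"  # qmle | svr | user-supplied

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidInputError("residuals must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("residuals must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def _as_series(series: Sequence[float]) -> np.ndarray:
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise InvalidInputError("series must be one-dimensional")
    if y.size == 0:
        raise InvalidInputError("series is empty")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("series contains non-finite values")
    return y


def compute_residuals(
    series: Sequence[float],
    params: ARMAParams,
    order: ARMAOrder | None = None,
    source: str = "qmle",
) -> ResidualSeries:
    """Conditional recursion residuals with zero pre-sample values.

    Implemented as a linear filter: the recursion is exactly
    ``eps = lfilter([1, -phi_1..-phi_p], [1, theta_1..theta_q], y)`` with a
    zero initial filter state, so the whole pass is a single C-loop.
    """
    y = _as_series(series)
    if order is None:
        order = params.order
    if len(params.phi) != order.p or len(params.theta) != order.q:
        raise ContractError(
            f"params dimensioned ({len(params.phi)},{len(params.theta)}) "
            f"inconsistent with order ({order.p},{order.q})"
        )
    if order.p == 0 and order.q == 0:
        return ResidualSeries(y.copy(), source=source)
    b = np.concatenate([[1.0], -params.phi])
    a = np.concatenate([[1.0], params.theta])
    eps = signal.lfilter(b, a, y)
    return ResidualSeries(eps, source=source)


def reconstruct_series(resid: ResidualSeries, params: ARMAParams) -> np.ndarray:
    """Invert :func:`compute_residuals` (used by the identity tests)."""
    b = np.concatenate([[1.0], -params.phi])
    a = np.concatenate([[1.0], params.theta])
    return signal.lfilter(a, b, resid.values)


def _css_objective(y: np.ndarray, order: ARMAOrder):
    p, q = order.p, order.q

    def objective(x: np.ndarray) -> float:
        phi, theta = x[:p], x[p:]
        # barrier keeps the optimizer inside the stationary/invertible region
        if not (_roots_outside_unit_circle(-phi) and _roots_outside_unit_circle(theta)):
            return 1e12 * (1.0 + float(np.sum(x**2)))
        b = np.concatenate([[1.0], -phi])
        a = np.concatenate([[1.0], theta])
        eps = signal.lfilter(b, a, y)
        return float(np.dot(eps, eps))

    return objective


def _fit_pure_ar(y: np.ndarray, p: int) -> np.ndarray:
    """Closed-form CSS for AR(p): least squares on the zero-padded lag
    matrix, which minimizes the sum of squared recursion residuals."""
    n = len(y)
    X = np.zeros((n, p))
    for i in range(1, p + 1):
        X[i:, i - 1] = y[:-i]
    phi, *_ = np.linalg.lstsq(X, y, rcond=None)
    return phi


def _gaussian_loglik(ssr: float, n: int) -> float:
    sigma2 = max(ssr / n, np.finfo(float).tiny)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def fit_arma_qmle(
    series: Sequence[float],
    order: ARMAOrder,
    method: str = "css",
) -> FitResult:
    """Fit a zero-mean ARMA(p, q) model by Gaussian quasi-maximum likelihood.

    Parameters
    ----------
    series : array-like
        Observed series, time-ordered.
    order : ARMAOrder
        (p, q) to fit.  ``(0, 0)`` degenerates to a variance estimate.
    method : {"css", "exact"}
        Estimation backend; see module docstring.

    Returns
    -------
    FitResult
        Estimates, conditional Gaussian log-likelihood, and a ``converged``
        flag that is recorded, never assumed.
    """
    y = _as_series(series)
    n = len(y)
    if n < 10 * order.n_params:
        raise InvalidInputError(
            f"series length {n} < 10*(p+q+1) = {10 * order.n_params} "
            f"required for a stable ARMA({order.p},{order.q}) fit"
        )

    if order.p == 0 and order.q == 0:
        sigma2 = float(np.var(y, ddof=1))
        if sigma2 <= 0:
            raise InvalidInputError("constant series: variance is zero")
        params = ARMAParams(np.empty(0), np.empty(0), sigma2)
        return FitResult(params, order, _gaussian_loglik(sigma2 * n, n), True, n)

    if method == "exact":
        return _fit_exact(y, order)
    if method != "css":
        raise InvalidInputError(f"unknown fit method {method!r}")

    if order.q == 0:
        phi = _fit_pure_ar(y, order.p)
        theta = np.empty(0)
        converged = True
    else:
        obj = _css_objective(y, order)
        starts = [np.zeros(order.p + order.q)]
        ar_start = np.zeros(order.p + order.q)
        if order.p > 0:
            ar_start[: order.p] = np.clip(_fit_pure_ar(y, order.p), -0.95, 0.95)
        starts.append(ar_start)
        best = None
        for x0 in starts:
            res = optimize.minimize(
                obj,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        phi, theta = best.x[: order.p], best.x[order.p :]
        converged = bool(best.success) and best.fun < 1e11

    b = np.concatenate([[1.0], -np.atleast_1d(phi)]) if order.p else np.array([1.0])
    a = np.concatenate([[1.0], np.atleast_1d(theta)]) if order.q else np.array([1.0])
    eps = signal.lfilter(b, a, y)
    ssr = float(np.dot(eps, eps))
    sigma2 = max(ssr / n, np.finfo(float).tiny)
    params = ARMAParams(np.atleast_1d(phi), np.atleast_1d(theta), sigma2)
    if not (params.is_stationary() and params.is_invertible()):
        warnings.warn("fitted ARMA parameters are on or outside the "
                      "stationarity/invertibility boundary", stacklevel=2)
    return FitResult(params, order, _gaussian_loglik(ssr, n), converged, n)


def _fit_exact(y: np.ndarray, order: ARMAOrder) -> FitResult:
    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(y, order=(order.p, 0, order.q), trend="n")
        res = model.fit()
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    sigma2 = float(res.params[-1])
    params = ARMAParams(
        np.asarray(res.arparams, dtype=float),
        np.asarray(res.maparams, dtype=float),
        max(sigma2, np.finfo(float).tiny),
    )
    return FitResult(params, order, float(res.llf), converged, len(y))


# ---------------------------------------------------------------------------
# Experimental SVR residual backend
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SVRConfig:
    """Support-vector-regression settings for the experimental residual
    backend.  Penalty and epsilon are chosen from a small fixed grid by
    rolling-origin validation (train on the first ``1 - validation_fraction``
    of the sample, score one-step errors on the rest, refit on everything)."""

    kernel: str = "rbf"
    c_grid: tuple = (1.0, 10.0, 100.0)
    epsilon_grid: tuple = (0.01, 0.1)
    gamma: str | float = "scale"
    validation_fraction: float = 0.3


def _lag_matrix(values: np.ndarray, lags: int) -> np.ndarray:
    """Zero-padded lag matrix, consistent with the zero pre-sample
    convention of the parametric recursion."""
    n = len(values)
    X = np.zeros((n, lags))
    for i in range(1, lags + 1):
        X[i:, i - 1] = values[:-i]
    return X


def _fit_svr(X: np.ndarray, y: np.ndarray, config: SVRConfig):
    from sklearn.svm import SVR

    n = len(y)
    split = max(int(n * (1.0 - config.validation_fraction)), 2)
    best_key, best_score = None, np.inf
    for C in config.c_grid:
        for eps in config.epsilon_grid:
            m = SVR(kernel=config.kernel, C=C, epsilon=eps, gamma=config.gamma)
            m.fit(X[:split], y[:split])
            score = float(np.mean((y[split:] - m.predict(X[split:])) ** 2))
            if score < best_score:
                best_key, best_score = (C, eps), score
    C, eps = best_key
    final = SVR(kernel=config.kernel, C=C, epsilon=eps, gamma=config.gamma)
    final.fit(X, y)
    return final


def compute_residuals_svr(
    series: Sequence[float],
    order: ARMAOrder,
    svr_config: SVRConfig | None = None,
) -> ResidualSeries:
    """One-step-ahead SVR residuals (experimental backend).

    Regresses y_t on its p lags; when q > 0 the MA structure is approximated
    by a second pass that adds q lags of the first-pass residuals to the
    regressors.  For order (0, 0) the convention is pinned to eps_hat = y
    exactly, matching the parametric backend.
    """
    y = _as_series(series)
    config = svr_config or SVRConfig()
    if order.p == 0 and order.q == 0:
        return ResidualSeries(y.copy(), source="svr")
    if len(y) < order.p + order.q + 10:
        raise InvalidInputError(
            f"series length {len(y)} too short to build {order.p} lagged "
            f"regressors (+{order.q} residual lags) for the SVR backend"
        )
    lags = max(order.p, 1)
    X = _lag_matrix(y, lags)
    model = _fit_svr(X, y, config)
    resid = y - model.predict(X)
    if order.q > 0:
        X2 = np.hstack([X, _lag_matrix(resid, order.q)])
        model = _fit_svr(X2, y, config)
        resid = y - model.predict(X2)
    return ResidualSeries(resid, source="svr")
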