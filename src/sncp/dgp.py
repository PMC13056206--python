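"""Seeded synthetic generators: stationary ARMA paths and ARMA paths with a
single structural break.

The break mechanics mirror the simulation designs of the size/power study:
observations up to the break index k* are generated under the baseline
parameter vector, observations after it under the post-break vector, with the
ARMA recursion *continuing across the break* (the last p observations and q
innovations carry over — no state reset).  An optional mean shift mu is added
to the observations after the break.  A burn-in prefix is generated and
discarded so the retained pre-break path is approximately stationary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .arma import ARMAOrder, ARMAParams
from .exceptions import ContractError, InvalidInputError

__all__ = [
    "ChangePointDGP",
    "SimulatedSeries",
    "simulate_arma",
    "simulate_changepoint",
]

_INNOVATION_DISTS = ("normal", "t", "uniform")


def _draw_innovations(rng: np.random.Generator, size: int, dist: str, t_df: float) -> np.ndarray:
    """Unit-variance i.i.d. innovations; sigma2 always means the variance."""
    if dist == "normal":
        return rng.standard_normal(size)
    if dist == "t":
        if t_df <= 2:
            raise InvalidInputError("t innovations need df > 2 for finite variance")
        return rng.standard_t(t_df, size) / np.sqrt(t_df / (t_df - 2.0))
    if dist == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size)
    raise InvalidInputError(f"unknown innovation distribution {dist!r}")


@dataclass(frozen=True)
class ChangePointDGP:
    """Specification of an ARMA data-generating process with at most one
    structural break.

    ``break_fraction=None`` means null-hypothesis data: the post-break
    parameters must then equal the baseline (or be omitted) and
    ``mean_shift`` must be zero.  ``shift_innovations=True`` switches to the
    alternate reading in which the mean shift is added to the innovations
    rather than the observations.
    """

    order: ARMAOrder
    baseline: ARMAParams
    post_break: Optional[ARMAParams] = None
    break_fraction: Optional[float] = None
    mean_shift: float = 0.0
    innovation_dist: str = "normal"
    t_df: float = 5.0
    burn_in: int = 200
    shift_innovations: bool = False

    def __post_init__(self) -> None:
        if self.innovation_dist not in _INNOVATION_DISTS:
            raise InvalidInputError(
                f"innovation_dist must be one of {_INNOVATION_DISTS}"
            )
        if self.burn_in < 0:
            raise ContractError("burn_in must be non-negative")
        for params in (self.baseline, self.post_break):
            if params is not None and params.order != self.order:
                raise ContractError("parameter dimensions inconsistent with order")
        if self.break_fraction is None:
            if self.mean_shift != 0.0:
                raise ContractError("mean_shift requires a break_fraction")
            if self.post_break is not None and not self._post_equals_baseline():
                raise ContractError(
                    "null DGP (break_fraction=None) must have post_break == baseline"
                )
        else:
            if not 0.0 < self.break_fraction < 1.0:
                raise ContractError("break_fraction must lie in (0, 1)")

    def _post_equals_baseline(self) -> bool:
        b, a = self.baseline, self.post_break
        return (
            np.array_equal(b.phi, a.phi)
            and np.array_equal(b.theta, a.theta)
            and b.sigma2 == a.sigma2
        )

    @property
    def effective_post(self) -> ARMAParams:
        return self.post_break if self.post_break is not None else self.baseline

    def to_dict(self) -> dict:
        return {
            "order": [self.order.p, self.order.q],
            "baseline": {
                "phi": self.baseline.phi.tolist(),
                "theta": self.baseline.theta.tolist(),
                "sigma2": self.baseline.sigma2,
            },
            "post_break": {
                "phi": self.effective_post.phi.tolist(),
                "theta": self.effective_post.theta.tolist(),
                "sigma2": self.effective_post.sigma2,
            },
            "break_fraction": self.break_fraction,
            "mean_shift": self.mean_shift,
            "innovation_dist": self.innovation_dist,
            "burn_in": self.burn_in,
            "shift_innovations": self.shift_innovations,
        }


@dataclass(frozen=True)
class SimulatedSeries:
    """A simulated path plus full provenance.  ``true_break_index`` is the
    1-based index of the last pre-break observation, floor(n * fraction)."""

    values: np.ndarray
    true_break_index: Optional[int]
    seed: int
    dgp: ChangePointDGP


def _recurse(
    order: ARMAOrder,
    pre: ARMAParams,
    post: ARMAParams,
    k_break: int,
    n: int,
    burn_in: int,
    rng: np.random.Generator,
    dist: str,
    t_df: float,
    innovation_shift: float,
) -> np.ndarray:
    """Run the ARMA recursion for burn_in + n steps, switching parameters
    after observation k_break of the retained sample (state carries over)."""
    p, q = order.p, order.q
    total = burn_in + n
    z = _draw_innovations(rng, total, dist, t_df)
    y = np.zeros(total)
    e = np.zeros(total)
    switch = burn_in + k_break  # first index generated under `post`
    sig_pre = np.sqrt(pre.sigma2)
    sig_post = np.sqrt(post.sigma2)
    for t in range(total):
        after = t >= switch
        par = post if after else pre
        et = (sig_post if after else sig_pre) * z[t]
        if after and innovation_shift:
            et += innovation_shift
        acc = et
        for i in range(1, min(p, t) + 1):
            acc += par.phi[i - 1] * y[t - i]
        for j in range(1, min(q, t) + 1):
            acc += par.theta[j - 1] * e[t - j]
        e[t] = et
        y[t] = acc
    return y[burn_in:]


def simulate_arma(
    params: ARMAParams,
    order: ARMAOrder | None = None,
    n: int = 100,
    seed: int | np.random.Generator = 0,
    burn_in: int = 200,
    innovation_dist: str = "normal",
    t_df: float = 5.0,
) -> np.ndarray:
    """Simulate n observations of a stationary ARMA(p, q) path.

    Seeded and reproducible: the same (params, n, seed, burn_in) always
    yields the same vector.  Non-stationary parameters are warned about,
    not rejected.
    """
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    if order is None:
        order = params.order
    if not (params.is_stationary() and params.is_invertible()):
        import warnings

        warnings.warn("simulating with non-stationary or non-invertible "
                      "parameters; burn-in will not stabilize the path",
                      stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _recurse(order, params, params, n, n, burn_in, rng,
                    innovation_dist, t_df, 0.0)


def simulate_changepoint(
    dgp: ChangePointDGP,
    n: int,
    seed: int | np.random.Generator = 0,
) -> SimulatedSeries:
    """Simulate a path from ``dgp``: observations 1..k* under the baseline
    parameters, k*+1..n under the post-break parameters (recursion state
    carried across), with the mean shift added to post-break observations
    (or innovations when ``dgp.shift_innovations``)."""
    if n < 20:
        raise InvalidInputError("n must be at least 20")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_label = seed if isinstance(seed, int) else -1
    if dgp.break_fraction is None:
        k = None
        y = _recurse(dgp.order, dgp.baseline, dgp.baseline, n, n, dgp.burn_in,
                     rng, dgp.innovation_dist, dgp.t_df, 0.0)
    else:
        k = int(np.floor(n * dgp.break_fraction))
        if not 0 < k < n:
            raise ContractError("break_fraction leaves an empty segment")
        shift = dgp.mean_shift if dgp.shift_innovations else 0.0
        y = _recurse(dgp.order, dgp.baseline, dgp.effective_post, k, n,
                     dgp.burn_in, rng, dgp.innovation_dist, dgp.t_df, shift)
        if not dgp.shift_innovations and dgp.mean_shift:
            y = y.copy()
            y[k:] += dgp.mean_shift
    return SimulatedSeries(values=y, true_break_index=k, seed=seed_label, dgp=dgp)
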