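"""Monte Carlo calibration: null distributions, critical values, p-values.

Two routes produce null samples of the trimmed-supremum statistic:

finite-sample (default)
    Simulate i.i.d. standard-normal series of the user's length n and
    compute T_n on each, optionally passing each draw through the fit +
    residual-extraction pipeline first (``refit=True``).  Under the null the
    estimated residuals are asymptotically i.i.d., so the i.i.d. proxy is
    the faithful default and the refit route is a robustness check.

limit-functional
    Simulate the limiting law directly: with independent Brownian bridges
    B, B1, B2 on [0, 1],

        sup_{s in [tau1, tau2]}  |B(s)| / { s(1-s) *
            sqrt( int_0^s [B1(u) - (u/s) B1(s)]^2 du
                + int_s^1 [B2(u) - B2(s)]^2 du ) },

    on a uniform path grid with left-Riemann integrals.  Bridges are built
    as B(s) = W(s) - s W(1) from scaled random walks.

Critical values are empirical quantiles with the conservative ceiling
order-statistic convention; p-values use the add-one permutation rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .arma import ARMAOrder, ARMAParams, compute_residuals, fit_arma_qmle
from .exceptions import ContractError, InvalidInputError
from .sn import TrimWindow, _gn_values, candidate_indices

__all__ = [
    "NullSampleSet",
    "simulate_null_Tn",
    "simulate_limit_functional",
    "critical_value",
    "p_value",
    "save_critical_value_table",
    "load_critical_value_table",
    "lookup_critical_value",
    "bundled_critical_values",
]


@dataclass(frozen=True)
class NullSampleSet:
    """Monte Carlo draws of a statistic's null distribution with full
    provenance (method, size, replication count, trimming, seed)."""

    samples: np.ndarray
    method: str  # finite_sample | limit_functional
    n_or_grid: int
    reps: int
    trim: TrimWindow
    seed: int
    statistic_id: str = "sn"

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if len(s) != self.reps:
            raise ContractError("reps must equal the number of samples")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ContractError("null samples must be finite and non-negative")
        object.__setattr__(self, "samples", s)

    def save(self, path) -> None:
        payload = {
            "method": self.method,
            "n_or_grid": self.n_or_grid,
            "reps": self.reps,
            "tau1": self.trim.tau1,
            "tau2": self.trim.tau2,
            "seed": self.seed,
            "statistic_id": self.statistic_id,
            "samples": self.samples.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "NullSampleSet":
        d = json.loads(Path(path).read_text())
        return cls(
            samples=np.asarray(d["samples"], dtype=float),
            method=d["method"],
            n_or_grid=int(d["n_or_grid"]),
            reps=int(d["reps"]),
            trim=TrimWindow(d["tau1"], d["tau2"]),
            seed=int(d["seed"]),
            statistic_id=d.get("statistic_id", "sn"),
        )


def simulate_null_Tn(
    n: int,
    reps: int,
    trim: TrimWindow = TrimWindow(),
    seed: int = 0,
    order: ARMAOrder = ARMAOrder(0, 0),
    params: Optional[ARMAParams] = None,
    refit: bool = False,
    fit_method: str = "css",
) -> NullSampleSet:
    """Finite-sample null Monte Carlo of the trimmed-supremum statistic.

    Each replicate draws an i.i.d. standard-normal series (or, when
    ``params`` is given, a stationary ARMA path under those parameters);
    with ``refit=True`` the series is passed through fit + residual
    extraction, otherwise it is used directly as the residual vector.
    """
    if reps < 100:
        raise InvalidInputError("reps must be at least 100")
    ks = candidate_indices(n, trim)  # validates n against the trimming
    rng = np.random.default_rng(seed)
    samples = np.empty(reps)
    for r in range(reps):
        if params is not None:
            from .dgp import simulate_arma

            y = simulate_arma(params, order, n=n, seed=rng)
        else:
            y = rng.standard_normal(n)
        if refit:
            fit = fit_arma_qmle(y, order, method=fit_method)
            e = compute_residuals(y, fit.params, order).values
        else:
            e = y
        samples[r] = np.max(_gn_values(e, ks))
    return NullSampleSet(samples, "finite_sample", n, reps, trim,
                         seed if isinstance(seed, int) else -1, "sn")


def simulate_limit_functional(
    grid: int = 1000,
    reps: int = 50000,
    trim: TrimWindow = TrimWindow(),
    seed: int = 0,
    bridge: str = "joint",
    chunk: int = 256,
) -> NullSampleSet:
    """Direct simulation of the Brownian-bridge limiting functional.

    Paths live on the uniform grid u_i = i/grid; integrals are left Riemann
    sums; the supremum runs over grid points with tau1 <= s <= tau2.
    Replicates are processed in chunks and fully vectorized within a chunk.

    ``bridge`` selects the dependence structure of the three limit
    processes:

    ``"joint"`` (default)
        All three are functionals of a single underlying Brownian motion W,
        exactly as they arise as limits of the finite-sample statistic:
        numerator bridge B(s) = W(s) - s W(1), first-segment process
        W(u) - (u/s) W(s), second-segment process
        W(u) - W(s) - ((u-s)/(1-s)) (W(1) - W(s)).  This is the law the
        finite-sample null distribution actually converges to.

    ``"independent"``
        B, B1, B2 drawn as three independent bridges, with segment
        processes B1(u) - (u/s) B1(s) and B2(u) - B2(s).  This is the
        asymptotic form as usually stated; treating the numerator as
        independent of the denominator is an approximation and its 95%
        quantile sits a few percent below the joint law's.
    """
    if grid < 200:
        raise InvalidInputError("grid must be at least 200")
    if reps < 100:
        raise InvalidInputError("reps must be at least 100")
    if bridge not in ("joint", "independent"):
        raise InvalidInputError("bridge must be 'joint' or 'independent'")
    rng = np.random.default_rng(seed)
    u = np.arange(1, grid + 1) / grid
    j_lo = max(int(np.ceil(grid * trim.tau1)), 2)
    j_hi = min(int(np.floor(grid * trim.tau2)), grid - 2)
    js = np.arange(j_lo, j_hi + 1)  # s = u[js - 1]
    s = u[js - 1]
    out = np.empty(reps)
    done = 0
    step = 1.0 / grid
    QU = np.cumsum(u * u)
    while done < reps:
        m = min(chunk, reps - done)
        n_paths = 1 if bridge == "joint" else 3
        W = np.cumsum(rng.standard_normal((n_paths, m, grid)) * np.sqrt(step),
                      axis=-1)
        Bs = W - u[None, None, :] * W[..., -1:]
        if bridge == "joint":
            B = B1 = Bs[0]
            W2 = W[0]
        else:
            B, B1 = Bs[0], Bs[1]
            W2 = Bs[2]  # second-segment process built from bridge B2

        # I1(s) = int_0^s [B1(u) - (u/s) B1(s)]^2 du, left Riemann: grid
        # points strictly below s (the u=0 term vanishes).  Note
        # B1(u) - (u/s) B1(s) = W(u) - (u/s) W(s), so the same expansion
        # serves both constructions.
        P2 = np.cumsum(B1 * B1, axis=-1)
        PU = np.cumsum(u * B1, axis=-1)
        B1s = B1[:, js - 1]
        I1 = (P2[:, js - 2] - 2.0 * (B1s / s) * PU[:, js - 2]
              + (B1s / s) ** 2 * QU[js - 2]) * step

        # I2(s): second-segment integral over [s, 1], left endpoints
        # u_j..u_{grid-1}; the u_j (= s) term is 0 in both constructions.
        if bridge == "joint":
            # V(u) = W(u) - W(s) - ((u-s)/(1-s)) (W(1) - W(s))
            #      = W(u) - A - c u,  c = (W(1)-W(s))/(1-s), A = W(s) - s c;
            # V(1) = 0 exactly, so suffix sums from u_j cover u_j..u_{grid-1}
            # up to that vanishing last term, which is removed explicitly.
            Wn = W2[:, -1:]
            Ws = W2[:, js - 1]
            c = (Wn - Ws) / (1.0 - s)
            A = Ws - s * c
            S2 = np.cumsum((W2 * W2)[:, ::-1], axis=-1)[:, ::-1]
            S1 = np.cumsum(W2[:, ::-1], axis=-1)[:, ::-1]
            SU = np.cumsum((u * W2)[:, ::-1], axis=-1)[:, ::-1]
            cnt = grid - js
            # suffix sums of u and u^2 over u_j..u_{grid-1}
            su = (np.cumsum(u[::-1])[::-1][js - 1] - u[-1])
            su2 = (QU[-1] - QU[js - 2]) - u[-1] ** 2
            sW2 = S2[:, js - 1] - W2[:, -1:] ** 2
            sW = S1[:, js - 1] - W2[:, -1:]
            sUW = SU[:, js - 1] - u[-1] * W2[:, -1:]
            I2 = (sW2 - 2.0 * A * sW - 2.0 * c * sUW
                  + 2.0 * A * c * su + cnt * A**2 + c**2 * su2) * step
        else:
            # [B2(u) - B2(s)]^2; B2(1) = 0 exactly, so suffix sums from u_j
            # already equal the sums over u_j..u_{grid-1}.
            S2 = np.cumsum((W2 * W2)[:, ::-1], axis=-1)[:, ::-1]
            S1 = np.cumsum(W2[:, ::-1], axis=-1)[:, ::-1]
            B2s = W2[:, js - 1]
            cnt = grid - js
            I2 = (S2[:, js - 1] - 2.0 * B2s * S1[:, js - 1] + cnt * B2s**2) * step

        den = s * (1.0 - s) * np.sqrt(np.clip(I1 + I2, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.abs(B[:, js - 1]) / den
        out[done : done + m] = np.nanmax(F, axis=-1)
        done += m
    method = "limit_functional" if bridge == "joint" else "limit_functional_indep"
    return NullSampleSet(out, method, grid, reps, trim, seed, "sn")


def critical_value(nullset: NullSampleSet, alpha: float) -> float:
    """Empirical (1 - alpha)-quantile: the order statistic at index
    ceil((1 - alpha) * reps), a conservative convention."""
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must lie in (0, 1)")
    if nullset.reps * alpha < 5:
        raise InvalidInputError(
            f"too few samples ({nullset.reps}) to estimate the "
            f"{1 - alpha:.3f}-quantile; need reps * alpha >= 5"
        )
    idx = int(np.ceil((1.0 - alpha) * nullset.reps))
    return float(np.sort(nullset.samples)[idx - 1])


def p_value(statistic: float, nullset: NullSampleSet) -> float:
    """Add-one Monte Carlo p-value: (1 + #{samples >= statistic}) / (reps + 1)."""
    if nullset.reps == 0:
        raise InvalidInputError("empty null sample set")
    count = int(np.sum(nullset.samples >= statistic))
    return (1 + count) / (nullset.reps + 1)


# ---------------------------------------------------------------------------
# Critical-value tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "statistic_id", "tau1", "tau2", "alpha", "method",
    "n_or_grid", "reps", "seed", "critical_value",
]


def save_critical_value_table(rows: pd.DataFrame, path) -> None:
    rows = rows[_TABLE_COLUMNS]
    rows.to_csv(path, index=False)


def load_critical_value_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"critical-value table missing columns {sorted(missing)}")
    return df


def critical_value_row(nullset: NullSampleSet, alpha: float) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "statistic_id": nullset.statistic_id,
            "tau1": nullset.trim.tau1,
            "tau2": nullset.trim.tau2,
            "alpha": alpha,
            "method": nullset.method,
            "n_or_grid": nullset.n_or_grid,
            "reps": nullset.reps,
            "seed": nullset.seed,
            "critical_value": critical_value(nullset, alpha),
        }
    ])


def lookup_critical_value(
    table: pd.DataFrame,
    alpha: float,
    trim: TrimWindow = TrimWindow(),
    statistic_id: str = "sn",
) -> Optional[float]:
    """Best matching row (largest reps) or None."""
    m = table[
        (table.statistic_id == statistic_id)
        & np.isclose(table.tau1, trim.tau1)
        & np.isclose(table.tau2, trim.tau2)
        & np.isclose(table.alpha, alpha)
    ]
    if m.empty:
        return None
    return float(m.sort_values("reps").iloc[-1].critical_value)


def bundled_critical_values() -> pd.DataFrame:
    """Precomputed default table shipped with the package; regenerate with
    ``sncp calibrate`` (the seeds and sizes are recorded per row)."""
    from importlib.resources import files

    return load_critical_value_table(files("sncp").joinpath("data/critical_values.csv"))
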