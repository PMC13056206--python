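# Methods

This note documents the model, the statistic, the calibration machinery,
the synthetic-data generator, and the numerical and design choices made
where more than one reasonable option existed.  It states nothing that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model and hypotheses

The observed series y_1..y_n follows a zero-mean stationary ARMA(p, q)
with parameter vector ϑ = (φ_1..φ_p, θ_1..θ_q, σ²)ᵀ.  The null hypothesis
is parameter constancy, ϑ_t = ϑ₀ for all t; the alternative is a single
break at an unknown index k*, after which ϑ_t = ϑ₀ + Δ.  The generator
additionally supports a post-break level shift μ added to the
observations, which is the break type this statistic is most sensitive to.

## Residuals

Residuals are always the conditional forward recursion
ε̂_t = y_t − Σ φ̂_i y_{t−i} − Σ θ̂_j ε̂_{t−j} with y_t = ε̂_t = 0 for t ≤ 0
(implemented as a linear filter with zero initial state).  No backcasting
or state-space smoothing is applied to the residual pass, because the test
statistic is defined on exactly these recursively computed residuals.
Series are used as given — the model has no intercept and no automatic
de-meaning is applied (a `demean` flag exists for real data whose level is
far from zero).

Two estimation backends share the `fit_arma_qmle` surface:

* **`css` (default)** — Gaussian QMLE via conditional sum of squares: the
  estimator minimizes Σ_t ε̂_t(φ, θ)², the sum of squares of the same
  recursion the statistic uses.  Pure AR orders reduce to a closed-form
  least-squares solve on a zero-padded lag matrix; mixed orders are
  minimized with Nelder–Mead (two starts: the origin and the AR-projected
  start) inside a stationarity/invertibility barrier.  Convergence is
  recorded in `FitResult.converged`, never assumed.
* **`exact`** — exact Gaussian MLE through the statsmodels state-space
  ARIMA.  The two backends agree to a few hundredths on simulated ARMA(1,1)
  data (tested); `css` is roughly two orders of magnitude faster, which is
  what makes 1000-replication studies cheap.

An experimental **SVR backend** regresses y_t on its p lags with an RBF
support-vector machine (penalty and epsilon chosen from a small fixed grid
by rolling-origin validation — train on the first 70%, score one-step
errors on the rest, refit on everything); when q > 0 a second pass adds q
lags of the first-pass residuals.  For order (0, 0) the convention ε̂ = y
is pinned to match the parametric backend.  On linear data its residual
variance tracks the QMLE residuals within a few percent; it exists for
series with suspected nonlinear conditional means and is not used by the
simulation harness.

## The statistic

For candidate k, G_n(k) is the absolute difference of the two segment
means of the residuals, scaled by n and divided by the square root of
n⁻¹ times the summed squared within-segment centered partial sums.  T_n is
the maximum of G_n(k) over k ∈ [⌈nτ₁⌉, ⌊nτ₂⌋] (defaults τ₁ = 0.15,
τ₂ = 0.85), and k̂ is the smallest maximizer (ties have probability zero
for continuous data; smallest-k is pinned for determinism).  All public
indices are 1-based with inclusive segments, and k̂ is the last index of
the pre-break segment.

Numerical conventions:

* **Degenerate normalizer.** If both segments are internally constant the
  denominator is exactly zero.  With a nonzero mean difference G_n(k) is
  returned as +inf with a warning (perfect within-segment constancy is
  infinitely strong evidence); with a zero numerator, G_n(k) = 0.
* **Complexity.** With C_t the residual prefix sums, each segment's sum of
  squared centered partial sums expands into three prefix/suffix sums
  (of C_t², tC_t, t²), so the whole profile costs O(n).  The literal per-k
  transcription is kept as `compute_Gn` and the optimized profile is tested
  against an independently written literal oracle at rtol 1e-8 on random
  integer-valued and Gaussian inputs (float summation order prevents exact
  bitwise equality).
* **Candidate window.** ⌈nτ₁⌉..⌊nτ₂⌋, clipped so every candidate leaves at
  least two observations per segment; an informative error states the
  minimum n otherwise.

Invariances (property-tested): G_n is invariant to positive rescaling and
to adding a constant to all residuals; every G_n(k) ≥ 0; the final
centered partial sum of any segment is identically zero.

## What the test can and cannot detect

The numerator of G_n is a difference of residual segment means, so the
test reacts to any break that displaces the residual mean — level shifts
in the observations, and parameter changes in models whose mean depends on
those parameters.  For a **zero-mean** ARMA process, however, a break in
φ, θ or σ² alone leaves E[ε̂_t] = 0 in both segments under any residual
backend (parametric or SVR — a symmetry argument: residuals are odd
functionals of a symmetric process), so the statistic has only trivial
asymptotic power against such breaks.  The simulation harness makes this
visible: pure φ/θ/σ² break scenarios produce rejection rates near the
nominal level, while mean-shift scenarios are detected with power
approaching 1 (a 2σ shift at n = 500 is near-saturating).  Users who need
power against pure variance or dependence changes should apply a test
built on squared or scored residuals instead; within this package the
likelihood-score benchmark statistic (its B(k) component cumulates ε̂_t²)
is the appropriate tool for variance breaks.

## Calibration

* **Finite-sample route (default).**  Simulate i.i.d. standard-normal
  series of the user's length n, compute T_n on each (10000 replications
  by default), and take empirical quantiles.  Under the null the estimated
  residuals are asymptotically i.i.d., so using the draws directly as
  residuals is the faithful default; a `refit=True` option passes each
  draw through fit + residual extraction, which moves the 95th percentile
  by only a few percent (tested at n = 300).
* **Limit-functional route.**  Simulate the limiting law on a uniform grid
  (default 1000 points, left-Riemann integrals, bridges built as
  B(s) = W(s) − sW(1) from scaled random walks).  The three limit
  processes — the numerator bridge and the two segment processes — arise
  from a *single* underlying partial-sum process, and the implementation
  honors that by default (`bridge="joint"`): the second-segment process is
  W(u) − W(s) − ((u−s)/(1−s))(W(1) − W(s)), which is what the centered
  partial sums actually converge to.  A variant with three independent
  bridges and second-segment form B₂(u) − B₂(s) — the form in which such
  limits are often quoted — is available as `bridge="independent"`; it is
  measurably wrong as a null law for this statistic: its 5% critical value
  is ≈ 31.7 versus ≈ 33.4 for the joint law, and its
  Kolmogorov–Smirnov distance from the finite-sample null at n = 2000 is
  0.042 versus 0.009 for the joint construction (both distances computed
  in the test suite at 20000 replications).
* **Quantile and p-value conventions.**  Critical values are the ceiling
  order statistic at ⌈(1−α)·reps⌉ (conservative); p-values use the add-one
  rule (1 + #{samples ≥ T_n}) / (reps + 1).
* **Shipped table.**  `data/critical_values.csv` holds 10/5/1% values from
  both routes at size 1000 and 50000 replications (5% value ≈ 33.2 finite,
  ≈ 33.5 limit); the generating `sncp calibrate` commands and seeds are
  recorded per row.
* Competitor statistics are calibrated by the same protocol, except that a
  fitted model is required (with residuals equal to the series the fitted
  part is identically zero and the score variance estimator degenerates),
  so competitor calibration always simulates a null ARMA model and refits.

## Synthetic-data generator

`simulate_changepoint` generates burn-in + n innovations (standard normal
by default; unit-variance t or uniform available), runs the ARMA recursion
with the baseline parameters up to the break index k* = ⌊n·fraction⌋ and
the post-break parameters afterwards, **carrying the recursion state across
the break** (no reset — a zero-magnitude break is bitwise identical to the
no-break path, which is tested), discards the burn-in (default 200, a
conventional safety margin for the parameter ranges used here), and adds
the mean shift to post-break observations.  An alternate reading that adds
the shift to the innovations instead (stationary level then shifts by
μ/(1−Σφ) for an AR model) is available via `shift_innovations=True`.
Everything is a pure function of (dgp, n, seed).

The study harness (`reproduce_table`, `run_scenario`) fixes the conditions
of the size/power grids: AR(1) baseline φ = 0.3 and ARMA(1,1) baseline
φ = θ = 0.3, σ² = 1, n ∈ {200, 500}, breaks at sample fractions 0.5 or
0.25/0.75, each scenario changing only its named parameter (variance
scenarios change the innovation *variance* 1 → 2), mean shifts of 2 where
stated, 1000 replications at α = 0.05, the fitted order equal to the true
order.  Replicates draw their seeds from a spawned SeedSequence, so
results do not depend on execution order; non-convergent fits are redrawn
and counted, and a redo rate above 10% aborts.

What the generator does *not* emulate: multiple or gradual breaks,
conditional heteroskedasticity, heavy-tailed innovations beyond the t
option, measurement error, seasonality, or a nonzero baseline mean.
Passing tests therefore demonstrate correct behavior under clean single-
break ARMA dynamics, not robustness to the full messiness of real series.

## Known limitations

* Single change point only; iterative application to subsamples is left to
  the user.
* No confidence interval for k̂.
* The SVR backend's hyperparameter grid is deliberately small and fixed;
  it is a reproducible default, not a tuned model.
* Power against pure variance or autocorrelation breaks is trivial by
  construction (see above) — this is a property of the mean-difference
  numerator, not an implementation artifact.
* Scale choices in the test suite (e.g. KS comparisons at 20000
  replications, study rows at 1000) balance Monte Carlo error against
  desk-scale runtimes; all replication counts are flags.
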