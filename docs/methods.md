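# Methods

## The model class

All systems have the commensurate form D^α x = f(t, x, x(t−τ)) with the
Caputo derivative of order α ∈ (0, 1] taken from t = 0 (left-sided
operators: causal evolution from a fixed origin).  Orders above 1 are
rejected everywhere — under the globally-slow-transcription reading, a
state increment can only be assigned a *longer* effective time increment,
never a shorter one — and α → 0 is treated as a limit, not a usable order.
The Caputo (rather than Riemann–Liouville) derivative is used so that
initial data keep their ordinary meaning: the derivative of a constant is
zero and an initial *value* (or history segment, for delayed systems)
fully determines the solution.

The memory interpretation is carried by the kernel
w(u) = u^(α−1)/Γ(α): the fractional integral is a weighted average of the
integrand's history, with uniform weight 1 at α = 1 (no fading) and mass
concentrating at the present as α → 0 (the fraction of kernel mass in the
most recent ε of a length-t history is (ε/t)^α → 1).

For the delayed Goodwin model the memory integral and the delay are
independent devices: the Caputo integral always starts at t = 0, and the
history segment on [−τ, 0] enters only through the delayed argument of the
right-hand side.  The default history is constant at the initial value,
matching the convention of starting a simulation with a step to the
initial state.

## Discretizations

**Product-trapezoidal quadrature.**  The Riemann–Liouville integral is
discretized on uniform grids by the product-trapezoidal rule (exact for
piecewise-linear integrands against the power kernel); the Caputo
derivative is computed as the (1−α)-order integral of a second-order
finite-difference first derivative.  The identity D^α I^α f = f holds in
discretization up to an error that vanishes with h (checked by step
halving in the tests).

**Adams–Bashforth–Moulton predictor–corrector (`method="abm"`).**  The
reference solver: a fractional rectangle-rule predictor followed by one
product-trapezoidal corrector step.  At α = 1 it reduces to the classical
second-order predictor–corrector.  Cost is O(n²) in the number of steps
because every step convolves the full right-hand-side history — that cost
*is* the memory and is not truncated.  Practical up to ~10⁵ steps.

**Oustaloup filter route (`method="oustaloup"`).**  Each fractional
integrator is replaced by the band-limited recursive zero/pole
approximation of s^(−α) on [10⁻³, 10³] rad/time with 5 cells (2·5+1
zero/pole pairs), made strictly proper by a first-order low-pass at the
upper band edge (without it the biproper filter would create an algebraic
loop with the feedback law).  The filter is diagonalized into first-order
modes by partial fractions and each mode is propagated with the exact
exponential two-stage rule (constant-u predictor, linear-u corrector), so
the stiff modes at the band edges are integrated unconditionally stably
and cost is O(n).  The filter gain is normalized to be exact at the
geometric band center; magnitude error is below 1 dB and phase error below
5° across the band (tested).  Initial values are handled by integrating
the increment y = x − x₀ with zero filter state, valid for the Caputo
operator since D^α x₀ = 0.

The two routes cross-validate each other: on the fractional relaxation
test problem D^α x = −x (exact solution E_α(−t^α), evaluated by series
summation of the Mittag-Leffler function) both match the exact solution to
~10⁻³ at h = 0.01 and agree with each other to ~10⁻³; at α = 1 both agree
with classical integrators (the ABM route to 10⁻⁴ relative error on the
Goodwin and Rössler right-hand sides).

**Delay handling.**  The delayed state x(t−τ) is read from the prescribed
history for t ≤ τ and linearly interpolated from the computed trajectory
afterwards; τ < h is rejected.  Because τ ≥ h, the corrector at t_{k+1}
only ever needs already-computed values.

**Blow-up.**  Any state exceeding 10⁸ in magnitude (or going non-finite)
truncates the run and flags the trajectory, making instability a
detectable, reportable outcome; analyses record such cells as failed
rather than crashing a sweep.

## Default parameters and run lengths

| parameter | default | rationale |
|---|---|---|
| Goodwin Hill coefficient n | 10 | comfortably above the n > 8 destabilization threshold ("sufficient nonlinearity") |
| Goodwin degradation k₂ | 0.1 /time | keeps the degradation timescale properly balanced; large k₂ suppresses oscillation |
| Goodwin delay τ | 15–25 time units in demos/sweeps | well beyond the α = 1 Hopf delay (~1.9 at n = 10, k₂ = 0.1) |
| Rössler (a, b, c) | (0.15, 0.20, 10.0) | the benchmark set of the standard Lyapunov-estimation literature; (0.2, 0.2, 5.7) ships as `rossler-classic` |
| step h | 0.01 (Goodwin demos), 0.02 (sweeps/scans) | resolves delays of 10–25 and the Rössler orbit (~6 time units/cycle) |
| Goodwin classification runs | 1000 time units, first half discarded | the post-transient window must hold ≥ 5 oscillation cycles at periods of ~2–3τ; 500 units are not enough at τ = 20–25 |
| Rössler LLE / bifurcation runs | 2000 time units, first 75% discarded, sampled at 0.1 | near the chaos onset transients are long and the weakly chaotic band (λ ≈ 0.03) needs the longer settled window to classify correctly |

The classifier labels post-transient motion from its local maxima:
range below tolerance → fixed point; with ≥ 5 peaks, a least-squares
peak-height slope ≥ −10⁻⁴ per time unit → sustained oscillation (slow
damping at finite run length is distinguished from a limit cycle by that
slope), decaying slope → damped; a peak-spacing coefficient of variation
above 0.25 → irregular.  Bifurcation scans merge post-transient maxima
closer than 10⁻³ (observable units) into clusters; 1/2/3 clusters read as
period-1/2/3, many as a chaotic candidate.  Period counts are invariant to
doubling the integration length (tested indirectly through the long-run
defaults; the near-onset cells are the reason for the 2000-unit default).

## Lyapunov estimation

The largest Lyapunov exponent of a scalar series follows the
nearest-neighbor divergence recipe: delay-embed, pair every vector with
its nearest neighbor at temporal separation greater than one mean period
(power-spectrum peak reciprocal), average log-distances of the pairs over
a growing horizon, and fit the linear region of that curve.

* **Lag**: first local minimum of the binned average mutual information,
  accepted only after the AMI has decayed below half its lag-1 value
  (shallow minima on a barely-decorrelated signal are binning artifacts);
  if the AMI reaches its 1/e floor first, the floor crossing is used
  (map-like series, small lags); if neither fires, the first zero crossing
  of the autocorrelation (a quarter period for a sinusoid).  A series
  already decorrelated at lag 1 gets lag 1.
* **Dimension**: false nearest neighbors (ratio test 15, size test 2) at
  the 1% threshold, capped at 10.  Monotone series are rejected as
  non-stationary.
* **Linear region**: the divergence curve is biased downward at both ends
  — early, neighbor pairs still contract along stable directions while
  aligning with the unstable one; late, separations saturate at the
  attractor diameter.  The default fit window is therefore the contiguous
  window (about one mean period long, at least 5 points) of *steepest*
  slope within the part of the curve below 60% of its total rise.  This
  choice recovers ln 2 on the r = 4 logistic map to better than 1% and
  1.44 on the classic Lorenz benchmark (true value 1.50); on the Rössler
  benchmark it reads ≈ 0.083 against a literature value of ≈ 0.09–0.10 —
  a known residual downward bias of divergence-curve estimates for weakly
  chaotic flows.  An explicit `fit_range` overrides it.
* **Classification**: |λ₁| ≤ 0.02 (inverse time units) counts as zero
  (limit cycle or quasiperiodic); above, chaotic; below, fixed point.  The
  band separates the benchmark chaotic exponent (~0.1) from the periodic
  noise floor (|λ₁| < 0.01 in practice) at the default series length of
  5000 samples.
* Trajectories that have relaxed onto a fixed point produce monotone or
  flat tails that cannot be embedded; the order-scan pipeline classifies
  those directly from the exponential decay rate of the residual motion.

The non-chaotic probability treats the scanned order as uniform on (0, 1]:
the critical order α_c is the smallest chaotic grid cell, refined by one
bisection of the bracketing interval, and the probability is the measure
α_c of the non-chaotic set below it.  Isolated zero-exponent cells *above*
α_c (periodic windows embedded in the chaotic band — the order scan of the
fractional Rössler system shows a period-three window near α ≈ 0.992) do
not move the onset.

## What the synthetic fixtures emulate

The deterministic fixtures (logistic map, sinusoid, damped sinusoid, white
noise, canned solver trajectories) exercise exactly the properties the
analyses rely on: a known positive exponent (ln 2), a known zero exponent
with known quarter-period lag, known decay, and absence of structure.
They are noise-free and stationary by construction; passing on them shows
the estimators are correct on clean signals, not that they are robust to
measurement noise, non-stationarity or the short, irregular sampling of
real transcription time courses — none of which the package models.

## Design choices and limitations

* Fractional-order linear stability theory (argument conditions on
  Jacobian eigenvalues) is deliberately *not* used for the delayed
  systems; all fractional/delayed classification is simulation-based.
  The analytic results shipped (critical Hill coefficient, Hopf delay of
  the α = 1 delayed Goodwin model) are classical integer-order ones, the
  latter serving as an independent oracle for the simulation pipeline.
* The critical Hill coefficient is computed generically — bisection on n
  with an inner search over rate scalings k, testing Jacobian eigenvalues
  at the fixed point — rather than by quoting the secant condition; the
  closed form (sec³(π/3) = 8) is the cross-check.  Only the symmetric-rate
  chain is implemented.
* The Oustaloup route is band-limited: behavior at frequencies outside
  [10⁻³, 10³] (very long runs, or relaxation tails slower than 1000 time
  units) is exponential rather than power-law.  The fractional Rössler
  system at orders far below the chaotic region (α ≲ 0.6) can blow up
  under this route even though the underlying fractional system is
  expected to be stable — order scans therefore anchor at α ≥ 0.7 and
  record blown-up cells as failures.
* The ABM route keeps the full memory (no short-memory truncation); long
  runs should use the Oustaloup route.
* The mapping between the reinitiation-survival rate γ and the order α is
  qualitative in this model class; the package exposes them as independent
  knobs and implements only the survival law exp(−γΔt) itself.
* No stochastic transcription: everything here is deterministic dynamics;
  bursting enters only through its deterministic timescale consequences.
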