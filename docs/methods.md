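# Methods

## The decision model

All computations refer to the one-dimensional drift-diffusion model
(DDM): within a trial a decision variable `x` evolves as
`dx/dt = A + ξ` with `E[ξ(t)] = 0`, `E[ξ(t)ξ(t')] = c² δ(t−t')`,
starting at `x(0) = mθ`, until it first reaches `+θ` (report "target
present") or `−θ` (report "target absent").  Reaction time is the
first-passage time plus a non-decision latency `Ter` that lumps
sensory transduction and motor output.  The model has no across-trial
parameter variability (no drift or start-point variability); lapses
are instead handled as a uniform outlier mixture during fitting.

With `r = 2Aθ/c²`:

- `p = [e^r − e^{−rm}] / [2 sinh r]`, the probability of absorption at
  `+θ`; at `r = 0` the continuous limit is `(1+m)/2`.
- `E[DT] = θ[cosh r − m sinh r − e^{−rm}] / [A sinh r]`; the `r → 0`
  limit is the pure-diffusion exit time `θ²(1−m²)/c²`.
- Sensitivities: `∂p/∂A = θg/(c² sinh²r)`,
  `∂p/∂c² = −Aθg/(c⁴ sinh²r)`, `∂E[DT]/∂c² = −2θ²g/(c⁴ sinh²r)`,
  where `g(r) = e^{−rm}[cosh r + m sinh r] − 1`.  `g > 0` for `r ≠ 0`
  (verified numerically on sign-spanning grids rather than proved),
  which fixes the direction of every mechanism prediction
  independently of parameter values.

### Numerical evaluation

Naive evaluation of these forms overflows (`e^r`) or cancels
catastrophically (`r → 0`).  Choices made:

- `p` is computed as `expm1(−r(1+m))/expm1(−2r)`, which is exact and
  overflow-free for `r > 0`; `r < 0` uses the reflection
  `p(A,m) = 1 − p(−A,−m)`.  Below `|r| < 1e−6` an explicit limit
  branch `(1+m)/2 + r(1−m²)/4` keeps the join smooth to ~1e−12.
- `E[DT]` uses the reflection `E[DT](A,m) = E[DT](−A,−m)` to reduce to
  `r > 0`, where `coth r − m − 2e^{−r(1+m)}/(1−e^{−2r})` has only
  non-positive exponents; the `|r| < 1e−6` branch is
  `θ²(1−m²)/c²·(1 − rm/3)`.
- The shared factor `g(r)/sinh²r` is computed from an equivalent form
  with all exponents ≤ 0 and a series branch below `|r| < 1e−3`.
- Derivatives at `r = 0` raise `UndefinedDerivativeError` (the printed
  forms are 0/0 there); callers that need the limit take it
  explicitly.

### First-passage distributions

The chi-square method needs the defective CDF
`F_b(t) = P(absorb at b, DT ≤ t)`.  Two exact series are implemented
in the unit-variance scaled frame (`a = 2θ/c`, start `z = (1+m)θ/c`,
drift `v = A/c`): the spectral (large-time) expansion of the
absorbed flux, and a method-of-images (small-time) expansion whose
terms integrate to shifted single-barrier passage CDFs evaluated via
`exp(coef + logΦ)` so that huge coefficients and tiny normal tails
cancel in log space.  Per evaluation point the representation with the
fewer estimated terms is chosen (the spectral form is also refused
when its prefactor exponent cannot cancel safely); truncation targets
an absolute tail below 1e−12, and the two representations agree to
~1e−10 across the tested parameter grid.  Quantiles of the defective
CDF are obtained by monotone bisection to 1e−8 s.

## Stochastic simulator

Trials are simulated by Euler–Maruyama with step `dt` (default 1e−4 s;
the generator uses 1e−3 s).  By default a Brownian-bridge test is
applied inside every step: given both endpoints strictly inside the
bounds, the continuous path still crossed a bound with probability
`exp(−2 d_i d_{i+1}/(c² dt))`, and a uniform draw decides absorption.
This removes the O(√dt) first-passage bias of the plain scheme (which
effectively widens the bounds by ≈ 0.583·c·√dt) and makes the
closed-form agreement checks pass at Monte-Carlo noise level with
coarse steps; `bridge=False` recovers the uncorrected scheme, and a
step-halving test covers its convergence.  Crossing times are recorded
at step ends (bias ≤ dt, below Monte-Carlo noise at the sizes used).
Outlier trials (probability `outlier_rate`) get a uniform RT on
[Ter, response window] and a fair-coin choice.

## Synthetic task generator

The generator reproduces the experiment's structure: per session,
trials are drawn sequentially; the probability that the next trial is
target-on is one minus the fraction of "report present" responses in
the agent's last 5 responded trials (0.5 at session start) — a
negative-feedback rule that counteracts side biases; mixture size
`x ∈ 1..6` follows `p(x) ∝ b^x`; a target-on mixture of `x` components
carries `x−1` backgrounds (targets A/B equiprobable), a target-off
mixture carries `x`.  Omitted trials (RT beyond the 2.8 s window,
measured from odor onset with the 200 ms odor-arrival delay already
subtracted, i.e. 2.6 s on the stored scale) consume a trial slot but
enter neither the table nor the choice history.  Sessions draw
`b ∈ {0.5, 0.75, 1}` (data collection used `b ≥ 0.5`); optional
training sessions at `b = 0.25` exercise the session filter.  Default
sizes: 70 sessions × N(250, 20²) trials, 5% outliers.

Ground-truth defaults (the "combined mechanism") are expressed
directly in the fitting gauge `θ = 1/2`: baseline drifts +1.25 / +1.15
(targets A / B) and −1.4 (target off), baseline diffusion variance
0.65, start bias m = −0.1, Ter = 0.35 s; each background odorant
shrinks |drift| by 0.06 and adds 0.15 to the diffusion variance.
These values were chosen once to land in the study's observed regime —
session accuracy ≈ 74–78% (so the 70% filter bites only occasionally,
as in the real dataset), choice probabilities spanning ≈ 0.55–0.85,
mean RTs ≈ 0.5–0.7 s and falling with background count, and a slight
negative side bias so the adaptive rule produces >50% target-on
trials.  The generator emulates trial statistics and decision
dynamics only: no learning within or across sessions, no satiety or
session-position effects, no odorant-identity-specific interference
(targets differ only in baseline drift).  Passing recovery tests
therefore show that the estimator inverts the generative model at
realistic sizes, not that real mice satisfy DDM assumptions.

## Preprocessing

Sessions with `b < 0.5` (training) or accuracy < 70% are dropped.
Reaction times are normalized per session:
`rt_norm = rt_raw · (grand mean / session mean)`, which preserves
within-session order and ratios and equalizes session means.  The
grand mean is the unweighted mean of session means by default
("session"); a trial-weighted variant ("trial") is available — the
convention matters only at the third decimal for balanced data.

## Chi-square quantile fitting

Per condition, correct and error RTs are separately cut at the
0.1/0.3/0.5/0.7/0.9 empirical quantiles (linear-interpolation
convention), giving observed counts of (0.1, 0.2, 0.2, 0.2, 0.2, 0.1)
of each response type — 12 statistics per condition, 216 per mouse.
Expected counts evaluate the defective CDF at the empirical quantiles
minus Ter (floored at 0), mix in a uniform outlier component of weight
5% (support [Ter, max observed RT], split evenly between boundaries),
difference successive values with end caps 0 and the boundary's total
mass, and multiply by the condition's **total** trial count.  This
total-N normalization is the method's standard form: it lets the
objective constrain the choice probability through the defective
masses.  The alternative reading — renormalizing each response type to
its own count — is implemented (`normalization="within_type"`) but not
default, because it makes expected sums equal observed sums by
construction, deleting all choice-probability information from the
objective; with an unbiased start point the drift sign is then
unidentifiable.

The objective is `Σ (O−E)²/max(E, 1e−3)` over bins and conditions.
Response types with < 12 trials collapse to a median split (2 bins);
an empty type contributes a single bin whose expected count penalizes
misplaced probability mass.  Free parameters: per-condition
`(θ_fit, A_fit)` with unit diffusion, bounds `θ_fit ∈ [0.05, 10]`,
`A_fit ∈ [−20, 20]`, plus shared `m' ∈ [0.05, 0.95]` and
`Ter ∈ [0, min RT)` — 38 in all.

Optimization exploits that conditions decouple given `(m', Ter)`:
moment-based starts (logistic inversion of accuracy for `r`, the
unbiased mean-DT identity for the scale) seed per-condition 2-D
Nelder-Mead fits with seeded random restarts; an outer Nelder-Mead
over `(m', Ter)` re-solves the conditions warm-started; a bounded
L-BFGS-B pass then polishes the full 38-vector.  The fit is
deterministic given its seed, and the reported objective never exceeds
the heuristic initialization's.  A flat 38-dimensional simplex was
rejected as both slower and less reliable than the nested scheme on
this block-separable objective.

Rescaling to the reported gauge is exact and exactly invertible:
`A = A_fit/θ_fit`, `c² = 1/θ_fit²`, `θ' = 1 (θ = 1/2)`, `m = 2m'−1`.
The objective itself is invariant under the scaling family
`(θ, A, c²) → (λθ, λA, λ²c²)`, which is why one parameter must be
pinned.

## Evaluation

The posterior-predictive check simulates 1000 responses per condition
at the fitted parameters and compares choice fractions and median RT ±
MAD (unscaled median absolute deviation) with the data.  Across-mouse
trends report mean ± SE of drift and diffusion per (trial type,
background count); target-on conditions pool targets A and B by simple
average.  The recovery report scores bias, RMSE, truth–estimate
correlation, and the sign of the fitted background trends (OLS slope
of |drift| and of c² against background count across the 18
conditions), after mapping the generating parameters onto the fit's
gauge.

## Problem sizes and tolerances in the test suite

Monte-Carlo comparisons use n = 1e5 trials at step 5e−4 s with the
bridge correction (agreement required within 3 SE); the KS calibration
bound is 0.01 at n = 1e5; derivative checks require 1e−4 relative
agreement with central differences at step 1e−6; the robustness sweep
draws 100 random baselines and background schedules with zero
tolerated violations.  The full-size recovery check generates one
65-session mouse (~900 trials/condition), requiring drift
truth–estimate correlation > 0.9, correct trend signs, and
posterior-predictive choice probabilities within 3 SE (combining
observed and simulated binomial noise).  A 6-replicate small-sample
check (~100 trials/condition) requires the trend signs to survive in
at least 5 replicates.

## Known limitations

- No across-trial variability parameters; if real data contain them,
  recovered drift/diffusion absorb their effects.
- Euler timing is recorded at step ends; for step 1e−3 this adds ≤ 1 ms
  to simulated RTs — negligible here but visible if tolerances were
  tightened tenfold.
- The sparse-cell rule (median split under 12 trials) is a pragmatic
  stabilizer; alternatives (dropping cells, pooling) would change
  low-count conditions' leverage.
- The within-type normalization variant is provided for comparison
  only; see above for why it cannot identify the drift sign alone.
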