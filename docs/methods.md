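# Methods

This note documents the statistical model behind `tamsdesign`, the numerical
choices made in implementing it, what the simulator does and does not
emulate, and the known limitations.

## Design model

A two-arm multi-stage (TAMS) design compares an experimental arm E against a
control arm C over `s` stages. Stages 1..s−1 test an intermediate
time-to-event outcome I; stage `s` tests the definitive outcome D. I is
assumed to occur no later and at least as often as D and to lie on the
causal pathway to D; it is not required to be a surrogate. The working
assumptions are proportional hazards for the treatment effect on both
outcomes and, **for stage timing only**, exponential survival with constant
(per-stage) uniform accrual. A violated exponential assumption distorts the
projected calendar times but not the event targets.

Per stage the user supplies a one-sided significance level `α_i`, a power
`ω_i`, and hazard ratios `Δ⁰_i` (null, default 1) and `Δ¹_i` (alternative).
The `α_i` must be strictly descending, otherwise later stages are redundant
(validated with an error). Descending geometric sequences such as
0.5, 0.25, 0.1, …, ending at 0.025 at the definitive stage, give roughly
evenly spaced looks; more than six stages triggers a warning as rarely
useful. The package treats a multi-arm (MAMS) trial as a collection of
pairwise TAMS comparisons and makes no familywise-error adjustment.

### Critical values and event targets

With `e_i` cumulative control-arm events on the triggering outcome and
allocation ratio A (experimental per control patient), the log-HR estimate
is modelled as normal with null variance `σ₀² = (1+1/A)/e_i` and alternative
variance `σ₁² = 1/e_i + 1/e*_i`, where `e*_i` is the expected
experimental-arm event count under H₁ at the look time (fewer events accrue
under H₁, which the naive `σ₀` form would ignore). The boundary is
`ln δ_i = ln Δ⁰_i + Φ⁻¹(α_i)·σ₀_i`; the trial continues iff the estimated HR
is ≤ `δ_i` (chosen so the stagewise level is not exceeded; ties have
probability zero).

`e_i` is found iteratively: start from the closed-form
`⌈(1+1/A)(Φ⁻¹(ω_i)−Φ⁻¹(α_i))²/ln²(Δ⁰_i/Δ¹_i)⌉`, then repeatedly (1) compute
`δ_i`, (2) invert the control-arm expected-event curve for the look time
`t_i`, (3) evaluate `e*_i` from the experimental-arm curve with hazard
`Δ¹·λ`, (4) accept the first integer `e_i` whose attained power reaches
`ω_i`. Incrementing by one (no bisection) guarantees the target is minimal;
this is verified by a property test. Attained powers `ω̃_i` slightly exceed
the nominal `ω_i` because the target is an integer; all downstream power
calculations use `ω̃_i` — using nominal powers instead fails to reproduce
the package's own conditional-power outputs (e.g. 0.969 at a nominal 0.95).

Looks are indexed by **control-arm** event counts, which the treatment
cannot affect, so stage times are identical under H₀ and H₁ and the design
is well-defined without reference to the true effect.

Interpretation note: published stage tables of this kind sit on rounding
boundaries — a target printed as 73 may correspond to an attained power of
0.9496 at one implementation's timing and 0.9501 at another's. The solver
here reproduces reference tables exactly except for occasional ±1-event
cells of this type.

### Accrual calculus

For one arm recruiting at rate r on (0, t] with exponential hazard λ, the
expected events are `e(t) = r·t − (r/λ)(1−e^{−λt})`. Stagewise-varying
rates are handled by a recurrence over stages for the pair (at-risk N(t),
events e(t)), valid because the exponential distribution is memoryless.
With no loss to follow-up, `N(t) + e(t)` equals the number recruited —
enforced as a test invariant. The inverse problem (time at which a target
event count is expected) is solved by Newton–Raphson with the exact
derivative `e'(t) = λ·N(t)`, a start value of half a median past the
previous stage end, convergence tolerance 10⁻⁶ events, and a bracketing
bisection fallback for any step that leaves the feasible interval. An
optional recruitment stop t\* (allowed only inside the final stage — an
earlier stop would make later looks pointless and is rejected) zeroes the
rate afterwards, with `N(t*)·F(t−t*)` governing subsequent events; targets
beyond the asymptote raise a "design infeasible" error.

Accrual rates are control-arm rates by default. Because published tables
are sometimes parameterised by whole-trial accrual, `DesignSpec` exposes
`accrual_basis="total"`, which divides by (1+A).

This calculus is a deterministic fluid approximation; stochastic arrivals
appear only in the simulator.

## Operating characteristics

The stagewise log-HR estimates are modelled as multivariate normal with the
same correlation matrix R under both hypotheses. Between two looks on the
same outcome, `R_ij = √(e_i/e_j)` (an equilibrium Poisson-process argument
gives this exactly under the null; simulation shows it is an excellent
approximation generally). Between an I-look and the definitive D-analysis
the correlation is attenuated: `R_is = c·√(e_i/e_s)` with a constant
`c ∈ (0,1]`; c = 1 recovers the identical-outcomes case. Overall
significance level and power are lower-orthant probabilities at the
stagewise quantiles (of `α_i` and of the attained `ω̃_i` respectively);
stagewise-conditional quantities are ratios of successive joint
probabilities and telescope back to the overall values (tested to 10⁻⁶).

Numerics: orthant probabilities use scipy's quasi-Monte-Carlo MVN CDF with
a fixed integration seed and a budget of 2×10⁵ points per dimension, making
repeated evaluations bit-identical and accurate to well below 10⁻⁵ at the
dimensions involved (s ≤ 10 enforced loosely; designs use s ≤ 6). Supplied
cross-outcome correlations may break positive semi-definiteness; matrices
with a minimum eigenvalue below −10⁻⁸ are projected to the nearest PSD
matrix (eigenvalue clipping with diagonal renormalisation) with a warning.

**Bounds.** With no information on the cross-outcome correlations, the
joint pass probability is monotone in c by Slepian's inequality, so the
bounds are: minimum at c = 0 (independence, where α factorises into
α_I·α_s) and maximum at c = 1. The comonotone limit R_is = 1 would violate
positive-definiteness; c = 1 is the PSD-feasible extreme and already brings
α close to its ceiling α_s. (Some published prose states the directions the
other way round; the monotone-in-c sensitivity tables and the ceiling
(α_s, ω_s) both confirm the direction used here.)

The default c is 0.6. Simulation at latent correlation ρ = 0.6 yields ĉ
around 0.63–0.77 depending on scenario; a rule of thumb `c ≈ 1.1·ρ` is
provided (`c_from_rho`, flagged heuristic), and the recommended practice —
supported by `sensitivity_over_c` and the `oc --c-grid` subcommand — is a
sensitivity analysis over c ∈ [0.4, 0.8]. Underestimating c is
conservative: it understates α more than it misstates ω.

## Correlated outcome generator

Patient-level outcomes come from a Gaussian copula: (U, V) standard
bivariate normal with correlation ρ (default 0.6), transformed by
`X = −ln Φ(U)/λ₁`, `Y = −ln Φ(V)/λ₂` (computed via `norm.logcdf` for tail
stability). X is the latent time to the intermediate-only event, Y the
definitive time, and the observable intermediate outcome is the composite
`Z = min(X, Y)` — a patient may die before progressing, in which case
Z = Y. Using `Φ(U)` rather than `1−Φ(U)` in the transform is an arbitrary
sign convention; applied to both coordinates it yields the same positive
dependence.

Two calibrations make the generator match a user's specification of the
*observable* hazards (λ₂ for Y, λ₃ for Z):

1. **Latent hazard.** The hazard of Z is approximated as the reciprocal of
   its Monte-Carlo mean; λ₁ is recovered from (λ₂, λ₃, ρ) by root-finding
   on a fixed common-random-numbers sample (2×10⁵ draws by default), making
   the objective smooth and strictly monotone; the forward check reproduces
   λ₃ within 0.5%. At ρ = 0 the closed form λ₁ = λ₃ − λ₂ is exact and used
   directly. Targets λ₃ ≤ λ₂ are rejected as infeasible.
2. **Exponentialising correction.** For ρ > 0 the composite Z is close to
   but not exactly exponential. A monotone empirical quantile map sends the
   simulated distribution of Z onto the exponential(λ₃) scale, using a
   sorted reference sample of 10⁶ standardized composites (λ₃·Z is
   scale-free, so one table serves any joint rescaling of the hazards, in
   particular a common treatment hazard ratio). The map preserves patient
   ordering exactly and leaves 1/mean(Z′) within 1% of λ₃. This replaces a
   parametric exponential-normal correction of the same quantity: the
   quantile map attains the stated goal (exponential marginal for Z′) by
   construction and is directly testable, at the cost of Monte-Carlo noise
   in the far tails (mid-rank clipping keeps it finite). Per-model direct
   calibration is used rather than smoothing λ₃ over a (λ₁, λ₂, ρ) grid.

Treatment is applied as proportional hazards on both outcomes: a common
hazard ratio rescales the whole joint distribution (exact, calibration
reused); distinct I/D ratios trigger re-solving λ₁ and recalibration.

## Trial simulator

Each replicate recruits patients at the design's stagewise rates —
deterministic-uniform entries by default, matching the fluid timing
calculus; Poisson arrivals optionally, matching the equilibrium correlation
theory — assigns (Z′, Y) pairs per arm, and executes event-driven looks:
look i fires at the calendar time of the e_i-th control-arm
triggering-outcome event, data after the look are invisible to it, and
follow-up extends as far as needed (slow replicates take longer rather than
failing). The log HR at a look is estimated by maximising the Cox partial
likelihood for the single binary treatment covariate, censoring at the look
time; ties (absent for continuous times, present if times are rounded) use
the Breslow approximation. The fitter is a vectorised Newton iteration
written for this purpose — general survival packages are two orders of
magnitude too slow for 10⁴–10⁵ interim fits — and is cross-checked against
an independent partial-likelihood implementation to 10⁻⁴ in the test suite.
If one arm has no events the estimate is ±∞ and the stage decision resolves
by sign (no experimental events ⇒ pass). An event-count estimator
`ln(O_i/(A·e_i))` is available for correlation studies, where it is the
exact quantity the √(e_i/e_j) rule describes; it is not consistent for the
HR under H₁ in the transient regime and is not used for stopping decisions.

`run_study` aggregates replicates into stagewise conditional pass
probabilities (conditioning on passing all earlier stages, with binomial
Monte-Carlo standard errors on the conditioning count), overall empirical
significance/power, and the mean information fraction at stopping
(control-arm D-events at the stopping look over the design's final target;
replicates reaching the final analysis count 1.0 — the averaging convention
is the package's own choice, so published information-fraction figures are
matched qualitatively, not numerically). Replicate seeds derive from a
single master seed via the generator's stream, making every summary
reproducible. `estimate_cross_correlation` runs without stopping to observe
every look, returning the empirical R̂, the per-stage attenuation estimates
ĉ_i = R̂_is/√(e_i/e_s), and the fixed-time I/D log-HR correlations.

### What the simulator does and does not emulate

It emulates: staggered entry at the design's rates, correlated
intermediate/definitive outcomes with exact exponential marginals,
event-driven interim analyses on partially followed-up data, and the exact
stopping rule. It does not emulate: loss to follow-up or censoring other
than administrative-at-look, non-proportional hazards, non-exponential
baselines, time-varying accrual within a stage, or multi-arm trials sharing
one control. Passing tests therefore show that the design mathematics is
internally correct under its own assumptions, not that those assumptions
hold for any particular disease setting.

A known estimator-level nuance: with the Cox MLE at small event counts the
empirical stagewise pass probabilities exceed their normal-theory values by
up to ~0.01 (the MLE's small-sample bias away from zero), the same
direction and similar magnitude as the discrepancies reported for such
designs generally. The aggregate empirical operating characteristics agree
with the analytic ones within Monte-Carlo error at the replication levels
used in the test suite. The accompanying bias diagnostics (`diagnostics_bias`)
standardise the log-HR by the design σ's; for this estimator the means sit
at the nominal quantiles with a small negative H₁ shift and both SDs within
a few percent of 1, indicating the variance formulas are adequate here and
the residual operating-characteristic bias is mean- rather than
variance-driven.

## Problem sizes and defaults

- Design solving and operating characteristics are effectively instant
  (seconds).
- The calibration reference is 10⁶ draws (4–5×10⁵ in tests); the λ₁ solve
  uses 2×10⁵ common random numbers.
- Simulation studies in the test suite use 10⁴ replicates for operating
  characteristics (Monte-Carlo SE ≈ 0.002–0.005 per probability) and
  5×10³ for correlation matrices (SE ≈ 0.014 per entry), sizes at which
  every published benchmark is resolvable within 3 combined SEs.
- Default attenuation c = 0.6; default latent correlation ρ = 0.6.

## Limitations

- Exponential survival for timing: projected `t_i` are planning values; a
  piecewise-exponential or baseline-transform extension would change the
  accrual calculus but not the event targets.
- The cross-outcome correlation model `R_is = c·√(e_i/e_s)` is a
  conjecture supported by simulation; c is not exactly stage-constant
  (simulated ĉ varies by a few hundredths across stages and scenarios).
- The normal model for log-HR estimates is first-order; its small-sample
  bias is visible at relaxed early-look levels (see above).
- No familywise-error control across experimental arms, no
  stopping-for-benefit boundaries, and no alpha/beta-spending machinery:
  boundaries here come from fixed stagewise levels on accumulating data,
  not from a spending function.
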