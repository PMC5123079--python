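# Methods

This note documents the models implemented in `urgeflow`, the choices made
where the designs were genuinely open, the numerical machinery, and what the
synthetic-data generators do and do not emulate.

## Urgency signal and effective bounds

A decision is made when one of two perfectly anti-correlated accumulators,
each driven by drift-diffusion evidence plus a common evidence-independent
urgency signal u(t), reaches a fixed unit bound. Because the accumulators
are anti-correlated, the model is mathematically identical to a single
diffusion started at 0 between symmetric time-varying bounds
b(t) = 1 − u(t).

u(t) is logistic,

    u(t) = min( u0 + (c − u0) · (Λ(t) − Λ(0)) / (1 − Λ(0)), 1 ),
    Λ(t) = 1 / (1 + exp(−(t − λ)/k)),

with static component u0 = u(0), shape k (s), latency λ (s), and ceiling c.
With c = 1 (default) the signal asymptotes at the bound and can take
concave, convex, approximately linear or flat (k → ∞) shapes. With c > 1
the clipped signal *reaches* the bound at a finite time with non-vanishing
slope. The distinction matters: a continuously collapsing bound absorbs
every diffusion path before full collapse (the first-passage probability of
a shrinking band is 1), so a bound that only asymptotes toward 0 cannot
put response mass near the deadline, whereas a clipped signal collapses the
bound fully at a planned time. `collapse_urgency(u0, t_collapse, lam, k)`
solves the ceiling for an exact collapse time.

## First-passage densities (renewal method)

For bounds ±b(t) that are piecewise continuously differentiable, the defect
first-passage densities g±(t) satisfy a system of Volterra integral
equations of the second kind in the free-diffusion transition kernel
(drift μ, noise s):

    g₊(t) = −2Ψ₊(t | 0, 0) + 2∫₀ᵗ [g₊(τ)Ψ₊(t | b(τ), τ) + g₋(τ)Ψ₊(t | −b(τ), τ)] dτ

(and symmetrically for g₋), with

    Ψ(t, S(t) | τ, y) = f(S(t), t | y, τ) · ½ [S′(t) − μ − (S(t) − y − μ(t−τ))/(t−τ)].

The system is discretized by a product rectangle rule on a uniform grid
(default dt = 1 ms; the solver refuses dt > 2 ms). The diagonal kernel
vanishes in the τ → t limit and is omitted. The inner double loop is
numba-compiled; drift variability v ~ N(v, η²) is marginalized with 7-node
Gauss–Hermite quadrature. Where b(t) falls below a stability floor of 1e−4
(full collapse), the solver stops and assigns all surviving probability to
that step, split 50/50 between the bounds (the surviving state is confined
to a vanishing band around 0, so commitment there is at chance; with
non-zero drift the residual asymmetry is of order the floor and negligible).

Validation (in the test suite): absorption probabilities and defect
densities match the constant-bound closed forms (absorption probability
formula and the large-time series solution) to <1e−3; solver and
Euler–Maruyama simulation agree to Kolmogorov–Smirnov distance <0.01 at
n = 10⁵ on flat, asymptotic-logistic, and full-collapse bounds; absorbed
mass + survival = 1 to ±1e−3 across random parameter draws. Single-step
discretization error at the collapse point can produce a pointwise negative
density of order 1e−3·dt; negative mass beyond 1e−3 raises an error, smaller
artifacts are clipped to zero.

## Simulation

Forward simulation uses Euler–Maruyama at dt = 1 ms with noise scaled by
√dt, plus a Brownian-bridge correction for within-step boundary excursions
(without it the simulated RT distribution is biased late by ~O(√dt) and
fails the KS comparison with the exact solver). At full collapse all active
paths commit immediately, choice taken from the sign of the diffusion state
(ties randomized). RT = decision time + non-decision time t_er.

## Likelihood, fitting, model comparison

Trial likelihoods interpolate the FPT grid at (RT − t_er), correct trials on
the correct-bound density and errors on the error-bound density; trials with
RT below t_er score a floor density of 1e−10; censored and missed-deadline
trials contribute the log survival mass beyond the deadline (right-censored;
the source text is silent on missed-trial handling). Free-response trials
with RT > 5 s are excluded. Fitting is Nelder–Mead over a bounded
reparameterization (logit for interval-bounded, log for positive
parameters) with seeded multistart; parameters named in `per_regime` get
independent copies per speed regime (the headline model: urgency shape and
t_er vary by regime, drift and its variability shared). Model classes are
compared per subject with likelihood-based BIC = −2 lnL + k ln n and across
subjects by Wilcoxon signed-rank on paired BIC differences. The
least-squares BIC form n·ln(SSR/n) + k·ln n is reserved for the pupil GLM,
which is estimated by least squares.

## Conditional accuracy functions

Accuracy (0/1) is regressed on RT with the piece-wise logistic model split
at inflection α; β₁ ≥ 0 constrains the left segment to the premature-error
rise. The α grid runs 0.15–1.0 s in 10 ms steps (the grid start is not
specified by the source; 0.15 s covers the plausible premature-response
range), SSE ties break toward smaller α. Whichever segment is fit first
pins β₀, so both orders are run per α and the lower combined SSE kept. The
inner Nelder–Mead uses warm starts propagated along the α grid (one run per
α) plus a 3-restart polish at the winning α; this is numerically equivalent
to 3 restarts everywhere at a quarter of the cost. If no trial falls below
α for any grid value (generated data contain no premature responses), the
left segment is vacuous and a single declining logistic with β₁ = 0 is fit.
Predicted probabilities are clipped to [1e−9, 1−1e−9]. Missed-deadline
trials are retained in deadline-regime fits.

A generate-and-refit oracle (known piece-wise logistic, n = 20,000)
establishes the attainable recovery precision: β₀ and β₂ recover within
±10%, but the SSE profile over α is flat enough that α is identified only
to ±40–50 ms, with β₁ errors up to ~50% through its correlation with α.
The tests assert these oracle-computed bounds; tighter claims would not be
statistically honest at this n.

## Synthetic behavioural data (study conditions)

The generator's frozen defaults define the conditions every downstream
stage is tested under: shared diffusion v = 0.12, η = 0.05, s = 0.1
(fixed scaling), t_er = 0.3 s; deadline 1.4 s. DL urgency has u0 = 0.3 and
reaches the bound exactly at 1.1 s of decision time
(λ = 0.88 s, k = 0.33 s, solved ceiling ≈ 1.40) — misses are structurally
negligible and the fitted CAF lands at chance by the deadline. FR urgency
(u0 = 0.2, k = 0.35, λ = 0.9, ceiling 1) rises more slowly and only
asymptotically, preserving the qualitative orderings: FR is slower, more
accurate, with a far shallower conditional-accuracy decline and most
responses beyond 1.4 s. Trials are independent (the task's
response-to-stimulus interval does not depend on previous-trial RT).

What the generator does **not** emulate: non-decision-time variability,
between-session or between-subject heterogeneity, premature (fast-guess)
errors, sequential dependencies, and lapses. Consequently the FR RT
quantiles sit above typical empirical medians for this paradigm (a
consequence of keeping the drift shared with the spec-pinned DL
configuration and static urgency lower in FR than DL), and the left
CAF segment is vacuous on generated data; passing tests demonstrate correct
inference machinery under the model's own assumptions, not robustness to
these real-data features.

## Pupil generator and GLM

Epochs span −0.2 s pre-stimulus to +2.5 s post-response at 50 Hz (regressor
resolution need not exceed the IRF bandwidth; recordings in this paradigm
are typically 250 Hz). Each trial contributes three unit-height components
on the trial clock — onset impulse, sustained profile over the decision
interval, response impulse — convolved with the unit-peak canonical IRF
(w = 10.1, t_max = 930 ms, truncated at 4 s; the kernel's analytic maximum
is at t_max, which the tests check on a 1 ms grid). Betas carry all
scaling. The eight sustained shapes: (1) boxcar; (2) up-ramp 0→1 across the
trial's decision interval; (3) ramp-to-threshold — fixed shared slope
1/median(RT), common peak 1 at response, clipped at 0; (4) linear decay
with RT-proportional start (RT/median(RT)) ending at 0; (5) decay-to-
threshold — fixed start 1, ending at 0; (6–8) boxcar/up-ramp/down-ramp
divided by the number of samples in the trial's decision interval. The
geometric details of shapes 3–5 beyond their one-line descriptions are this
package's choices. Designs concatenate epochs trial-major with no
inter-trial gaps; an intercept column is included and counted in k.
Optional RT-parametric modulation adds mean-centred-RT-weighted copies of
the onset and response columns.

Model selection fits all shapes per subject and picks the lowest summed
BIC, with Wilcoxon signed-rank tests of every shape against the winner. At
the default noise level (noise_sd = 1.0, roughly half the variance of the
clean trace) the generating shape (boxcar or up-ramp) wins in ≥90% of
seeded cohorts, and the boxcar-vs-upramp decision is invariant to fitting
with IRF parameters perturbed across w ∈ [8, 12], t_max ∈ [800, 1100] ms.

## Gain-modulated LCA

Finite-difference updates at dt = 10 ms (noise is per-step, hence
dt-specific):

    Δxᵢ = −leak·xᵢ + excit·f(xᵢ) − inhib·f(xⱼ) + f(Iᵢ) + N(0, σ),   xᵢ ← max(xᵢ + Δxᵢ, 0),

with transfer f(x) = θ(2Φ(gx) − 1) (linear near 0 as g → 0, step-like as
g → ∞). Commitment when an activation exceeds A. A 0.3 s pre-motion period
runs with inputs off to measure baseline activation. Gain is flat at g_FR
under free response; under deadline g(t) = g0_DL + slope_DL·t from motion
onset (the linear ramp is this package's parameterization of a monotone
gain trajectory; the static offset also applies pre-motion). Recurrent
excitation must exceed lateral inhibition — with a rising gain this
produces building common activation of both accumulators, the
time-dependent-urgency signature.

Defaults (leak 0.06, excit 0.07, inhib 0.05, σ 0.03, A 1, θ 1,
inputs (0.033, 0.026), g_FR 0.85, g0_DL 1.5, slope_DL 2.2) were calibrated
once so that the deadline regime is faster and less accurate with <0.1%
misses, pre-motion activation is elevated under deadline, losing-accumulator
activation at commitment rises across RT bins under deadline but is flat
under free response, and the winner-minus-loser difference shrinks for
slower deadline decisions. They are package defaults, not estimates of any
empirical cohort. The effective accumulation time constant is defined by
linearizing the noise-free baseline dynamics around x* = 0:
τ = dt / (leak − (excit − inhib)·f′(0; g)); at the default constants the
small-gain (leak-dominated) limit is 167 ms and a gain g ≈ 2.6 yields
τ = 555 ms, spanning the short- and long-time-constant regimes of interest.
Behavioural fitting minimizes a quantile chi-square (RT deciles plus
accuracy, per regime) over the gain schedule by seeded multistart
Nelder–Mead with common random numbers — full-width noise draws keep the
simulated noise stream aligned across parameter values, without which the
objective is too rugged for simplex descent.

## Orchestration and statistics

`run_pipeline` runs simulate → CAF → DDM → pupil → LCA with per-stage seeds
derived by stable SHA-256 hashing of the stage name (adding a stage does
not perturb the others), plain-text CSV/JSON outputs, and a checksummed
manifest; reruns with the same seed are byte-identical. `group_stats`
provides two-tailed one-sample t and paired Wilcoxon tests (all-identical
Wilcoxon input returns p = 1 with a warning).

## Problem sizes and tolerances in the test suite

Solver cross-validation runs at n = 10⁵ paths, dt = 1 ms (KS < 0.01).
Recovery studies use: CAF oracle n = 20,000 with 8 replicates for the β₂
criterion; urgency-DDM recovery n = 1,440 trials per subject over 5 seeded
replicates (v and u0 within ±15% median); model recovery 6 subjects × 400
trials per cohort; pupil selection cohorts of 8–12 subjects × 30 trials,
12 cohorts per generating shape; LCA slope recovery 3 seeds at 2,500
observed / 1,200 simulated trials per evaluation (±25% median). These sizes
were chosen to make each statistical claim decidable at its stated
tolerance while keeping the default suite runnable on a single CPU in a few
minutes per module.

## Known limitations

* The exact logistic parameterization of the urgency signal and the
  supplementary fitting objectives of the original analyses are not public;
  the forms here are documented package choices validated by property
  tests, not replicas.
* The renewal solver's 50/50 split of surviving mass at full collapse
  ignores the drift-induced asymmetry of the surviving state (order of the
  bound floor; negligible at the default floor).
* Quantile-based LCA fitting identifies the DL gain ramp only jointly with
  its baseline offset at moderate n; slope recovery is asserted at ±25%.
* Real pupil data require artifact handling (blinks, gaze position,
  luminance) that is out of scope here; the GLM assumes clean, baselined
  epochs.
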