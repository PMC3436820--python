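# Methods

## The estimation problem

Signal-transduction models are coupled ODE systems
dx/dt = f(x(t), u(t), θ_dyn), observed through y(t) = g(x(t), u(t), θ_scale),
where the external stimulus u(t) (a hormone concentration, a phosphorylated
receptor) is itself only measured at a handful of noisy time points.  To
integrate the ODEs, u(t) must be defined for all t; the conventional
("standard") remedy is to pre-fit u(t) by an interpolating or smoothing
spline of the input data, freeze it, and fit the kinetic parameters against
the downstream data alone.  That discards the input measurement
uncertainty: point estimates can be biased and, more importantly,
confidence intervals become systematically too narrow.

`odeinput` implements the joint ("comprehensive") alternative.  The input is
parametrized by the control points v_1..v_N of a natural cubic spline with
knots at the input measurement times — v_i = S(t_i) determines the spline
uniquely — and the maximum-likelihood objective

    chi^2(θ, v) = Σ_ij ((y_ij^meas − y_ij(θ, v)) / σ_ij)^2  +  λ ∫ (S''(t))^2 dt

is minimized over kinetic parameters, scaling parameters, initial
concentrations *and* control points at once.  The first sum runs over all
observables, downstream and input alike; the second term penalizes input
curvature exactly as in smoothing-spline regression, so λ = 0 interpolates
and λ → ∞ forces a straight-line input.  For Gaussian measurement noise
this weighted least-squares objective equals twice the negative
log-likelihood up to a constant, so the minimizer is the MLE.

Because biological stimuli are concentrations (strictly positive) while a
cubic spline can undershoot zero between data points, the spline is built
on the log10-input scale and exponentiated at evaluation time:
u(t) = 10^(S(t)).  All other parameters are likewise estimated on log10
scale inside box bounds (default [−5, 5]).

## Spline algebra

Natural cubic interpolation and evaluation use standard piecewise-cubic
machinery.  The smoothing spline with per-point weights 1/σ_i² is computed
by the Reinsch/Green–Silverman algorithm: with Q, R the usual second-
difference matrices, the roughness integral of a natural spline with knot
values g is g'Kg, K = QR⁻¹Q', and the minimizer solves
(R + λ Q'W⁻¹Q) γ = Q'g for the interior curvatures.  The linear system is
solved for γ at small λ and for λγ at large λ, which keeps both the
interpolation limit and the straight-line limit accurate to machine
precision (the naive normal-equation form loses ~4 digits at λ = 1e12).

Inside the joint objective the penalty is folded into the residual vector
as pseudo-residuals √λ·L'v with K = LL' (eigendecomposition; L has N−2
columns because straight lines are penalty-free), so a single
least-squares backend handles both terms.

The smoothing parameter is chosen once from the input data by a
chi-square discrepancy rule: the largest λ on a 25-point log grid spanning
10⁻⁶..10⁶ whose weighted residual sum stays at or below the median of the
χ²_N distribution.  It is then held fixed during optimization, not
co-estimated — λ is a regularization weight, not a likelihood parameter.
For the simulation study below λ = 0 throughout (interpolation), for both
approaches, so the comparison isolates the effect of propagating input
uncertainty rather than of smoothing.

## Optimization

Trust-region-reflective least squares on the stacked residual vector, with
finite-difference Jacobians (step 1e-6 on the log10 scale, well above the
integrator tolerance so the quotients are clean).  Integration failures
inside the search region return a large sentinel value rather than raising,
which keeps the optimizer away from pathological corners.  Multistart via
Latin hypercube sampling inside the bounds is available for multimodal
problems (the signaling application needs it; the 3-state study does not).
Convergence tolerances default to 1e-10 (step/objective) and 1e-8
(gradient); 1000-iteration cap.

ODE integration uses LSODA with rtol 1e-8 / atol 1e-10.  The built-in
3-state and JAK-STAT networks have numba-compiled right-hand sides
(including inline spline evaluation) because the Monte-Carlo study performs
~10⁵ ODE solves; a generic pure-Python path covers user-defined models and
serves as the cross-check in the test suite.

## Uncertainty quantification

Likelihood profiles: one parameter is walked away from its MLE in adaptive
steps (targeting an objective increase of Δ_α/50 per step, step clipped to
[1e-4, 0.5] log10 units) while all other free parameters — including the
input control points — are re-optimized at every step.  The point-wise
confidence interval at level α is where the profile crosses
chi²(MLE) + Δ_α with Δ_α the α-quantile of χ²₁ (3.841 at 95%); the crossing
is refined by root finding.  A profile that reaches the box bound while
still below the threshold yields an open interval (upper ∞, lower 0 on the
natural scale) — the operational signature of practical
non-identifiability.  The df = 1 point-wise convention is the package
default and configurable; simultaneous thresholds are out of scope.

For the Monte-Carlo coverage study the per-realization intervals default to
the quadratic (Wald-type) approximation of the profile,
θ̂ ± √(χ²₁,α) · se(θ̂), with the covariance (J'J)⁻¹ taken from the
unit-weighted residual Jacobian at the optimum.  Near the optimum of this
mildly nonlinear study the profile is almost exactly quadratic, and the
coverage miscalibration being tested is a property of *which parameters the
covariance includes*: the standard approach's Jacobian simply has no
input-uncertainty columns, which is what shrinks its intervals.  Walking
true profiles for 7 parameters × 2 approaches × 200 realizations would add
nothing but ~100× runtime; `run_study(ci_method="profile")` exists for
spot checks.

## The simulation study

The generator reproduces the reference design exactly:

| quantity | value |
|---|---|
| network | X1 ⇌ X2 ⇌ X3, first forward reaction catalyzed by u(t) |
| rates (k1, k−1, k2, k−2) | 0.01, 1, 0.5, 0.1 |
| initials | (30, 20, 50) — near steady state |
| input | u(t) = 100·exp(−(t−25)²/(2w²)), peak 100 at t = 25 |
| sampling | N = 12 equidistant points on [0, 50] |
| observables | y_i = log10(x_i), y4 = log10(u) |
| noise | additive Gaussian on log10 scale: σ_X = 0.1, σ_u = 0.3 |

The input width w = 7.5 is a package choice (only the peak height and
location are pinned by the design); it is exposed on `StudyDesign`.  Noise
added on the log10 observation scale makes the natural-scale data
log-normal, the usual error model for immunoblot-type protein
quantification.  Per-realization seeds derive from the master seed as
SeedSequence((seed, i)), so realizations are independent, reproducible and
safely parallelizable.

Study defaults: M = 200 realizations (binomial SE ≈ 0.021 for coverage at
α = 0.9 — adequate to resolve the calibration effects; larger M is a flag
away); initial concentrations treated as known so the four rate constants
(plus control points) are fitted, with `free_initials=True` switching to
the seven-parameter layout used for the coverage study; optimizer starts
at the generating parameters with control points at the input-data
interpolant.  The study characterizes the *estimator distribution*, for
which a local search from the truth is the appropriate instrument; global
multimodality is a separate question probed with LHS multistart in the
signaling application.

A caveat the harness itself resolves: at this design (N = 12 samples,
σ_u = 0.3, w = 7.5) the joint MLE of k−1 retains a small finite-sample
bias of about +0.02 log10 units (≈ 5%).  It is invisible at single-fit
standard errors (~0.12) but statistically resolvable at M = 200, where the
Monte-Carlo standard error drops below 0.01; the corresponding
standard-approach bias is about four times larger.  Expect the strict
"mean within 2 MC standard errors of truth" reading to flag k−1 while k2
and k1 pass.

Assessment criteria, per parameter on the log10 scale: accuracy = mean
signed deviation from truth; precision = sample SD (ddof 1); the
trajectory score is the mean squared deviation between fitted and true
observable curves over 500 equidistant time points; coverage = fraction of
realizations whose CI contains the truth, on the α grid
{0.5, 0.6, 0.7, 0.8, 0.9, 0.95}.

What the synthetic study does *not* emulate: real input shapes are not
Gaussian bells, real σ's are estimated rather than known, real sampling is
rarely equidistant, and model error (wrong network) is absent.  Passing
tests therefore demonstrate correct behavior of the estimator under its
own assumptions, not robustness to misspecification.

## The signaling-pathway application

The built-in JAK-STAT model tracks STAT5 phosphorylation driven by
phosphorylated Epo receptor (the input): phosphorylation k1·u·x1,
dimerization k2·x2² (two monomers per dimer), nuclear import k3·x3, and
delayed export k4·x4(t−τ) returning two monomers per dimer to the
cytoplasm, so x1 + x2 + 2x3 + 2x4 is conserved.  Observables are the
immunoblotting sums y1 = s1(x2+2x3), y2 = s2(x1+x2+2x3) and the input
measurement y3 = s3·u, with x(0) = (1,0,0,0) and s3 = 1 fixed to remove
structural non-identifiabilities.

The discrete delay is integrated by the linear chain trick: a cascade of
n first-order compartments with rate n/τ (default n = 8, configurable)
approximates x4(t−τ) with an Erlang-distributed lag, so one stiff ODE
solver handles everything; the chain output is used consistently in both
the export and the return flux, which preserves conservation exactly at
any chain length.  Tests verify convergence of the chain to a direct
method-of-steps delay solution, and reduction to a plain ODE at τ = 0.

Known limitation: with the export flux proportional to the *delayed
nuclear state*, the linearized export dynamics ẋ4 ≈ −k4·x4(t−τ) are
oscillatory-unstable whenever k4·τ > π/2.  Published fits of this pathway
with k4 ≈ 1.5 min⁻¹ and τ of several minutes implicitly delay the import
flux instead.  The built-in model keeps the delayed-state form; users
combining large k4 with long τ should expect (genuine, not numerical)
blow-up, and the package's own pathway tests run at small τ.

Because the quantitative immunoblotting time courses are external data not
shipped with the package, the pathway tests use a clearly-labelled
synthetic surrogate generated from the model itself at literature-scale
parameter values.  The surrogate reproduces the qualitative landscape of
the application: only the monomer/dimer sums being measurable, LHS
multistart finds distinct local minima with the dimerization and
translocation rates switched at a chi-square gap far below the parameter
count, and the nuclear-import rate shows an open (infinite) upper
confidence bound.

## Numerical choices and degenerate inputs

* Observation maps that take log10 of a state clip at 1e-12 and warn; the
  RHS is never clipped.
* Splines continue as constants outside their knot span (integrators may
  step marginally past the last measurement).
* Zero noise levels in the generator produce exact log10 trajectories with
  unit-weight sigmas (σ = 0 would make the weighted objective ill-defined).
* A realization whose fit raises is excluded from *both* approaches (the
  comparisons stay paired) and counted in the summary.
* Profile walks that fail to re-optimize at a point shrink the step and
  retry; four consecutive failures abandon that side, flagged
  "not determined" — distinct from an open interval.
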