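# odeinput

Joint maximum-likelihood estimation of time-dependent input functions and
kinetic parameters in ODE models of biochemical reaction networks.

## The problem

Signaling models are driven by external stimuli — a hormone dose, a
phosphorylated receptor time course — that are measured at a handful of
noisy time points but must be defined for *all* t to integrate the ODEs.
The common workaround pre-fits the input u(t) by a spline, freezes it, and
then estimates the kinetic parameters θ against the downstream data.  This
two-step ("standard") procedure ignores the uncertainty of the input
measurements, which biases estimates and — more insidiously — produces
confidence intervals that are too narrow: true parameter values get
rejected more often than the confidence level promises.

`odeinput` implements the joint ("comprehensive") alternative.  The input
is written as a natural cubic spline parametrized by its control points
v_i = S(t_i) at the input measurement times, on log10 scale so that
u(t) = 10^S(t) stays positive, and a single objective

    chi²(θ, v) = Σ_ij ( (y_ij − y_ij(θ, v)) / σ_ij )²  +  λ ∫ (S''(t))² dt

is minimized over kinetic parameters *and* control points simultaneously.
The data term covers every observable including the input itself; the
curvature penalty plays the role of the smoothing-spline penalty (λ = 0
interpolates, λ → ∞ forces a straight line) and λ is picked from the input
data by a χ² discrepancy rule.  Input uncertainty then propagates into the
parameter confidence intervals, which are computed from likelihood
profiles with the χ²₁ threshold (open intervals flag practical
non-identifiability).

The package is aimed at systems-biology modelers who fit ODE pathway
models to time-course data with measured stimuli, and ships:

* `toy_model()` — a 3-state benchmark network driven by a Gaussian-bell
  stimulus, with the full synthetic-data generator (`odeinput.synthetic`);
* `jakstat_model()` — the Epo-induced JAK2/STAT5 cascade with a discrete
  nuclear residence delay (linear chain trick);
* `OdeMLE` / `EstimationResult` — model/results classes in the
  statsmodels style (`fit()`, `summary()`, `conf_int()`, `profile()`);
* `run_study()` — a Monte-Carlo harness comparing both approaches by
  accuracy, precision, trajectory score and coverage;
* a CLI: `odeinput simulate | fit | profile | mc-study | compare`.

## Worked example

```python
from odeinput import OdeMLE, toy_model, StudyDesign, generate_realization

design = StudyDesign()                         # sigma_X=0.1, sigma_u=0.3, N=12
data = generate_realization(design, seed=42)   # one noisy dataset
mle = OdeMLE(toy_model(), data, approach="comprehensive", lam=0)
result = mle.fit(start={"k1": 0.01, "km1": 1.0, "k2": 0.5, "km2": 0.1})
print(result.summary())
```

```
comprehensive approach MLE  (chi2 = 23.001, 16 free parameters, 1 starts)
parameter          log10     natural   se(log10)     ci95_lb     ci95_ub
k1               -2.0509    0.008895      0.1820    0.003913     0.02022
km1               0.0159       1.037      0.1086      0.6354       1.693
k2               -0.2498      0.5626      0.1294      0.3138       1.009
km2              -1.0138     0.09687      0.1167     0.05721       0.164
v1               -0.1273     -0.1273      0.2998     -0.7149      0.4603
...
v12              -0.3298     -0.3298      0.2962     -0.9103      0.2507
```

The four rate constants land near their generating values
(0.01, 1, 0.5, 0.1) with honest uncertainties; the v_i rows are the
estimated log10 input control points — the reconstructed stimulus is
`result.input_spline()`, and `result.profile("k1")` walks the full
likelihood profile when the quadratic intervals above are not enough.

The same fit with `approach="standard"` freezes the input at its pre-fit
and reports visibly smaller standard errors for k1 and k−1 — smaller than
the actual estimator spread, which is the miscalibration the joint
approach removes.  `run_study(m=200, seed=0)` quantifies this across 200
noise realizations (precision ratios, score distributions and
coverage-vs-confidence-level tables; see `MonteCarloSummary.summary()`).

## Documentation

`docs/methods.md` describes the model class, the spline algebra, the
optimizer and profile-likelihood conventions, the simulation-study design
and its limitations, and the delayed JAK-STAT application.
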