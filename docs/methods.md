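# Methods

## Models

`aquasorb` calibrates three empirical water-adsorption-isotherm equations for
the equilibrium moisture content `X_e` (% dry basis) as a function of water
activity `a_w ∈ (0, 1)`:

- **Peleg**: `X_e = b0·a_w^b1 + b2·a_w^b3` — a double power law; nonlinear in
  its parameters. The two terms are interchangeable, so fitted Peleg
  parameter vectors are only identified up to a term swap; comparisons should
  be made on predicted curves, not raw parameters.
- **Polynomial**: a cubic in `a_w`.
- **DLP** (double log polynomial): a cubic in the transformed variable
  `x = ln(−ln a_w)`, which is strictly decreasing in `a_w` and maps (0, 1)
  onto the whole real line. The transform (and the Peleg powers) are
  undefined at `a_w ∈ {0, 1}`, so the domain is kept strictly open and
  boundary records are rejected rather than clamped.

Temperature enters through the *generalized* forms: each parameter becomes an
affine function of absolute temperature, `b_i → b_i·T + b_i1`, giving eight
parameters per family in the canonical order
`(b0, b01, b1, b11, b2, b21, b3, b31)`. All internal evaluation uses Kelvin;
datasets declare their unit (°C or K) and are converted on ingestion, and the
prediction interface accepts the declared unit. The Kelvin convention matters
for the raw parameter values (an affine reparameterization absorbs any
temperature shift without changing the fitted curves — the package's affine-
invariance property test checks exactly this), so parameter-level comparisons
across tools must agree on the unit.

The Polynomial and DLP generalized families are linear in their parameters;
the N×8 design matrix with columns `[1, T, u, T·u, u², T·u², u³, T·u³]`
(`u = a_w` or `x`) makes the closed-form least-squares solution available as
an independent oracle for the iterative fitter.

## Fitting

The objective is the mean squared error over all pooled replicate records —
replicates are never averaged before fitting; replicate means ± SD are used
only for display. Optimization is Levenberg–Marquardt (MINPACK via
`scipy.optimize.least_squares`, unbounded). The configured tolerance
(default 1e-6) is applied to the objective-change (`ftol`) and step-size
(`xtol`) tests; the gradient test is pinned at 1e-12 so badly scaled problems
are not cut off before the optimum. The evaluation cap (default 600) maps
directly onto MINPACK's `max_nfev`; MINPACK exposes no separate iteration
counter, so the iteration cap (default 400) is enforced as
`max_nfev = min(cap_evals, cap_iters·(M+1))`. Hitting the caps returns the
best-so-far parameters flagged `converged=False` with feedback pointing at
the initial values, rather than raising.

Jacobians are analytic for the linear families (the design matrix itself) and
forward-difference for Peleg. The shipped default initial values are the
calibrated generalized parameters for Achira biscuit adsorption data, one
vector per family; single-temperature fits start from the temperature-
independent entries. They are defaults, not priors — any vector can be
supplied.

Inference is standard nonlinear least squares: `cov = s²(JᵀJ)⁻¹` with
`s² = SSE/(N−M)` at the optimum, Student-t confidence intervals (95 % by
default) and two-sided t-tests on N−M degrees of freedom. A singular JᵀJ
produces infinite standard errors and a collinearity warning instead of an
exception. Fewer than two distinct temperatures cannot identify the
generalized temperature slopes and raise an identifiability error up front.

## Validation

Goodness of fit: MSE, RMSE (= √MSE), R² in percent and
`R²_adj(%) = 100 − ((N−1)/(N−M))·(100 − R²)`. R² is computed in the
conventional form `100·(1 − SS_res/SS_tot)` with `SS_tot = Σ(X_e − X̄_e)²`;
a variant with the predicted-value denominator exists behind an explicit
opt-in for comparison but is not on a percent scale and is used nowhere else.
R² is undefined for constant observations (zero total variance); the metric
raises, and a fit on such data records NaN goodness with a warning. A
calibration is **validated** when R²_adj strictly exceeds the threshold
(default 98 %); the boundary case counts as a failure, which returns
structured feedback (revisit initial values, or the model choice).

Residual screens, applied to the pooled residual vector:

- **Ljung–Box** `Q = N(N+2)·Σ_{k≤h} ρ̂_k²/(N−k)` against χ²(h), with
  `h = min(20, N−1)` by default (computed via statsmodels). Constant
  residuals have undefined autocorrelation and raise.
- **Lilliefors**: `D = sup|ECDF − Φ((x−μ̂)/σ̂)|` with moments estimated from
  the sample. P-values come from a seeded Monte-Carlo simulation of the null
  (default 5000 draws, cached per sample size), giving deterministic,
  table-free p-values with resolution 1/(reps+1); the statistic itself is
  cross-checked against statsmodels in the test suite. Both screens default
  to α = 0.05.

## Synthetic campaigns

The generator emulates a DDI acquisition: a regular a_w grid from 0.10 to
0.80 with 76 points (a little above one point per 0.01 of a_w), three
replicates, temperatures 25/35/45 °C, and additive homoscedastic Gaussian
noise with SD 0.15 % d.b. — the scale of the fitted RMSE values these
campaigns produce. Negative moisture draws are clipped to zero (counted and
logged). Everything is seeded; per-replication seeds in
`recovery_experiment` are spawned from one root seed.

What it does **not** emulate: DDI non-equilibrium artifacts and drift,
replicate-specific a_w grids (real replicates do not share exact a_w values;
the plotting code groups within a 0.005 tolerance for mean ± SD display, but
synthetic replicates share the grid exactly), heteroscedastic or correlated
noise, and desorption/hysteresis. Passing tests therefore demonstrate the
statistical machinery under a correctly specified model with independent
Gaussian noise — not robustness to instrument pathologies.

Monte-Carlo problem sizes used by the test suite and the acceptance script —
100 replications for the mean fitted RMSE, 500 for CI coverage, 1000 null
replications for the empirical size of each residual test, 200 random
datasets for the LM-vs-closed-form oracle — keep each run in the seconds
range while leaving the binomial noise on estimated rates well inside the
asserted bands (e.g. coverage SE ≈ 1 % at 500 replications against a
[92 %, 98 %] band).

## Design choices and limitations

- Degrees of freedom N−M everywhere (s², t, CIs) — the conventional choice.
- Record order: fitted parameters are invariant to permuting the input rows
  up to QR round-off; with Kelvin-scale design columns the design's condition
  number makes ~1e-12 relative differences possible, so tests assert
  permutation invariance at 1e-9.
- The acceptance verdict and residual screens operate on the pooled residual
  vector; per-temperature screening is possible by passing subsets.
- No weighted/robust regression, no global or metaheuristic initialization:
  a poor starting vector for Peleg can end in a local minimum, which is what
  the non-convergence feedback loop is for.
- Column aliases for ingestion are deliberately permissive
  (case/whitespace/underscore-insensitive); decimal commas are rejected with
  a pointed message because mixed-locale spreadsheets are a recurring source
  of silent corruption.
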