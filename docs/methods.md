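# Methods

This note records the modelling assumptions, numerical choices and default
conditions the package ships with, and what its synthetic validation does and
does not establish.

## Perceptual model

The 3-level binary-input HGF tracks a Bernoulli tendency `x2` whose random
walk has step variance `exp(kappa2 * x3 + omega2)`, and a log-volatility `x3`
with step variance `exp(omega3)`.  Trial-wise inversion gives, per trial, a
prediction (`muhat1 = s(mu2')`, `sigmahat1 = muhat1(1-muhat1)`,
`sigmahat2 = sigma2' + v2` with `v2 = exp(kappa2*mu3' + omega2)`) and a
posterior (`sigma2 = 1/(1/sigmahat2 + sigmahat1)`,
`mu2 = mu2' + sigma2 * delta1`, and the level-3 update driven by the
volatility prediction error `delta2` with weight `w2 = v2/sigmahat2`).

Two variants of the level-3 update are implemented:

* `standard` (default): `pi3 = 1/(sigma3' + exp(omega3)) +
  (kappa2^2/2) * w2 * (w2 + (2 w2 - 1) delta2)`,
  `mu3 = mu3' + (kappa2/2) (w2/pi3) delta2`.  Any non-positive `pi3` (or
  numerical overflow anywhere) marks the whole parameter vector inadmissible —
  it is reported, never clipped, because silent repair would warp the
  likelihood surface that the optimiser and the evidence integrate over.
* `ehgf`: a stabilised construction in which the level-3 *mean* is updated
  first using the predicted precision
  (`mu3 = mu3' + (kappa2/2) * sigmahat3 * w2 * delta2`) and the precision
  update then re-evaluates the volatility weight at the updated mean.  This
  is this package's construction of the "enhanced" update family; the default
  remains `standard`, and all shipped analyses use it.

Free perceptual parameters are `omega2` and `omega3` only.  `kappa2 = 1` and
the initial beliefs (`mu2_0 = 0, sigma2_0 = 0.1, mu3_0 = 1, sigma3_0 = 1`)
are fixed configuration, so the richest model (M1) has exactly nine free
parameters: two perceptual plus seven response-side.

## Response models and likelihood

Choices follow the unit-square sigmoid in `muhat1` with inverse decision
temperature `zeta`; log RTs follow trial-wise Gaussian GLMs (informed family
M1–M4, uninformed family M5–M7).  The combined log-likelihood is the sum of
the two streams (conditional independence given the beliefs).  Conventions:

* RTs are stored in seconds; GLMs operate on `log(rt * scale)` with
  `scale = 1000` (log-milliseconds) by default.  The unit only shifts the
  intercept `beta0`.
* Trial 1 has no previous outcome: the surprise regressor is set to 1 bit
  (the surprise of a uniform prediction) and the two-intercept model (M7)
  uses its post-correct intercept `a`; M7 also falls back to `a` when the
  previous response is missing.
* Ignored trials (no response) contribute no likelihood term, but their
  inputs still drive belief updating.  Irregular trials (RT < 0.1 s)
  contribute only the choice term.
* `muhat1` is clamped to `[1e-8, 1 - 1e-8]` inside likelihoods only, never
  inside the filter, and choice log-probabilities are computed in log space.
* Simulated RTs are drawn from the untruncated Gaussian (the likelihood is
  untruncated); an optional flag clips them to the response window for
  display purposes.  Simulated datasets carry no ignored/irregular flags —
  those are data-quality annotations applied when reading real recordings
  (`read_trials` flags any RT below 0.1 s).

`Sigma` is a *variance* (the Gaussian on log RT has variance `Sigma`); anyone
comparing raw `beta0`/`Sigma` magnitudes against other parameterisations
should check this convention first.

## Task design and adjusted correctness

The default design is 160 trials of complementary two-option reward
probabilities: a 40-trial stable block at 0.8, four rapid-switch volatile
blocks (0.2/0.8 alternating every 10 trials), a 20-trial stable block at 0.2,
a 30-trial unpredictable block at 0.5, two more volatile switches, and a
closing stable block at 0.8.  The response window is 1.7 s.  All of this is
user-configurable; the default reproduces the qualitative phase structure of
the original task, whose exact numeric trajectory is not published.

Adjusted correctness rescales percent correct by the maximum achievable under
the probabilistic schedule — the count of trials on which the objectively
more probable option was rewarded (122 of 160 for the original fixed
sequence; recomputed per realised sequence here).  Trials at p = 0.5 have no
more probable option; they count their realised outcome towards the maximum,
so the scale never punishes what no observer could predict.  Values are
capped at 100%.  Inclusion rules: at most 10 ignored-or-irregular trials,
adjusted correctness at least 65%, task complete.

## Priors

Default ("initial") priors, in estimation space: `omega2 ~ N(-3, 16)`,
`omega3 ~ N(-6, 16)`, every GLM weight `~ N(0, 4)`,
`log Sigma ~ N(log 0.01, 2)`, `log zeta ~ N(log 48, 1)`.  These are
toolbox-style defaults kept as configuration; the zero mean on GLM weights is
load-bearing for the post-hoc t-tests (which test posterior means against the
initial prior mean of 0).

Empirical priors are elicited from an independent pilot cohort in two steps:
fit every pilot subject under the initial priors, then set the new prior mean
and (diagonal) variance to the robust location/scatter of the pilot MAP
matrix via FAST-MCD (subset size `h = floor((n+p+1)/2)`, standard reweighting
step; rows are canonically sorted first so the estimate does not depend on
subject order, and a near-degenerate scatter falls back to plain moments).
Only the diagonal is kept because priors are independent normals; a variance
floor of 1e-4 prevents degenerate point priors from small pilots.  This is
deliberately *not* empirical Bayes on the analysis data — the pilot set is
independent.

## Inversion numerics

* Optimiser: BFGS per start with central-difference gradients (step 1e-5 in
  estimation space), `gtol = 1e-5`, at most 500 iterations.  Start 1 is the
  prior mean; the rest are prior draws from a dedicated per-(subject, model)
  stream, so fits are order-independent and reproducible.  Non-converged
  starts are kept but only converged ones can win; ties go to the first
  found.
* Inadmissible parameter vectors evaluate to +inf in the public negative log
  joint; inside the optimiser the value is capped at 1e10 so finite
  differences stay representable.
* Hessian: central second differences with per-parameter step
  `1e-3 * max(1, |x|)`; non-positive-definite Hessians are repaired by
  escalating diagonal jitter (1e-8 to 1e-2 of the mean diagonal magnitude)
  and flagged on the fit.
* LME constants follow the Laplace formula exactly; absolute values may
  differ from other implementations by a constant, which cancels in model
  comparison.

## Model selection

The random-effects scheme follows the Dirichlet-multinomial variational fixed
point (`g_nk ∝ exp(L_nk + psi(alpha_k) - psi(sum alpha))`,
`alpha = alpha0 + sum_n g_n`, iterated to `|d alpha|_inf < 1e-6`).  The free
energy F1 of this model is the standard variational expression (expected log
joint plus entropies); the null free energy F0 — all models equally frequent —
is exact: `sum_n [logsumexp(L_n) - log K]`.  `BOR = 1/(1+exp(F1-F0))` and
`PXP = (1-BOR) XP + BOR/K`.  XP uses 1e5 Dirichlet draws by default; the K=2
Beta closed form serves as a test oracle only.  Family inference assigns each
model `alpha0 = 1/|family|` (uniform prior mass per family) and aggregates
member frequencies per posterior draw.

## Validation battery and the scales used

The shipped test battery runs the full logic at reduced scale, chosen so the
whole suite completes comfortably on one CPU; the same functions scale to the
full protocol (100 simulations per model, 400 starts, 5000 meta-datasets) via
their arguments or the `recover` CLI command:

* parameter recovery: 30 synthetic subjects per model, 40-start fits, all
  seven models; Pearson r between true and estimated values in estimation
  space.  The informed family's advantage for meta-volatility recovery is
  asserted as an ordering (mean `omega3` r over M1–M4 above M5–M7), not as
  specific coefficients, which depend on prior width and scale.
* model identifiability: the M1/M5/M6 subset at 20 simulations per
  generator, 40-start fits; winner confusion matrix and balanced accuracy
  against a simulated chance bound.
* family recovery: 200 meta-cohorts of 60 subjects resampled from the
  identifiability evidences with uniformly drawn true mixtures.
* posterior predictive checks: 100 posterior draws per subject; adjusted
  correctness coverage and residual noise-variance recovery.

The chance bound for balanced accuracy is provided two ways: `binomial`, the
one-sided upper quantile of a *single* per-class recall at p = 1/K (for K=7,
n=100 at the 90% level this gives 0.19), and `simulation`, the quantile of
the full balanced accuracy under uniformly random winners, which averages
over classes and is tighter.  The constructions disagree by design; both are
exposed and the battery uses the simulation bound for its own K and n.

## What the synthetic data do and do not show

The generator draws parameters from the model's own priors, uses fresh
Bernoulli outcomes from the fixed probability schedule per synthetic subject,
and produces responses from the exact likelihood.  Passing recovery therefore
demonstrates *internal* consistency: the inversion machinery identifies
parameters and models when the generative assumptions hold.  It does not
establish that human data satisfy those assumptions — real RT distributions
are bounded by the response window and left-truncated by motor limits, real
choices exhibit sequential effects outside the model class, and real
parameter dispersion need not match the priors.  Analyses of an empirical
cohort should additionally rely on the posterior predictive checks and
residual diagnostics.

## Analysing an empirical cohort (recipe)

1. Export trials to the CSV schema (`subject_id, trial, u, y_bin, y_rt_s,
   ignored, irregular`; seconds; missing responses empty) and load with
   `read_trials`; apply `qc_filter` per subject.
2. Elicit empirical priors from a held-out pilot subset with
   `elicit_empirical_priors` (per model), inspect `prior_predictive`.
3. Fit all seven models per subject (`fit_dataset`, 400 starts for the full
   protocol), collect the evidence matrix.
4. Family-level then model-level selection (`family_bms`, `rfx_bms` +
   `bor_pxp`).
5. For the winning model: `beta_ttests` on the GLM-weight MAP table
   (Bonferroni across weights), `posterior_predictive` and `rt_residuals`
   per subject, `group_summary` for cohort traces, and `phase_anova` on
   phase-averaged log RTs (subjects treated as independent observations per
   phase — a fixed-effects simplification, noted as a limitation).

## Known limitations

* Only MAP + Laplace inference; no MCMC/variational posteriors, no
  simulation-based calibration.
* No sequential-sampling (drift-diffusion) RT models; no truncated or
  shifted log-normal RT likelihoods; choice and RT are conditionally
  independent given beliefs.
* `kappa2` and initial beliefs are not estimable.
* The phase ANOVA ignores the repeated-measures structure.
* KDE summaries use scipy's normal-reference bandwidth.
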