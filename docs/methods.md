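# Methods

## Task model

The task engine simulates a two-armed adaptive probabilistic reversal task.
Defaults: 120 trials; the currently "good" stimulus wins with probability
0.70 (loses 0.30), the bad one wins with 0.40; feedback is ±0.20 €.  A
correct-choice streak counter increments on each choice of the good stimulus
and resets to zero otherwise.  At the end of every trial whose post-update
streak is at least 4, a hazard draw below 0.25 reverses the contingencies
and resets the streak — the draw is repeated on every subsequent qualifying
trial, not only on the first.  Under this timing a reversal cycle for a
perfect player lasts 3 + Geometric(0.25) trials (mean 7, ≈17 reversals per
session), while agents at study-typical parameters trigger ≈6–7; both
follow from the same rule.  Each session consumes a single seeded generator
in a fixed order (choice draw if the agent is stochastic, feedback draw,
hazard draw when qualifying), so every session is bit-reproducible.

Missing trials are representable (`choice = None`); they contribute nothing
to likelihoods or behavioural statistics and freeze the learner's value
state.

## Learning models

The model family crosses {single-update, double-update} × {choice
sensitivity β, reinforcement sensitivity with one ρ or separate ρ_win /
ρ_loss} × {one or two learning rates} — 12 variants, plus a zero-parameter
coin-flip baseline used for reference likelihoods.  Values start at
Q₀ = (0, 0).  The chosen option's value moves toward the scaled outcome
r (= ρ_outcome, or ±1 with free β) by learning rate α; double-update
additionally moves the unchosen value toward −r.  With both options updated
symmetrically from a symmetric start the two values remain exactly
anticorrelated, which is the sense in which feedback for one stimulus is
informative about the other.  Choice follows a logistic in the value
difference with slope β ≡ 1 for reinforcement-sensitivity models (ρ and β
are not jointly identifiable).

Fitting operates on transformed parameters: logit for learning rates, log
for β, identity for ρ.  The likelihood recursion and its analytic gradient
(forward accumulation of ∂Q/∂θ) are numba-compiled; a plain-Python replay
path (`update_values`, `choice_probability`, `trial_latents`) serves
readability, latents and tests.

## Hierarchical estimation

Subjects are fitted by MAP under a diagonal Gaussian empirical prior in
transformed space, maximized with L-BFGS-B (analytic gradients, bounds ±16
on logit/log parameters, ±60 on ρ).  Multi-start: the prior mean plus
`n_restarts − 1` prior draws (default 5 starts).  The Hessian of the
negative log joint at the optimum — central finite differences of the
gradient, step 1e-4 — gives the Laplace posterior covariance; non-positive-
definite curvature is flagged and pseudo-inverted.

The EM loop alternates per-subject MAP fits (E) with moment updates of the
prior (M): μ = mean of MAPs, σ² = mean(MAP² + posterior variance) − μ²,
floored at 1e-6 with a warning.  From the second iteration onward each
subject warm-starts from its previous MAP (plus the prior mean) rather than
re-running the full multi-start — the posterior moves little between
iterations and this cuts the E-step cost several-fold.  Convergence:
relative change of the total log joint below 1e-3 (≤ 200 iterations).
Per-subject optimizer seeds are keyed on subject identity, so group fits are
exactly invariant to subject ordering.  The total log joint can in principle
dip slightly across iterations because the M-step variance update includes
the Laplace correction; the tests allow small non-monotonicity.

The integrated BIC uses K = 2000 Monte-Carlo draws from the fitted prior
(log-sum-exp; K < 100 warns), counts hyperparameters as two per parameter
(mean and variance), and penalizes against the total number of responded
choices.  Model comparison ("joint" pooling, or one prior per wave) reports
ΔiBIC against the winner and records per-spec failures instead of raising.

## Recovery studies

Parameter recovery draws subject parameters from a prior, simulates
sessions, refits with the full EM machinery (no shortcut likelihoods) and
correlates truth with refit on the natural scale (Pearson, with Spearman
alongside).  Behavioural recovery re-simulates each subject at their MAP
and correlates simulated against observed summary behaviour across
subjects.  In the adaptive design the stay probabilities recover strongly
while accuracy and reversal counts have compressed true-score variance
(the task difficulty tracks ability), so their simulated–observed
correlations are positive but modest — the same pattern the empirical
literature reports for adaptive tasks.  Model recovery simulates cohorts
per generating model and tabulates iBIC winners.

## Behavioural statistics

Stay is `choice(t) == choice(t−1)` conditioned on the feedback valence at
t−1; the first trial and pairs touching a missing trial are excluded.
Accuracy is the proportion of responded trials choosing the currently
better stimulus, regardless of feedback.  Development is modelled by
mixed-effects logistic regressions — `stay ~ Session × Valence +
(1 + Session | Subject)` (one joint model across valences, valence reference
"loss") and `accuracy ~ Session + (1 + Session | Subject)` — with Session a
raw numeric 1/2/3 covariate.  Estimation is delegated to lme4 via
`Rscript` (CSV in, JSON out); on convergence failure or a singular fit the
random structure falls back from correlated to uncorrelated to
intercept-only, and the structure actually used is recorded on the result.
Shrunken per-subject predicted probabilities (`predict` with random
effects) provide the "estimated" accuracy/stay values used downstream.

Cumulative alcohol consumption is the trapezoid rule over grams/week
against elapsed weeks (52.1775 weeks/year), by default over the nominal
0/2/4-year wave spacing; exact per-subject visit times can be supplied.
Change-score analyses correlate wave-3 − wave-1 differences with cumulative
consumption (Pearson; at least 3 complete pairs required).

## Latent growth curve model

AUDIT scores at the three waves load on a latent intercept (1, 1, 1) and
slope — loadings (1, 2, 3) as specified in the study figure, with (0, 1, 2)
available for sensitivity checks — plus per-wave regressions γ_t on a
time-varying covariate and wave-specific residual variances.  Outcome and
covariate are z-scored by default so γ_t is on a correlation-like scale.
The multivariate-normal likelihood is maximized directly: the linear
parameters (latent means, γ) are profiled out by GLS at each step, and
Nelder–Mead searches the six covariance parameters; variances are
*unconstrained*, so inadmissible solutions (negative latent or residual
variances, out-of-range latent correlation — the classic sign of a poorly
fitting growth model) are detected and flagged rather than hidden.
Standard errors come from the observed information (finite-difference
Hessian over the full parameter vector); 95% CIs are ±1.96 SE.  Missing
data: listwise deletion by default, full-information ML over missingness
patterns as the fidelity mode.  In the zero-residual limit the likelihood
is unbounded and the latent covariance block is only weakly identified at
finite optimizer tolerance; means and residual variances remain exact, and
the tests assert exactly that.

## fMRI regressors and reliability

Per-trial regressors: the fitted model's choice probability of the actual
choice (interpretable as decision confidence), a below-chance flag
(choice probability strictly < 0.5), and prediction-error traces computed
with outcomes coded ±1 while keeping the subject's fitted learning rate —
fixing the sensitivities isolates learning-rate effects and avoids scaling
degeneracies in BOLD regressions.  The single-update PE is o − Q_c under an
SU trace; the "DU-unique" regressor subtracts it from the chosen-option PE
under a DU trace, isolating the influence of counterfactual updating
history (it is exactly zero until the agent first switches).  The
alternative reading — the unchosen option's counterfactual PE — is
available behind `du_pe="counterfactual"`.  Export: BIDS-style
`events.tsv` ("n/a" for missing trials) plus per-modulator 3-column text
files.

ICC is the two-way mean-squares decomposition; the default form is
consistency ICC(3,1), with absolute-agreement ICC(2,1) optional (both are
reported in analyses to avoid form ambiguity; the package's values match
pingouin's ICC(C,1)/ICC(A,1)).  Zero between-subject variance degenerates
to 0 with a warning.  Split-half reliability splits odd/even trials
(preserving task-phase balance in a learning task), applies a per-subject
estimator to each half, correlates across subjects and applies
Spearman–Brown 2r/(1+r); subjects on which the estimator is undefined are
dropped and counted.

## Synthetic cohort

The generator emulates the study conditions: 143 subjects × 3 waves.
Population parameter means follow the reported trajectories — α 0.61/0.625/
0.64, ρ_win 2.36/2.49/2.62, ρ_loss −0.77/−0.715/−0.66 — applied on the
transformed scale (logit α), with between-subject SDs 0.8 (logit α), 0.8
(ρ_win), 0.4 (ρ_loss) and equicorrelated across-wave correlation 0.5.
These spreads are generator choices, not reported values: they produce
plausible cohort behaviour (accuracy ≈ 0.56, win-stay ≈ 0.94, lose-stay
≈ 0.5) and realistic parameter-recovery difficulty.  Because the logistic
is nonlinear, the natural-scale mean of α is slightly below the logit of
the wave mean (≈0.02); this is immaterial at the spread used.

AUDIT and grams/week are zero-inflated to reflect the drinking pattern of
mid-adolescent cohorts (about half of 14-year-olds not yet drinking, ~95%
drinking by 18): zero probabilities (0.5, 0, 0) for AUDIT and (0.5, 0.2,
0.05) for grams, with the positive component's moments solved so the
overall wave mean/SD hit the configured targets — AUDIT (0.9, 1.48),
(3.2, 2.87), (4.2, 2.97) as a rounded, zero-floored normal; grams (5.2,
38.7), (24.9, 41.9), (52.3, 61.7) as a log-normal (drinking quantities are
strongly right-skewed).  Rounding and flooring leave small residual biases
well inside sampling error at n = 143.  ROI signals are subject true score
+ wave effect + noise with configurable variance components (defaults
0.6/0.4, i.e. test-retest ICC 0.6).  An optional coupling injects a known
standardized association γ between a chosen measure and AUDIT by mixing
the AUDIT latent with the measure's z-score (√(1−γ²) noise weighting;
|γ| ≥ 1 is rejected as infeasible).  What the generator does **not**
emulate: attrition, response times, smoking/cannabis covariates,
questionnaire item structure, and any real coupling between drinking and
brain signals — couplings exist only as configurable truths for recovery
testing, so passing tests demonstrate pipeline correctness, not
substantive claims about real cohorts.

## Problem sizes and numerical choices

The test suite runs cohorts of 20–143 subjects; the model-selection study
uses 20 replications × 100 subjects × 3 candidate models, parameter
recovery one 143-subject cohort, and the growth-model coverage study 50
replications at n = 143 — sizes chosen to match the study scale where the
claim depends on it and to keep a full run in a few minutes otherwise.
The simulation summary script uses 10,000 random-agent sessions and 1000
model agents per parameter set.

Key constants: variance floor 1e-6 (prior), iBIC draws 2000, EM tolerance
1e-3 (relative), MAP restarts 5, finite-difference steps 1e-4, weeks/year
52.1775.

## Known limitations

* At the printed population mean parameters the double-update model
  reproduces accuracy, reward, and reversal counts well, but simulates
  win-stay slightly above and lose-stay somewhat below the study's
  mixed-model estimates (≈0.98 and ≈0.49 vs ≈0.94 and ≈0.55): a
  homogeneous agent at mean parameters is more deterministic than real
  adolescents, and cohort heterogeneity closes only part of the gap.
* The empirical-prior EM slightly compresses the prior variance relative
  to the generating spread (Laplace posterior variances underestimate
  per-subject uncertainty in near-deterministic regimes), and the prior
  mean of weakly identified parameters (large ρ_win) carries a small
  shrinkage bias.
* The growth model is univariate with exogenous covariates; bivariate
  dual-process growth models are out of scope.
* The GLMM contract is formula + link + random structure; estimates are
  whatever lme4 produces, including its convergence diagnostics.
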