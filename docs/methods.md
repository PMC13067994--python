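# Methods

`cierstates` detects careless/insufficient-effort responding (C/IER) in
intensive longitudinal Likert data — the kind produced by ecological
momentary assessment (EMA) studies, where respondents answer short
questionnaires several times a day — and models how respondents move
between attentive and careless states over continuous time. This note
documents the statistical model, the estimation choices, what the synthetic
data generator does and does not emulate, and known limitations.

## Model

### Measurement mixture (step 1)

Each respondent-by-occasion observation `y_it` (J ordinal items, categories
0..G) is a draw from a two-component mixture. The *attentive* component is a
graded response model (GRM) on cumulative logits,

    P(y_ijt >= g | attentive) = logistic(a_j * theta_it + kappa_jg),

with item discriminations `a_j` (negative for negatively worded items: raw
responses are modelled, nothing is recoded), item thresholds `kappa_jg`
strictly decreasing in g, and the substantive trait `theta ~ N(0, 1)` for
identification. The *C/IER* component is the same functional form with the
content channel removed: all loadings fixed to 1, one threshold vector
shared by all items, and a category-preference trait `xi ~ N(0, sigma2_xi)`.
A careless respondent's answers are exchangeable across items and driven
only by where on the scale they like to click. As `sigma2_xi -> 0` the
component collapses to a single multinomial over categories (pure random
responding); large `sigma2_xi` produces strong person-specific preferences
up to straightlining-like behaviour. Category probabilities are adjacent
differences of the cumulative curve.

Marginal maximum likelihood treats every observation as independent in this
step, with a single global mixing proportion `pi_cier` (the step-1 model
deliberately carries no covariates; those enter in step 3).

### Classification and error (step 2)

Observations are assigned to their modal posterior state, ties going to
attentive. The modal assignment is imperfect, so step 3 treats it as an
error-prone indicator with the fixed 2x2 error matrix

    D[k, l] = P(assigned l | true k),

estimated by total-posterior weighting of the assignments. `D` is computed
globally (not per covariate pattern) and its entries are floored at 1e-10
before entering the step-3 likelihood.

### Continuous-time latent Markov transitions (step 3)

The true states follow a two-state continuous-time Markov chain. Covariates
`z` act on the initial state through a logit model and on the transition
intensities through log-linear models `log q_lk = gamma_0lk + gamma_lk' z`.
Over an interval `delta` the transition matrix is `expm(Q * delta)`,
computed by the closed-form two-state decomposition
`P = Pi + exp(-(q12+q21) delta) (I - Pi)` with stationary rows `Pi`
(agreeing with the general matrix exponential to 1e-12). Intensities are
piecewise constant within an interval and use the covariates at the
destination occasion. The likelihood is a scaled forward recursion over
each respondent's assignment sequence with `D` as the fixed response model;
measurement parameters from step 1 are never re-estimated here. Wald tests
(df = 2, both transition slopes of one covariate) drive backward selection
at alpha = 0.05. Reported transition probabilities default to a 1-hour
interval. Covariates stay on their raw scale. Person-level covariates
repeated over a person's rows inflate the effective sample size; the fitter
warns when it detects a within-person-constant covariate.

## Estimation

Step 1 is EM. The E-step computes, per observation, posterior component
probabilities and within-component quadrature-node responsibilities; the
M-step maximises the expected complete-data log-likelihood per component
with L-BFGS-B (warm-started, analytic gradients, a handful of inner
iterations — a generalized-EM step with a safeguard that never accepts a
worse expected log-likelihood, so the observed log-likelihood trace is
nondecreasing). Thresholds are parameterised as a first threshold plus
log-gaps, keeping category order intact at every iterate;
`sigma2_xi = s^2` is estimated through the common C/IER "loading" `s`,
bounded at 10 (variance 100). Hitting that bound flags a
straightlining-degenerate solution.

Numerical choices that matter:

- **Quadrature.** Latent traits are integrated on an equally spaced grid
  over [-6, 6] with normal-density weights (the C/IER grid is rescaled by
  `s`). Standalone measurement operations default to 61 nodes; estimation
  defaults to 31 nodes, where the residual integration error (~1e-3
  relative per pattern) is orders of magnitude below the reporting
  precision of the estimates and replication studies run about twice as
  fast.
- **Starts.** Random starting values draw loading magnitudes from
  U(0.5, 2.5) (signs from a user-declared wording vector, otherwise
  random), thresholds as sorted standard-normal draws scaled to span about
  +/-2.5, the mixing proportion from U(0.05, 0.30), and `sigma2_xi` from
  U(0.25, 4). A short-run/long-run schedule runs every start for 25 burn-in
  iterations (15 in the study harness) and only the most promising few to
  convergence; the best final log-likelihood wins, and the number of starts
  replicating it within 0.01 is reported as a stability diagnostic.
- **Stopping.** EM stops when the largest absolute parameter change falls
  below 1e-4 or the log-likelihood change falls below 1e-4 (the default
  criterion of standard marginal-ML IRT engines), within 1000 iterations;
  solutions exceeding the cap are recorded as non-converged, which is data
  for the replication summaries rather than an error.
- **Step 3 optimisation.** BFGS from a deterministic near-identity start
  (log-intensities log 0.1, zero slopes, initial-state intercept from the
  first-occasion assignment share), optional jittered multistart, standard
  errors from the inverse observed information (finite-difference Hessian);
  a singular information matrix falls back to a pseudo-inverse and flags
  the model.

Step-1 posteriors for rows with every item missing are the prior mixing
proportions; such rows are dropped from the likelihood and counted.

Two degeneracy flags accompany a fit: a mixing proportion at the 0/1
boundary, and a *majority flip* (`cier_majority_flip`) raised whenever the
constrained component captures more than half of the observations. The
flip arises when large parts of the data carry little item structure
(e.g. when all loadings have decayed to nearly zero late in a study): the
best-likelihood solution then separates weak- from strong-structure
responses and the confirmatory careless-minority reading no longer holds.
The replication harness treats flipped fits like non-converged ones and
summarises the remaining replications, which matches the converged-only
reporting convention of the original studies.

## Synthetic data

The generator reproduces a specific EMA study design: N = 75 respondents,
T = 60 occasions at 1-hour spacing, J = 10 seven-point items, each
respondent-by-occasion observation generated independently, and 10% of
observations careless. Four careless patterns are available — uniform
random responding; strong midpoint preference (0.80 on the midpoint, 0.05
adjacent, 0.025 elsewhere); straightlining (one uniform category repeated
across the row, redrawn independently per observation); and the constrained
category-preference GRM — plus three attentive measurement-model
manipulations: threshold scaling (x0.5 for three random items, x2.0 for
three others) and negative-wording flips for questionnaire-property
studies; exponential loading decay `a_jt = a_j1 * d^(t-1)` for drift
studies; and a 5+5 two-factor trait structure with correlation `rho` for a
configurable share of attentive observations.

**Generating parameters are surrogates.** The empirical parameter tables
this design imitates are not public, so defaults were chosen once to match
the emulated scale's published characteristics and the reported
distributional behaviour of the original simulation studies: attentive
loading magnitudes in [2.0, 3.6] with two negative items and thresholds
spanning roughly [-5, 5] (a highly reliable, homogeneous scale whose items
concentrate on few adjacent categories at any trait value), and a C/IER
component with unit preference variance and narrowly spaced thresholds
(0.75 ... -0.75), giving a marginal careless distribution peaked on the two
extreme categories with light middle mass. Two properties of this regime
are load-bearing and were verified during design: (i) random and
preference-driven careless rows are both far less likely under the
attentive model than under a single blended C/IER component, so the mixture
captures pattern mixes without splitting; (ii) a substantially more diffuse
attentive model (loadings below ~2.5 with thresholds inside +/-2.5) lets
the attentive component absorb half the careless observations at the global
maximum, which contradicts the behaviour the original studies report.

What the generator does *not* emulate: planned missingness (complete data
are generated; the estimator itself handles missing responses), attention
check items, response times, respondent-level carryover in straightlining
(each observation is independent by design), and signal-contingent
timestamp jitter (the mixture step ignores the time axis; transition-model
tests draw their own unequal intervals). Passing tests therefore speak to
the identification and recovery properties of the models under the stated
design, not to robustness against, e.g., informative missingness.

A latent-Markov generator produces state sequences from the step-3 model
(initial logit, covariate-dependent intensities, unequal intervals
optionally uniform on 1-3 h) with responses from the state-specific
measurement models, or error-prone assignment indicators drawn directly
through a known `D` for transition-model inference studies.

## Replication harness

`evaluation.run_study` reruns the three study grids (questionnaire
properties 2x2x3; loading decay {0.99, 0.98, 0.95} x {2, 5, 10} affected
items; factor-structure violation rho {0.8, 0.6, 0.4} x {20, 30, 50}%
affected). Metrics follow the original definitions, including the
non-standard ones: *sensitivity* = correctly identified C/IER among all
observations classified C/IER (a precision), *specificity* = correctly
identified attentive among all classified attentive (an NPV); conventional
recall/TNR are reported alongside. Estimate-based summaries average
converged replications only. The default 10 replications per condition is a
desk-scale choice (50 reproduces the original scale); per-replication seeds
derive from the master seed by counter, so results are independent of
execution order.

## Known limitations

- Straightlining with homogeneous, purely positively worded items is a
  boundary condition for the mixture. The original report shows severe
  downward bias of the estimated C/IER rate there and attributes it to
  category-preference variance estimates beyond the reach of default
  starting values. This implementation's EM (ordered-threshold transform,
  variance bound 100) reliably reaches the large-variance solution, so the
  estimated rate stays near 10% instead; the absorption of extreme
  straightliners by the attentive component shows up as reduced detection
  sharpness rather than a collapsed rate estimate.
- Estimation supports one attentive trait (the application's case);
  two-factor models exist in the generator only.
- No mixture-of-persons clustering on top of the latent chain, no
  proportional (non-modal) step-2 assignment, and no response-time or
  response-style components.
- The Wald-based backward selection inherits the usual caveats of stepwise
  procedures; it is provided because it is the procedure the method
  prescribes, not as a recommendation for confirmatory use.
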