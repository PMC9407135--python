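# Methods

## The causal model

The unit of analysis is a team-period: one five-minute window of a second
half for one team.  Each observation is `O = (W1, W2, W3, A, Y)`:

| variable | meaning | support |
|---|---|---|
| `W1` | period index within the half | 1 … 9 |
| `W2` | substitutes already on the pitch | 0 … 3 |
| `W3` | substitution during the current period | {0, 1} |
| `A`  | substitution in the previous period (treatment) | {0, 1} |
| `Y`  | total team distance, min-max normalised | [0, 1] |

The assumed causal structure: `W1` drives everything (substitutions
accumulate late in the half; distance declines over the half); `W2` and
`W1` confound the treatment; `W3` affects the outcome (a substitution
interrupts play) but, conditional on `W1`, is independent of `A`; all
remaining variation is exogenous noise.  Rows are treated as mutually
independent — within-match serial dependence is deliberately out of scope,
so standard i.i.d. TMLE applies rather than a longitudinal variant.

The target parameter is the average treatment effect
`ψ = E_W[E(Y|A=1,W) − E(Y|A=0,W)]`, identified under positivity
(`0 < P(A=1|W) < 1` in every stratum) and no unmeasured confounding.

## The structural simulator

`simulate.SimConfig` holds the structural equations:

* `W1 ~ DiscreteUniform{1..n_periods}`;
* `W2 ~ Binomial(max_subs, expit(b0 + b1 W1))` — substitutes present
  accumulate with the period;
* `W3 ~ Bernoulli(expit(c0 + c1 W1))`, drawn independently of `A` given
  `W1`;
* `A ~ Bernoulli(expit(a0 + a1 W1 − a2 W2))` — more likely late in the
  half, less likely when the bench is already used up;
* `Y_raw = y0 + y1 W1 + y2 W1² + y3 W2 + y4 W3 + y5 A + y6 A·W2 + ε`,
  `ε ~ N(0, noise_sd)`, in meters; `Y` is the dataset-level min-max
  normalisation of `Y_raw`.

Both potential outcomes are evaluated on a shared noise draw, so
counterfactual consistency holds exactly and `true_ate` can compute the
ground truth by direct Monte-Carlo contrast.

### Default calibration

The defaults (`coef_A = (−0.6, 0.32, 1.05)`, `coef_W2 = (−1.2, 0.22)`,
`coef_W3 = (−2.5, 0.25)`,
`coef_Y = (5400, −126, 7, 50, −120, 212, −103)`, `noise_sd = 30` m) were
chosen once to make the simulator a faithful testbed for the
misspecification study:

* team distance declines by several hundred meters over the half, with
  the decline levelling off (negative linear, small positive quadratic);
* treatment prevalence rises from ~27% in the first period to ~52% in the
  last at an overall rate of ~0.40, and every (W1, W2) stratum keeps a
  true propensity inside [0.031, 0.91] — positivity holds by construction
  and the default truncation bound (0.025) never binds on the truth;
* the treatment effect is strongly heterogeneous: a substitution in the
  previous period adds 212 m when no substitutes are yet present but
  103 m less per substitute already on the pitch.  The population ATE is
  ~65 m, i.e. ~0.064 on the normalised scale.  Because the main-effects
  GLM pools these heterogeneous effects with variance-based weights that
  over-represent low-`W2` strata (where the propensity varies most), its
  coefficient on `A` overstates the ATE by ~17% — a qualitative
  reproduction of the GLM-vs-TMLE bias pattern, not of any particular
  magnitude, which would require structural coefficients this package
  defines for itself;
* `W3` predicts the outcome (−120 m) but is not a confounder given `W1`,
  so dropping it ("misspecified" adjustment) leaves the ATE identified:
  the targeted estimators are expected to stay unbiased while the GLM's
  bias persists.

What the simulator does **not** emulate: serial dependence between
adjacent periods of the same match, score/home-away/opponent context
(these live in the unmeasured-confounder node), player-level tracking
noise, or non-Gaussian outcome tails.  Passing the simulation study
therefore demonstrates estimator correctness under the assumed causal
graph, not robustness to violations of it.

## Estimators

### GLM g-computation (`gcomp`)

Identity-link least squares of `Y` on `(1, A, W_adj)`; counterfactual
predictions with `A` forced to 1/0; plug-in average of the contrast.  For
this main-effects model the estimate equals the coefficient on `A`
exactly, so the 95% CI is the OLS Wald interval on that coefficient.  `W1`
enters as a numeric covariate (a single slope), matching its index
interpretation.  Terms of the form `"A:col"` are supported so that a
saturated model on discrete confounders can be requested, in which case
g-computation reproduces the stratified difference-in-means estimator
(property-tested).

### Super learner (`superlearner`, `learners`)

V-fold cross-validation (default V = 10; every observation validates
exactly once; fold sizes differ by ≤ 1, deterministic given the seed).
Squared-error loss for conditional means, negative Bernoulli
log-likelihood for probabilities, probability predictions clipped to
`[1e−6, 1−1e−6]`.  The discrete super learner picks the lowest
fold-averaged risk (ties: lowest library index).  The continuous super
learner solves for convex weights over the library by NNLS on the stacked
out-of-fold predictions followed by an equality-constrained polish
(SLSQP), so the achieved cross-validated loss never exceeds that of any
single learner.  A learner that fails on a fold is replaced by the
marginal-mean learner for that fold; failures are counted, and only a
library that fails everywhere aborts.  Single-learner libraries skip the
CV stage (the weight vector is forced to `[1]`), which keeps fully
parametric runs cheap in replicated studies.

Rosters: `default` (mean, linear, pairwise-interaction linear, full
degree-2 polynomial, spline additive, random forest, tree), `handpicked`
(linear, interaction linear, forward-stepwise AIC with and without
interactions, spline additive, random forest, tree — the classical
handpicked library), plus reduced rosters (`fast`, `fast_handpicked`,
`parametric`) used for replicated studies and fully parametric runs.

### TMLE (`tmle`)

1. Initial `Q̄(A,W)` by regression super learner on `(W_adj, A)`.
2. Propensity `g(1|W)` by probability super learner, truncated to
   `[lb, 1−lb]` with `lb = 0.025` by default (bounds the clever covariate
   at 1/lb = 40).
3. Clever covariate `H = A/g1 − (1−A)/(1−g1)`.
4. One-parameter fluctuation: `ε` is the MLE of the intercept-free
   logistic regression of `Y` on `H` with offset `logit Q̄(A,W)` —
   a single-ε update, matching the one-clever-covariate formulation.
   Initial predictions are clipped to `[1e−6, 1−1e−6]` before the logit.
   The score `mean(H(Y − expit(offset + εH)))` is strictly decreasing in
   ε, so Newton iteration (≤ 100 steps, tolerance 1e−8) converges
   essentially always; a bracketed root-finder is the fallback, and a
   residual score above 1e−6 raises rather than returning a silently
   untargeted estimate.
5. `ψ* = mean(q1* − q0*)` with
   `q1* = expit(logit q1 + ε/g1)`, `q0* = expit(logit q0 − ε/(1−g1))`;
   the logistic scale keeps every targeted prediction inside (0, 1), which
   is the reason the outcome is min-max normalised in the first place.
6. 95% CI from the efficient influence curve
   `D = H(Y − qa*) + (q1* − q0*) − ψ*`: `ψ* ± 1.96 sd(D)/√n`.

The estimator classes follow scikit-learn conventions (constructor
parameters, `get_params`/`set_params`, fitted attributes with trailing
underscores); `SuperLearner` is a regular sklearn estimator usable in
pipelines, while `GComputationATE`/`TMLEATE` take the observation table as
their `fit` input since treatment, outcome and confounders travel
together.

## The simulation study (`experiments`)

`run_simulation_study` simulates `replications` datasets, runs each
estimator under each adjustment set, and aggregates against the
Monte-Carlo truth.  One subtlety: each replicate normalises `Y` by its own
sample min/max, and because Gaussian noise extremes grow with sample size,
the normalised-scale estimand differs slightly between a replicate at
n = 2,000 and a truth sample at n = 10⁶.  The study therefore compares on
the raw meters scale — each replicate's estimate is back-transformed with
that replicate's stored bounds — and divides by the truth sample's range
only for display, so the reported mean ATE and the reported true ATE are
on one common scale.  Bias% uses the true ATE as denominator.  Estimator
failures exclude that replicate for that cell and are counted in the
table.

Default study size is 200 replicates at n = 5,000 (the same order as the
observed dataset); the packaged acceptance checks run 200 replicates at
n = 2,000 with the reduced rosters, which preserves the bias pattern while
keeping a full recomputation in the minutes range on one core.

The positivity diagnostic cross-tabulates `A` within `(W1, W2)` strata
(`W3` is collapsed to avoid sparse thirds) and flags any stratum with an
empty treated or control arm.

`run_observed_analysis` produces the observed-data comparison: each
estimator under both adjustment sets plus exact difference and
difference-% rows (denominator: the correct-adjustment ATE).  The reader
(`io.read_observed`) maps user-named columns onto the canonical roles via
a YAML-configurable schema, drops and counts incomplete rows, rejects
non-binary `A`/`W3` loudly, auto-detects whether the outcome column is raw
meters or pre-normalised (any value outside [0, 1] ⇒ raw, logged), and
normalises over the loaded dataset as a whole.  Exclusion rules applied
upstream of such a file (removed matches, extra time, goalkeepers, first
halves) are assumed already applied; the reader performs no match-level
filtering.

## Seeds and determinism

Every operation takes an explicit seed; study runners derive child seeds
for data draws, CV folds and stochastic learners from one master seed via
`numpy.random.SeedSequence`.  Two CLI runs with identical arguments
produce byte-identical output files (CSV floats are written with `%.17g`,
which round-trips IEEE doubles).

## Known limitations

* The influence-curve CI treats the super-learner fits as fixed; no
  cross-fitting (CV-TMLE) is implemented, so coverage can degrade with
  very aggressive learners at small n.  The packaged coverage study
  (randomised treatment, n = 2,000) attains ~95%.
* One fluctuation covariate targets the ATE only; no CTMLE, IPTW/AIPW
  comparators, or longitudinal extensions.
* The min-max normalisation makes the estimand scale dataset-dependent;
  the raw-scale back-transform (`estimate × (y_max − y_min)`) is exact but
  inherits the sample-extreme dependence described above.
* Simulation ground truth uses the population min/max estimated from the
  same Monte-Carlo sample; with a degenerate (constant) raw outcome the
  normalised scale is undefined and values are mapped to 0.5.
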