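# soccertmle

Doubly robust causal inference for soccer substitutions: does a substitution
in the previous five-minute period increase the total distance covered by
the team in the current period?

Answering this from observational match data requires more than a
regression coefficient.  `soccertmle` implements the full estimation
pipeline for the average treatment effect (ATE)

```
ψ = E_W [ E(Y | A=1, W) − E(Y | A=0, W) ]
```

of a previous-period substitution `A ∈ {0,1}` on min-max normalised team
distance `Y ∈ [0,1]`, adjusting for the confounders
`W = (W1, W2, W3)` — the period index within the half, the number of
substitutes already on the pitch, and whether a substitution happens in the
current period.  Three estimators are provided:

* **GLM g-computation** — an identity-link least-squares outcome model
  `E[Y|A,W] = β0 + β1 A + β2'W`; predict each row under `A=1` and `A=0`
  and average the contrast (which for this main-effects model equals `β1`).
* **TMLE** — targeted maximum likelihood: an initial super-learner fit of
  the outcome regression is fluctuated along the clever covariate
  `H(A,W) = A/g(1|W) − (1−A)/g(0|W)` (with `g` the super-learned,
  truncated propensity score) by a one-parameter logistic regression with
  offset, so that the efficient-influence-curve score equation is solved.
  Inference comes from the empirical variance of the influence curve.
* **TMLEH** — the same with a "handpicked" base-learner library
  (linear models with and without interactions, forward-stepwise AIC,
  spline additive model, random forest, decision tree).

The super learner (V-fold cross-validated convex ensembling with NNLS
weights over a pluggable learner library) is implemented from scratch, as
is the targeting step.  A structural simulator for the substitution causal
graph generates synthetic match data with known ground truth, which powers
a replicated misspecification study: the main-effects GLM is biased by the
unmodelled treatment-effect heterogeneity (the benefit of a fresh
substitute shrinks as more substitutes are already present), while TMLE
remains essentially unbiased — even when the current-period-substitution
covariate `W3` is dropped from the adjustment set, because the simulator
draws `W3` independently of `A` given `W1`.

## Worked example

```python
import soccertmle as st

cfg = st.SimConfig()                       # calibrated structural defaults
data = st.simulate(cfg, 5000, seed=1)      # one simulated half-season
truth = st.true_ate(cfg, 1_000_000, seed=1)

glm = st.GComputationATE("correct").fit(data)
tmle = st.TMLEATE("correct", random_state=1).fit(data)

print(f"true ATE  {truth.value:.4f}")
print(f"GLM  ATE  {glm.ate_:.4f}  95% CI {glm.ci_}")
print(f"TMLE ATE  {tmle.ate_:.4f}  95% CI {tmle.ci_}")
```

prints (this dataset's normalisation bounds put the ground truth at 0.0731
on its own scale):

```
true ATE  0.0663
GLM  ATE  0.0873  95% CI (0.0828, 0.0919)
TMLE ATE  0.0729  95% CI (0.0692, 0.0766)
```

The GLM overshoots the truth by ~20% because its single `β1` pools
heterogeneous period/substitute-count effects with weights that do not
match the covariate distribution; the targeted estimator lands on the
truth with a valid interval.  Inspecting
`tmle.outcome_model_.weights_` shows the super learner placing ~99.7% of
the ensemble weight on the degree-2 polynomial learner — the only library
member able to represent the quadratic fatigue decline and the
treatment-by-substitutes interaction simultaneously.

The same analysis runs from the shell:

```bash
soccertmle simulate -n 5226 --seed 1 --out observed.csv
soccertmle observed-study --data observed.csv --out results/
soccertmle sim-study --replications 200 --n-per-replicate 2000 \
    --roster fast --seed 1 --out study/
soccertmle positivity -n 100000
```

`observed-study` accepts any per-period CSV with columns
`W1,W2,W3,A,Y` (or a YAML column mapping via `--schema`) and produces the
GLM/TMLE/TMLEH comparison under both the full and the W3-dropped
adjustment sets, including the between-adjustment difference rows.

## Layout

```
src/soccertmle/
  simulate.py      structural simulator + Monte-Carlo ground truth
  learners.py      base-learner library (rosters: default, handpicked, ...)
  superlearner.py  CV engine, discrete/continuous super learner
  gcomp.py         GLM g-computation estimator
  tmle.py          propensity, clever covariate, fluctuation, IC inference
  experiments.py   bias study, observed-data analysis, positivity check
  io.py            observed-data reader/validator, fixture writer
  cli.py           command-line interface
```

See `docs/methods.md` for the model, assumptions, and numerical choices.
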