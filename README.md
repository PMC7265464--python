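# driftlearn

Drift-diffusion decision models with trial-by-trial category-boundary
learning: simulation, sequential choice-bias analysis, and simulation-based
maximum-likelihood fitting for two-alternative olfactory decisions.

## The scientific problem

Rats categorizing binary odor mixtures barely slow down as the task gets
harder, while the same animals identifying faint pure odors slow down a lot
— two very different speed–accuracy tradeoffs from one brain. A standard
drift-diffusion model (DDM), in which the only noise is fast fluctuation of
the momentary sensory evidence, cannot fit both behaviors with one parameter
set. The resolution explored here is *continual learning of the
stimulus-to-choice mapping*: the animal treats the category boundary — the
weights `w = (w1, w2)` and bias `b` that turn accumulated evidence
`s(t) = (s1, s2)` into a decision variable `e(t) = w·s(t) + b` — as volatile
and keeps updating it from reward feedback. Boundary fluctuations cannot be
averaged away by integrating longer within a trial, so they cap the benefit
of evidence accumulation precisely in the mixture-categorization regime.

`driftlearn` is for computational neuroscientists and psychophysicists who
want to simulate, analyze and fit this model family:

* **Diffusion core** — two evidence channels with power-law transduction
  `mu_i = k c_i^beta`, simulated as an equivalent 1-D diffusion against
  constant or collapsing stopping bounds `±theta(t)`, with lapses and
  stochastic non-decision time. Constant-bound first passage uses
  Brownian-bridge-corrected stepping (unbiased crossing detection),
  validated against the closed forms `P(upper) = 1/(1+e^{-2·mu·theta})` and
  `E[t_d] = (theta/mu)·tanh(mu·theta)`.
* **Learning rules** — the confidence-weighted Bayesian rule (Gaussian
  belief over the boundary, probit-likelihood moment matching, AR(1)
  volatility model), a reinforcement-learning point-estimate rule, a
  confidence-free delta rule, and a random-weights control; each in
  weights-only / bias-only / both variants.
* **Behavior metrics** — lapse-scaled cumulative-Gaussian psychometrics and
  the conditional choice-bias statistic
  `ΔC_B(d) = ½[ψ(I | prev correct R, d) − ψ(I | prev correct L, d)]`,
  with stratified-bootstrap confidence intervals and after-error variants.
* **Fitting** — simulation-based maximum likelihood (per-condition Gaussian
  RT and Bernoulli choice kernels; optional sequential-dependency cells),
  common-random-number Nelder–Mead search, and BIC/AIC/AICc comparison with
  log10 Bayes factors.
* **Boundary analysis** — per-trial inferred drifts, Mahalanobis stimulus
  ellipses, and frozen-noise reclassification quantifying why multiplicative
  (weight) fluctuations hurt high-concentration mixtures far more than faint
  pure odors.
* **Synthetic studies** — multi-animal, multi-session datasets with known
  ground truth (the public stand-in for unavailable animal data).

## Worked example

Simulate the confidence-weighted learner on the mixture-categorization task
and measure its trial-history signature:

```python
from driftlearn import build_stimulus_set, make_model
from driftlearn.psychometrics import bias_trend

model = make_model("bayes")
stimuli = build_stimulus_set("categorization")
trials = model.simulate(model.defaults, stimuli, 30_000, seed=7,
                        session_trials=300)
print(trials.groupby("contrast_pct")[["correct", "t_r"]].mean().round(3))

rho, lo, hi, curve = bias_trend(trials, n_boot=100, seed=0,
                                difficulty_values={1: 100, 2: 60, 3: 36, 4: 12})
print(curve.round(4))
print(f"Spearman rho vs previous contrast: {rho:.2f}  95% CI [{lo:.2f}, {hi:.2f}]")
```

Output:

```
              correct    t_r
contrast_pct
12.0            0.554  0.653
36.0            0.665  0.647
60.0            0.773  0.613
100.0           0.952  0.481

   difficulty  delta_cb  n_trials
0           1    0.0147      7088
1           2    0.0364      5708
2           3    0.0455      4991
3           4    0.0693      4190
Spearman rho vs previous contrast: -1.00  95% CI [-1.00, -0.80]
```

Accuracy falls from 95% to 55% as mixture contrast drops from 100% to 12%,
while mean reaction time grows only ~170 ms — the flat chronometric profile
characteristic of categorization. The bias curve shows win-stay behavior
(`ΔC_B > 0` everywhere): after a rewarded choice the model repeats that
direction more often, and the effect roughly quadruples from easy (0.015)
to hard (0.069) previous trials. The negative Spearman correlation against
previous-trial contrast, with a bootstrap CI excluding zero, is the graded
sequential-effect signature of confidence-weighted learning; running the
same analysis on the identification task yields a flat, uniformly positive
curve instead.

A command-line layer mirrors the library:

```bash
driftlearn simulate --model bayes --task categorization --n-trials 10000 \
    --seed 1 --out trials.csv
driftlearn bias-analysis trials.csv --n-boot 200 --out bias.csv
driftlearn fit trials.csv --model bayes --free k,beta,theta0,t_nd \
    --task categorization --out fit.json
driftlearn generate --spec study.yaml --out data/
```

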