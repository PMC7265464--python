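# Methods

This note documents the models implemented in `driftlearn`, the conventions
and defaults chosen where the design was open, the numerical schemes, and
what the synthetic data can and cannot show.

## Decision model

### Transduction and accumulation

Each trial presents a pair of odorant concentrations `(c_A, c_B)` (v/v
fractions). Perceived intensity follows a power law: the mean momentary
evidence rate of channel *i* is `mu_i = k * c_i^beta`, corrupted by Gaussian
noise of unit standard deviation per unit time (`sigma = 1` by convention,
so `k * c^beta` is a signal-to-noise rate and the noise scale is absorbed
into `k`). The two channels are integrated independently into `s1(t),
s2(t)`, and the decision variable is the linear read-out

    e(t) = w1*s1(t) + w2*s2(t) + b .

`(w1, w2)` and `b` are the slope and offset of the *category boundary* — the
mapping from sensory evidence to choice — and are distinct from the stopping
bound. The optimal boundary is `w = (1, -1)/sqrt(2)` (unit norm) and
`b = 0`. A decision is triggered when `e(t)` crosses `+theta(t)` (left) or
`-theta(t)` (right).

Stopping bounds may be constant, linearly collapsing
(`theta(t) = theta0 + theta_slo*t`, floored at 0) or exponentially
collapsing (`theta0 * exp(-t/tau)`). Reaction time adds a stochastic
non-decision component `t_r = t_d + t_ND + eta` with
`eta | t_d ~ N(0, (0.1*t_d)^2)`, floored at zero. Lapses replace the
*choice* (not the decision time) with a Bernoulli draw: with probability
`lapse_rate` the response is right with probability `lapse_right_prob`
(default 0.5). The lapse probability and the lapse side preference are kept
as two separate fields because a one-parameter reading ("lapse rate =
right-choice probability") is also conceivable; both readings are
expressible in this parameterization.

### Simulation scheme

Only the 1-D projection is simulated: `x(t) = e(t) - b` has drift `w·mu` and
diffusion variance `||w||^2` per unit time and is absorbed at
`theta(t) - b` and `-theta(t) - b`.

* **Constant bounds** use Euler proposals at `dt = 1 ms` with
  Brownian-bridge crossing probabilities at both barriers. Bridge detection
  makes a barrier hit inside a step exact (the only approximations are the
  negligible probability of crossing *both* barriers within one step and
  the midpoint assignment of the crossing time, biased by less than
  `dt/2`). Choice probabilities and mean decision times match the closed
  forms `1/(1+e^{-2 mu theta})` and `(theta/mu) tanh(mu theta)` within
  Monte-Carlo error at 1e5 trials (tested). The bridge factor is skipped
  when it is below `e^-30`.
* **Collapsing bounds** use plain Euler at `dt = 1 ms` with the final
  position clamped onto the crossed barrier. If the bound collapses to zero
  the trial terminates with the sign of `x` (fair coin on a tie).
* Trials unresolved at `t_max = 10 s` are forced to the nearer barrier and
  flagged (`capped`); a cap is needed because zero-drift walks against
  constant bounds terminate only almost surely.
* If the bias satisfies `|b| >= theta0` the starting evidence already lies
  beyond a bound and the decision is immediate toward the bias side.
* Every trial's noise stream derives from its own seed (sub-streams of a
  root seed), so simulations are reproducible per trial and likelihood
  surfaces built on frozen seeds are deterministic.

The 2-D accumulated evidence at decision time is recovered by exact
conditional-Gaussian sampling: `s ~ N(mu_vec * t_d, I*t_d)` conditioned on
`w·s + b = e(t_d)`, implemented as projection of an unconstrained sample
onto the constraint line.

Note that the per-trial "inferred drift" `s(t_d)/t_d` used for boundary
visualization is *not* an unbiased estimate of `mu_vec` (the ratio's
expectation differs because `1/t_d` is convex and co-varies with `s`); the
unbiased statement is Wald's identity `E[s(t_d)] = mu_vec * E[t_d]`, which
the tests verify via the ratio-of-sums estimator.

## Learning rules

All rules are notified after every trial with the reconstructed evidence
`s(t_d)`, the decision time, the choice and the revealed correct side
`C* ∈ {+1 left, -1 right}` (signs follow the accumulator convention
`e > 0 -> left`).

### Confidence-weighted Bayesian rule

The learner assumes the true boundary parameters follow an AR(1) random
walk, `w*(k+1) | w*(k) ~ N(gamma_w * w*(k), sigma2_w * I)` (bias channel
with `sigma2_b`), and tracks a Gaussian belief `N(mu_w, Sigma_w)` over
`(w1, w2)`, `(b)`, or `(w1, w2, b)` depending on the variant. The bias is an
appended constant evidence channel equal to 1 before normalization.
Feedback enters through the probit likelihood `Phi(C* * w·s~)` of the
normalized evidence

    s~ = s_aug(t_d) / sqrt(t_d + 1/sigma2_e) ,

where `sigma2_e` is the across-trial difficulty variance, assumed known and
computed by default as the variance of `w_opt·mu_vec` over the session's
stimulus set. The posterior is moment-matched back to a Gaussian. With
`a = sqrt(1 + s~·Sigma·s~)`, `g = C* mu_w·s~ / a` (the decision-confidence
variable) and `z = N(g|0,1)/Phi(g)`:

    mu_w  <- mu_w + (z/a) * C* * Sigma * s~
    Sigma <- Sigma - z*(z+g)/a^2 * (Sigma s~)(Sigma s~)^T

For a probit likelihood these are exact moment identities (verified against
2-D Gauss-Hermite quadrature to 1e-3 and beyond); the Gaussian projection is
the only approximation. The effective learning rate `z/a` is small for
high-confidence correct trials, moderate at low confidence, and large for
high-confidence errors. The Sherman–Morrison form above avoids matrix
inversion and remains valid for singular `Sigma` (zero uncertainty is a
fixed point). After the feedback step the AR(1) transition is applied:
`mu <- gamma_w mu`, `Sigma <- gamma_w^2 Sigma + diag(sigma2_w, sigma2_w,
sigma2_b)`. Its steady-state variance `sigma2_w/(1-gamma_w^2)` serves as the
initial prior; the belief mean starts at the optimal boundary (animals are
trained to proficiency before testing).

Numerics: `z` is evaluated in the log domain (no `Phi(g)` underflow);
`Sigma` is symmetrized each trial and eigenvalue-floored at 1e-12 every 1024
trials as a safety net against float drift over long runs.

### Heuristic rules

* **RL rule**: `w <- w + alpha*(C* - e(t_d)/theta0)*s(t_d)`, then
  renormalized to unit length; `b <- b + alpha_b*(C* - b/theta0)`. With a
  collapsing bound the residual inherits a confidence modulation through
  elapsed time; fast correct decisions (`e = C* theta0`) produce no update.
* **Delta rule**: `w <- w + alpha*(C* - C)*(theta(t_d)/theta0)*s(t_d)`
  (normalized), bias analogous without the evidence factor. The residual is
  zero after correct choices, so only errors teach; there is no confidence
  weighting beyond the bound-height factor.
* **Random weights**: `w ~ N(w_opt, sigma2_rw I)`, `b ~ N(0, sigma2_rb)`
  redrawn independently every trial — matched marginal variability with no
  trial-to-trial memory, hence no sequential effects.

### Leaky competing accumulator (LCA)

A non-learning race control: `ds_i = (mu_i - s_i/tau_leak - w_inh*s_{3-i})dt
+ dW_i` with rectification `s_i >= 0`, Euler-integrated at `dt = 0.1 ms`;
the first accumulator to reach `theta(t)` wins. Lapses, decision bias and
non-decision time follow the diffusion conventions (the bias shifts the two
thresholds antisymmetrically). Constant-bound (8-parameter) and linearly
collapsing (9-parameter) variants exist. The Wiener noise amplitude is fixed
at 1 per unit time; its scale is absorbed by `k`.

## Stimulus spaces and adaptive training

Identification: 4 dilutions (1e-1..1e-4 v/v) x 2 sides, one odorant per
trial. Categorization: minority fractions {0, 0.20, 0.32, 0.44} and
complements at total concentration 1e-1 (contrasts 100/60/36/12%).
Interleaved: the 8 contrast-pairs at each of 4 totals (32 stimuli).
Presentation is uniform i.i.d. Difficulty is ordinal 1 (easiest) to 4.
The common psychometric axis is the signed contrast for mixtures and
`sign * (5 + log10 c)/4` for pure odorants, both spanning [-1, 1].

Training-phase algorithms are implemented for completeness: an
exponentially-smoothed online bias estimate
`b_t = (1-tau) C_t + tau b_{t-1}` (`tau = 0.05`) feeding the logistic
anti-bias side probability `p_R = 1 - 1/(1+exp((b_t-b0)/gamma))`
(`b0 = 0.5`, `gamma = 0.25`), and a difficulty schedule that maps running
performance through `delta = -1 + 2/(1+exp((p_t-p0)/gamma))` (`p0 = 0.95`)
into geometric-tail weights `1 - GeomCDF(i, |delta|)` over difficulty
levels, with the index orientation flipped for `delta < 0` and the geometric
CDF convention `1-(1-p)^i` (support starting at 1). Both running estimates
start at 0.5 (unbiased prior); the `|delta| -> 1` limit concentrates all
mass on one end by continuity.

## Choice-bias statistics

Psychometric curves are lapse-scaled cumulative Gaussians
`psi(x) = l_L + (1-l_L-l_R) Phi((x-mu)/sigma)` fitted by unweighted least
squares (Nelder–Mead; sigma floored at 1e-6, lapses constrained to
[0, 0.5)). The indifference point `I` solves `psi(I) = 0.5` on the
unconditional fit. After-correct conditional curves are fitted per (previous
rewarded side, previous difficulty) cell — mirrored stimuli of equal
difficulty pool into the same cell, justified by the left/right symmetry of
the design and checked by the `bias_symmetry` helper — and

    dCB(d) = 1/2 [ psi(I | prev R, d) - psi(I | prev L, d) ] .

Positive values mean win-stay. After errors the bias change is referenced to
the two-back baseline (choice at T-2 vs stimulus at T-2) conditioned on the
intervening error's side and difficulty; trials whose two-back reference is
itself an error are excluded so that bouts of errors do not contaminate the
baseline. Cells below 50 trials are dropped with a warning. Confidence
intervals come from a trial-level bootstrap stratified by conditioning cell
(200 resamples by default), holding `I` at its full-data value; when joint
coverage across several difficulty cells is asserted, per-cell 99% intervals
are used to control the family-wise error. A nonparametric cross-check
(conditional choice fractions at the stimuli nearest `I`) guards against
fit artifacts.

Two statistical caveats discovered during development and worth knowing:
the mean of per-trial ratios `s/t_d` is a biased drift estimate (see above),
and at near-chance difficulties, conditioning on a previous *correct* choice
selects moments when any slowly-drifting bias already pointed that way —
with large bias volatility this selection inflates `dCB` for hard previous
trials even without any difficulty-dependent learning.

## Simulation-based fitting

Without closed-form RT densities, the likelihood of a parameter vector is
computed from a simulation of the candidate model (default 100,000 trials
per stimulus set; scaled-down values are used in tests). Per condition *m*
(stimulus identity, prefixed by task for joint fits):

* RT term: Gaussian density of the simulated mean RT under
  `N(t_m, (sigma2_t,m + extra)/n_m)` where `extra` adds the non-decision
  noise allowance `(0.1 t_d,m)^2` and the Monte-Carlo variance of the
  simulated mean (`sigma2_t,m * n_m / n_sim,m`). The MC term matters: the
  simulated prediction is itself an estimate, and scoring it as exact lets
  the optimizer chase simulation noise. The data-side variance is used for
  this term because using the model's own variance estimate would let
  high-variance parameter regions soften their own misfit penalty (observed
  as a systematic drift of fits toward slow/noisy parameter regions before
  this was fixed).
* Choice term: the Bernoulli kernel
  `p^(P n) (1-p)^((1-P) n)` with the simulated correct probability clipped
  to `[1/(n_sim+1), 1-1/(n_sim+1)]`; a condition absent from the simulation
  predicts 0.5.
* Sequential mode replaces the marginal choice term with per-cell terms
  (previous difficulty x previous side x current condition) after correct
  trials, and per-condition terms pooled over previous conditions after
  errors (error trials are too few to condition further). For the 32-stimulus
  interleaved task the previous trial is pooled by (difficulty, side), not by
  all 32 identities, to keep cells populated.

Every evaluation reuses one frozen simulation seed (common random numbers),
making the objective deterministic and far smoother than independent
resampling. Simulations are split into independent 300-trial sessions with
the learner reset at each session start, matching the experimental protocol
(daily sessions of 250–400 trials) — this also caps the correlation length
of the learner's slow boundary random walk, whose ~1/(1-gamma_w)-trial
memory otherwise makes per-condition summaries from one long run far noisier
than their nominal trial counts suggest.

Search is Nelder–Mead over transformed parameters (log for positive
quantities, logit for rates/probabilities), multi-start with jittered
initializations when requested. Accurate recovery benefits from a staged
schedule — a broad search at small `n_sim` followed by short polish stages
at larger `n_sim` — because the optimum of a frozen-noise surface is
displaced from the expected-likelihood optimum by an amount that shrinks
with `n_sim`. Joint fitting of both tasks is essential for identifiability:
at a single total concentration only the product `k * c_total^beta` is well
constrained, while the identification task's three-decade concentration span
pins `beta`. In the bundled recovery experiment (1e5 trials, both tasks,
staged fits) the base parameters `k, beta, theta0, t_ND` return within 10%
of their generating values; the residual error is dominated by a shallow
likelihood ridge trading `k`, `theta0` and `t_ND` against one another,
so single-parameter accuracy varies by a few percent across data
realizations.

Model comparison uses `BIC = -2 ln L + q ln n` (`q` free parameters fitted,
`n` data trials), `AIC`, `AICc`, and the BIC-based log10 marginal likelihood
`-BIC/(2 ln 10)`; pairwise differences are log10 Bayes factors with 2 as the
conventional decisiveness threshold. In the bundled model-recovery
experiment the base psychophysical parameters are held at their generating
values and only the learning hyperparameters are fitted, isolating the
learning-rule comparison (which is the scientific question) at a fraction of
the cost; the sequential-mode likelihood is what separates the
confidence-weighted learner from matched-variability controls.

## Boundary-fluctuation analysis

In the plane of inferred drifts the category boundary is the line
`s2 = -(w1/w2) s1 - b/w2` (the zero set of the decision variable). Weight
perturbations rotate the line about the origin, so their effect grows with
the distance of the evidence from the origin; bias perturbations translate
it, affecting all magnitudes alike. The frozen-noise reclassification keeps
each simulated trial's evidence `(s1, s2)` fixed and compares its
classification under the reference boundary with that under per-trial
perturbed boundaries (default SD: the Bayesian learner's steady-state weight
SD). High-concentration mixtures are reclassified several times more often
than low-concentration pure odorants — the mechanism behind the
categorization task's greater vulnerability to boundary learning. Stimulus
clouds are summarized by Mahalanobis D=1 ellipses (for a Gaussian cloud the
enclosed fraction is `1 - e^{-1/2}`, used as a calibration check).

## Synthetic data: defaults and rationale

The animal data this model family was developed on are not publicly
deposited, so all analyses run on synthetic studies with known ground truth.
Default study conditions (one choice, fixed before the validation suite was
finalized):

| Parameter | Value | Notes |
|---|---|---|
| k (sensitivity) | 10 | drift (SNR/s) per unit `c^beta` |
| beta (exponent) | 0.4 | psychometric spans ~0.55–0.95 over the stimulus sets |
| theta0 (bound) | 0.6 evidence units | decision times a few hundred ms |
| theta_slo | -0.2 /s (learning models) | linear collapse; the full learning model is the 10-parameter variant |
| t_ND | 0.25 s | plus multiplicative noise, CV 0.1 of t_d |
| lapse_rate | 0.05 | typical fitted magnitude for this paradigm |
| gamma_w | 0.997 | boundary volatility time constant ~300 trials |
| sigma2_w | 0.30^2 (1-gamma^2) | steady-state weight SD 0.30 |
| sigma2_b | 0.20^2 (1-gamma^2) | steady-state bias SD 0.20 |
| sessions | 250–400 trials, learner reset | daily-session protocol |
| invalid trials | 5.8% dropped, d_odor ~ U(0.3, 0.6) s | early-withdrawal emulation |

The learning hyperparameters have no published point values; they were
calibrated once against the published descriptive phenotype — accuracy
ranges, reaction-time ranges, and the sequential-effect pattern (choice bias
graded by previous contrast in categorization, flat and positive in
identification, with magnitudes of a few percent) — and then frozen. Two
couplings found during calibration are worth recording: the collapsing bound
compresses decision-time (hence confidence) differences across difficulties,
which is required for the identification task's flat bias profile; and bias
volatility must stay moderate or the selection artifact described above
re-grades the identification curve.

Across-animal heterogeneity jitters positive parameters log-normally
(SD 10%), enabling per-animal vs pooled fitting comparisons. Generated
stimulus sequences are uniform i.i.d.; the generator does not emulate
sniff-cycle timing, motivational drifts, satiation, or any within-session
non-stationarity other than the learner itself — so passing tests show the
analysis pipeline is correct and well-calibrated for this model family, not
that real animals obey it.

## Known limitations

* Collapsing-bound simulation is plain Euler (crossings inside a step can be
  missed), biasing decision times by O(sqrt(dt)); both sides of a fit share
  the bias, but comparisons against external closed forms should use the
  constant-bound path.
* The sequential likelihood pools after-error trials per current condition;
  with very few errors (easy-heavy designs) those cells carry little
  information.
* BIC-based Bayes factors inherit BIC's large-n Laplace approximation; with
  simulation noise in `ln L`, differences of a few log10 units near the
  decisiveness threshold should not be over-interpreted.
* The bias-only learner can transiently push `|b|` past `theta0`; this is
  handled as an immediate decision, a regime the original formulation never
  needed to define.
* Fitted parameter uncertainty (standard errors/profiles) is not computed;
  the package reports point estimates and information criteria only.
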