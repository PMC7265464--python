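"""Psychometric fits and trial-history conditional choice-bias statistics.

The psychometric function is a lapse-scaled cumulative Gaussian,

    psi(x) = l_L + (1 - l_L - l_R) * Phi((x - mu) / sigma),

fitted by least squares to the fraction of *rightward* choices at each
stimulus value. The stimulus axis used throughout is ``x_r = -x`` where ``x``
is the trial table's signed stimulus value (positive toward odor A / left),
so psi is increasing and psi -> l_L for strongly-left stimuli.

The sequential-effect statistic Delta C_B conditions the psychometric curve
on the previous trial's rewarded side and difficulty and evaluates the
conditional curves at the indifference point I of the unconditional curve:

    dCB_correct(d) = 1/2 [ psi(I | prev correct R, d) - psi(I | prev correct L, d) ]

Positive values indicate win-stay behavior (a tendency to repeat the
previously rewarded direction). After errors, the change in bias is measured
against the pre-error baseline two trials back, conditioned on the error's
side and difficulty; trials whose two-back reference is itself an error are
excluded to avoid contamination by bouts of errors.

Bootstrap (trial-level, stratified by conditioning cell) supplies confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr, ndtri
from scipy.stats import spearmanr

from .stimuli import LEFT, RIGHT

#: conditional-cell fits with fewer trials are dropped
MIN_CELL_TRIALS = 50


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted lapse-scaled cumulative Gaussian."""

    mu: float
    sigma: float
    l_l: float
    l_r: float
    n_trials: int
    sse: float
    degenerate: bool = False

    def predict(self, x):
        """psi(x): probability of a rightward choice."""
        x = np.asarray(x, dtype=float)
        return self.l_l + (1.0 - self.l_l - self.l_r) * ndtr((x - self.mu) / self.sigma)

    @property
    def indifference_point(self) -> float:
        """Stimulus value I with psi(I) = 0.5 (nan if 0.5 is outside range)."""
        span = 1.0 - self.l_l - self.l_r
        arg = (0.5 - self.l_l) / span if span > 0 else np.nan
        if not 0.0 < arg < 1.0:
            return np.nan
        return self.mu + self.sigma * ndtri(arg)


def _psi(params, x):
    mu, log_sigma, t_l, t_r = params
    l_l = 0.5 * expit(t_l)
    l_r = 0.5 * expit(t_r)
    sigma = np.exp(log_sigma) + 1e-6  # floored so the simplex cannot hit 0
    return l_l + (1.0 - l_l - l_r) * ndtr((x - mu) / sigma)


def fit_psychometric(x, frac_right, n=None) -> PsychometricFit:
    """Least-squares psychometric fit by simplex search.

    ``x`` are distinct stimulus values (>= 4 required), ``frac_right`` the
    empirical rightward-choice fractions, ``n`` the per-value trial counts
    (bookkeeping only; the square distance is unweighted, matching the
    fitting convention for these curves). Lapse rates are constrained to
    [0, 0.5). All-same-choice data yield a flagged degenerate fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(frac_right, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct stimulus values")
    n_total = int(np.sum(n)) if n is not None else len(x)
    degenerate = bool(np.all(y > 0.95) or np.all(y < 0.05))

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # crude initialization: crossing point and dynamic range
    mu0 = float(np.interp(0.5, np.clip(ys, 1e-3, 1 - 1e-3), xs))
    sigma0 = max(0.25 * (xs[-1] - xs[0]), 1e-3)
    p0 = np.array([mu0, np.log(sigma0), logit(2 * 0.02), logit(2 * 0.02)])

    def loss(p):
        r = _psi(p, x) - y
        return float(r @ r)

    res = minimize(loss, p0, method="Nelder-Mead",
                   options={"maxfev": 800, "xatol": 1e-6, "fatol": 1e-10})
    mu, log_sigma, t_l, t_r = res.x
    return PsychometricFit(
        mu=float(mu),
        sigma=float(np.exp(log_sigma)),
        l_l=float(0.5 * expit(t_l)),
        l_r=float(0.5 * expit(t_r)),
        n_trials=n_total,
        sse=float(res.fun),
        degenerate=degenerate,
    )


def _choice_fractions(trials: pd.DataFrame):
    g = trials.groupby("x_r", observed=True)["choice_right"]
    frac = g.mean()
    return frac.index.to_numpy(), frac.to_numpy(), g.size().to_numpy()


def prepare_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the analysis columns: rightward axis, lags within session.

    ``x_r``: stimulus axis oriented toward right choices; ``choice_right``:
    indicator; ``prev_*``: previous-trial attributes; ``back2_*``: two-back
    attributes. Lags never cross session boundaries.
    """
    t = trials.copy()
    t["x_r"] = -t["x"]
    t["choice_right"] = (t["choice"] == RIGHT).astype(float)
    g = t.groupby("session", observed=True)
    for lag, prefix in ((1, "prev"), (2, "back2")):
        for col in ("choice", "correct", "difficulty", "x_r", "choice_right"):
            t[f"{prefix}_{col}"] = g[col].shift(lag)
    return t


def fit_unconditional(trials: pd.DataFrame) -> PsychometricFit:
    """Psychometric fit over all trials (defines the indifference point I)."""
    x, y, n = _choice_fractions(trials)
    return fit_psychometric(x, y, n)


def conditional_psychometrics(trials: pd.DataFrame, outcome: str = "correct",
                              min_cell: int = MIN_CELL_TRIALS) -> dict:
    """Family of psychometric fits conditioned on the previous trial.

    ``outcome="correct"`` fits the current-trial curve per (previous rewarded
    side, previous difficulty). ``outcome="error"`` fits, per (previous error
    side, previous difficulty), both the current-trial curve and the two-back
    baseline curve (choice at T-2 vs stimulus at T-2), excluding trials whose
    T-2 reference is itself an error. Cells below ``min_cell`` trials are
    dropped with a warning. Returns ``{(side, difficulty): fit_or_pair}``.
    """
    want_correct = outcome == "correct"
    eligible = trials[trials["prev_correct"] == want_correct]
    if not want_correct:
        eligible = eligible[eligible["back2_correct"] == True]  # noqa: E712
    out: dict = {}
    for (side, diff), cell in eligible.groupby(["prev_choice", "prev_difficulty"],
                                               observed=True):
        if len(cell) < min_cell:
            warnings.warn(
                f"conditional cell (side={side}, difficulty={diff}) has "
                f"{len(cell)} < {min_cell} trials; dropped"
            )
            continue
        x, y, n = _choice_fractions(cell)
        if len(x) < 4:
            continue
        fit_now = fit_psychometric(x, y, n)
        if want_correct:
            out[(int(side), int(diff))] = fit_now
        else:
            gb = cell.groupby("back2_x_r", observed=True)["back2_choice_right"]
            xb, yb = gb.mean().index.to_numpy(), gb.mean().to_numpy()
            if len(xb) < 4:
                continue
            fit_back = fit_psychometric(xb, yb, gb.size().to_numpy())
            out[(int(side), int(diff))] = (fit_now, fit_back)
    return out


def delta_choice_bias(cond_fits: dict, indifference: float,
                      outcome: str = "correct") -> pd.DataFrame:
    """Collapse conditional fits into the per-difficulty bias curve.

    After correct trials, dCB(d) is the half-difference of the after-right
    and after-left conditional curves at I. After errors, each side's change
    is first referenced to its own two-back baseline curve, then the two
    sides are half-differenced.
    """
    rows = []
    difficulties = sorted({d for (_, d) in cond_fits})
    for d in difficulties:
        right = cond_fits.get((RIGHT, d))
        left = cond_fits.get((LEFT, d))
        if right is None or left is None:
            rows.append((d, np.nan, 0))
            continue
        if outcome == "correct":
            value = 0.5 * (right.predict(indifference) - left.predict(indifference))
            n = right.n_trials + left.n_trials
        else:
            d_r = right[0].predict(indifference) - right[1].predict(indifference)
            d_l = left[0].predict(indifference) - left[1].predict(indifference)
            value = 0.5 * (d_r - d_l)
            n = right[0].n_trials + left[0].n_trials
        rows.append((d, float(value), n))
    return pd.DataFrame(rows, columns=["difficulty", "delta_cb", "n_trials"])


def bias_curve(trials: pd.DataFrame, outcome: str = "correct",
               min_cell: int = MIN_CELL_TRIALS) -> pd.DataFrame:
    """Point estimate of the conditional choice-bias curve for a trial table.

    ``trials`` must carry the history columns from :func:`prepare_trials`
    (they are added if absent).
    """
    if "prev_correct" not in trials.columns:
        trials = prepare_trials(trials)
    ref = fit_unconditional(trials)
    fits = conditional_psychometrics(trials, outcome=outcome, min_cell=min_cell)
    return delta_choice_bias(fits, ref.indifference_point, outcome=outcome)


def delta_choice_bias_empirical(trials: pd.DataFrame,
                                indifference: float = 0.0) -> pd.DataFrame:
    """Nonparametric cross-check of the after-correct bias curve.

    Uses the raw conditional rightward-choice fractions at the two stimuli
    nearest the indifference point instead of fitted curves.
    """
    if "prev_correct" not in trials.columns:
        trials = prepare_trials(trials)
    eligible = trials[trials["prev_correct"] == True]  # noqa: E712
    dist = (eligible["x_r"] - indifference).abs()
    nearest = np.sort(dist.unique())[:2]
    eligible = eligible[dist.isin(nearest)]
    rows = []
    for d, cell in eligible.groupby("prev_difficulty", observed=True):
        p_r = cell.loc[cell["prev_choice"] == RIGHT, "choice_right"].mean()
        p_l = cell.loc[cell["prev_choice"] == LEFT, "choice_right"].mean()
        rows.append((int(d), 0.5 * (p_r - p_l), len(cell)))
    return pd.DataFrame(rows, columns=["difficulty", "delta_cb", "n_trials"])


def bootstrap_bias_curve(trials: pd.DataFrame, n_boot: int = 200,
                         seed: int = 0, outcome: str = "correct",
                         min_cell: int = MIN_CELL_TRIALS,
                         ci: float = 95.0) -> pd.DataFrame:
    """Bias curve with stratified-bootstrap confidence intervals.

    Trials are resampled with replacement within each conditioning cell
    (previous side x previous difficulty); the unconditional indifference
    point is held at its full-data value. Returns one row per difficulty with
    delta_cb, ci_lo, ci_hi (percentile interval at level ``ci``; use 99 when
    asserting joint coverage across several cells) and the bootstrap draws'
    SD.
    """
    if "prev_correct" not in trials.columns:
        trials = prepare_trials(trials)
    rng = np.random.default_rng(seed)
    ref = fit_unconditional(trials)
    point = delta_choice_bias(
        conditional_psychometrics(trials, outcome=outcome, min_cell=min_cell),
        ref.indifference_point, outcome=outcome,
    )
    want_correct = outcome == "correct"
    eligible = trials[trials["prev_correct"] == want_correct]
    if not want_correct:
        eligible = eligible[eligible["back2_correct"] == True]  # noqa: E712
    groups = [g for _, g in eligible.groupby(["prev_choice", "prev_difficulty"],
                                             observed=True)]
    draws = np.full((n_boot, len(point)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_boot):
            resampled = pd.concat(
                [g.iloc[rng.integers(0, len(g), len(g))] for g in groups],
                ignore_index=True,
            )
            fits = conditional_psychometrics(resampled, outcome=outcome,
                                             min_cell=min_cell)
            curve = delta_choice_bias(fits, ref.indifference_point, outcome=outcome)
            merged = point[["difficulty"]].merge(curve, on="difficulty", how="left")
            draws[i] = merged["delta_cb"].to_numpy()
    tail = 0.5 * (100.0 - ci)
    out = point.copy()
    out["ci_lo"] = np.nanpercentile(draws, tail, axis=0)
    out["ci_hi"] = np.nanpercentile(draws, 100.0 - tail, axis=0)
    out["boot_sd"] = np.nanstd(draws, axis=0)
    return out


def bias_trend(trials: pd.DataFrame, n_boot: int = 200, seed: int = 0,
               min_cell: int = MIN_CELL_TRIALS,
               difficulty_values: dict | None = None):
    """Spearman correlation between previous-trial difficulty and dCB after
    correct trials, with a stratified-bootstrap CI.

    ``difficulty_values`` optionally maps each ordinal difficulty level to a
    physical value (e.g. mixture contrast in percent) so the correlation is
    reported on that axis; by default the ordinal level itself is used
    (1 = easiest, so win-stay biases growing with previous difficulty give
    rho > 0, equivalently rho < 0 against contrast). Returns
    ``(rho, ci_lo, ci_hi, curve)``.
    """
    if "prev_correct" not in trials.columns:
        trials = prepare_trials(trials)
    rng = np.random.default_rng(seed)
    ref = fit_unconditional(trials)
    curve = delta_choice_bias(
        conditional_psychometrics(trials, min_cell=min_cell),
        ref.indifference_point,
    )

    def axis(difficulties):
        if difficulty_values is None:
            return difficulties
        return [difficulty_values[d] for d in difficulties]

    rho = spearmanr(axis(curve["difficulty"]), curve["delta_cb"]).statistic
    eligible = trials[trials["prev_correct"] == True]  # noqa: E712
    groups = [g for _, g in eligible.groupby(["prev_choice", "prev_difficulty"],
                                             observed=True)]
    rhos = np.full(n_boot, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_boot):
            resampled = pd.concat(
                [g.iloc[rng.integers(0, len(g), len(g))] for g in groups],
                ignore_index=True,
            )
            fits = conditional_psychometrics(resampled, min_cell=min_cell)
            c = delta_choice_bias(fits, ref.indifference_point)
            ok = c["delta_cb"].notna()
            if ok.sum() >= 3:
                rhos[i] = spearmanr(axis(c.loc[ok, "difficulty"].tolist()),
                                    c.loc[ok, "delta_cb"]).statistic
    ci_lo, ci_hi = np.nanpercentile(rhos, [2.5, 97.5])
    return float(rho), float(ci_lo), float(ci_hi), curve


def bias_symmetry(trials: pd.DataFrame, min_cell: int = MIN_CELL_TRIALS) -> pd.DataFrame:
    """Check that conditional bias shifts are left/right symmetric.

    For each previous difficulty, compares the after-right and after-left
    deviations of the conditional curves from the unconditional curve at I;
    collapsing over mirrored stimuli is justified when the two deviations are
    of similar magnitude and opposite direction.
    """
    if "prev_correct" not in trials.columns:
        trials = prepare_trials(trials)
    ref = fit_unconditional(trials)
    i_pt = ref.indifference_point
    base = ref.predict(i_pt)
    fits = conditional_psychometrics(trials, min_cell=min_cell)
    rows = []
    for d in sorted({d for (_, d) in fits}):
        r = fits.get((RIGHT, d))
        l = fits.get((LEFT, d))
        if r is None or l is None:
            continue
        shift_r = r.predict(i_pt) - base
        shift_l = l.predict(i_pt) - base
        rows.append((d, float(shift_r), float(shift_l),
                     float(shift_r + shift_l)))
    return pd.DataFrame(rows, columns=["difficulty", "shift_after_right",
                                       "shift_after_left", "asymmetry"])
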