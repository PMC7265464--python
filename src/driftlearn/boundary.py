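"""Category-boundary geometry and weight-fluctuation reclassification.

In the plane of per-trial inferred drift rates (mu1, mu2) — accumulated
evidence divided by accumulation time — the category boundary
``w1 s1 + w2 s2 + b = 0`` is the line with slope ``-w1/w2`` and intercept
``-b/w2``; the optimal boundary is the main diagonal. Weight fluctuations
rotate this line about the origin and therefore affect stimuli in proportion
to their distance from the origin (high-concentration mixtures), whereas
bias fluctuations translate it, affecting all stimuli alike. The frozen-
noise reclassification quantifies this: the same simulated trials (identical
evidence samples) are re-classified under per-trial perturbed boundaries and
the flips are counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def inferred_drift(s_td, t_d):
    """Per-trial mean drift estimates: accumulated evidence / accumulation time.

    ``t_d`` is the decision time (non-decision time excluded — it is the time
    during which evidence was integrated). Vectorized over trials. Requires
    positive integration times.
    """
    s_td = np.asarray(s_td, dtype=float)
    t_d = np.asarray(t_d, dtype=float)
    if np.any(t_d <= 0):
        raise ValueError("integration times must be positive")
    return s_td / t_d[..., None] if s_td.ndim > 1 else s_td / t_d


@dataclass(frozen=True)
class BoundaryLine:
    """Slope/intercept form of the category boundary in the (s1, s2) plane."""

    slope: float
    intercept: float
    vertical: bool = False  # w2 == 0: the line s1 = intercept


def boundary_from_weights(w, b: float = 0.0) -> BoundaryLine:
    """Boundary line s2 = -(w1/w2) s1 - b/w2 (vertical representation if w2=0).

    The line is the zero set of the decision variable w1 s1 + w2 s2 + b, so
    every point on it satisfies the plane equation exactly.
    """
    w1, w2 = float(w[0]), float(w[1])
    if w2 == 0.0:
        if w1 == 0.0:
            raise ValueError("weights must not both be zero")
        return BoundaryLine(slope=np.inf, intercept=-b / w1, vertical=True)
    return BoundaryLine(slope=-w1 / w2, intercept=-b / w2)


def classify(s1, s2, w, b: float = 0.0):
    """Choice implied by the boundary inequality: +1 (left) if w.s + b > 0."""
    e = np.asarray(s1) * w[0] + np.asarray(s2) * w[1] + b
    return np.where(e > 0, 1, -1)


def add_inferred_drift(trials: pd.DataFrame) -> pd.DataFrame:
    """Append mu1/mu2 columns (drops non-positive integration times, counted)."""
    ok = trials["t_d"] > 0
    out = trials[ok].copy()
    out["mu1"] = out["s1"] / out["t_d"]
    out["mu2"] = out["s2"] / out["t_d"]
    out.attrs["n_excluded_nonpositive_td"] = int((~ok).sum())
    return out


def frozen_noise_reclassification(trials: pd.DataFrame, sd_w: float,
                                  sd_b: float = 0.0, seed: int = 0,
                                  w_ref=None, b_ref: float = 0.0) -> pd.DataFrame:
    """Re-classify frozen trials under per-trial perturbed boundaries.

    Each trial's accumulated evidence (s1, s2) is kept fixed ("frozen
    noise") and its classification under the reference boundary (optimal
    weights unless given) is compared with the classification under
    ``w + N(0, sd_w^2 I), b + N(0, sd_b^2)`` drawn independently per trial.
    Returns per-(task, stim_id) counts of unchanged / became-correct /
    became-error trials and the reclassified fraction.
    """
    from .stimuli import OPTIMAL_WEIGHTS

    rng = np.random.default_rng(seed)
    w_ref = np.asarray(OPTIMAL_WEIGHTS if w_ref is None else w_ref, dtype=float)
    s1 = trials["s1"].to_numpy()
    s2 = trials["s2"].to_numpy()
    base = classify(s1, s2, w_ref, b_ref)
    n = len(trials)
    dw = rng.normal(0.0, sd_w, (n, 2))
    db = rng.normal(0.0, sd_b, n) if sd_b > 0 else np.zeros(n)
    e_pert = (s1 * (w_ref[0] + dw[:, 0]) + s2 * (w_ref[1] + dw[:, 1])
              + b_ref + db)
    pert = np.where(e_pert > 0, 1, -1)
    correct_side = trials["correct_side"].to_numpy()
    changed = base != pert
    became_correct = changed & (pert == correct_side)
    became_error = changed & (base == correct_side)
    df = pd.DataFrame(
        {
            "task": trials["task"].to_numpy(),
            "stim_id": trials["stim_id"].to_numpy(),
            "changed": changed,
            "became_correct": became_correct,
            "became_error": became_error,
        }
    )
    out = df.groupby(["task", "stim_id"], observed=True).agg(
        n=("changed", "size"),
        n_changed=("changed", "sum"),
        n_became_correct=("became_correct", "sum"),
        n_became_error=("became_error", "sum"),
    )
    out["frac_reclassified"] = out["n_changed"] / out["n"]
    out["n_unchanged"] = out["n"] - out["n_changed"]
    return out.reset_index()


def mahalanobis_groups(trials: pd.DataFrame, min_trials: int = 3) -> pd.DataFrame:
    """Per-stimulus mean and covariance of the inferred drifts with the D=1
    ellipse parameters.

    The ellipse at Mahalanobis distance 1 has axes along the covariance
    eigenvectors with half-lengths sqrt(eigenvalue). Stimuli with singular
    covariance or fewer than ``min_trials`` trials are flagged.
    """
    if "mu1" not in trials.columns:
        trials = add_inferred_drift(trials)
    rows = []
    for stim_id, g in trials.groupby("stim_id", observed=True):
        pts = g[["mu1", "mu2"]].to_numpy()
        if len(pts) < min_trials:
            continue
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T)
        singular = not np.all(np.linalg.eigvalsh(cov) > 1e-12)
        if singular:
            axes = (np.nan, np.nan)
            angle = np.nan
        else:
            vals, vecs = np.linalg.eigh(cov)
            axes = tuple(np.sqrt(vals))
            angle = math.atan2(vecs[1, 1], vecs[0, 1])
        rows.append((stim_id, len(pts), mean[0], mean[1], cov[0, 0], cov[1, 1],
                     cov[0, 1], axes[0], axes[1], angle, singular))
    return pd.DataFrame(
        rows,
        columns=["stim_id", "n", "mean_mu1", "mean_mu2", "var_mu1", "var_mu2",
                 "cov_mu12", "axis_minor", "axis_major", "angle", "singular"],
    )


def mahalanobis_within(trials: pd.DataFrame, d: float = 1.0) -> pd.DataFrame:
    """Fraction of each stimulus cloud within Mahalanobis distance ``d``.

    For a bivariate Gaussian this fraction is ``1 - exp(-d^2/2)`` (chi-square
    with 2 df), a useful calibration check on the ellipse grouping.
    """
    if "mu1" not in trials.columns:
        trials = add_inferred_drift(trials)
    rows = []
    for stim_id, g in trials.groupby("stim_id", observed=True):
        pts = g[["mu1", "mu2"]].to_numpy()
        if len(pts) < 3:
            continue
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T)
        try:
            prec = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            continue
        delta = pts - mean
        d2 = np.einsum("ni,ij,nj->n", delta, prec, delta)
        rows.append((stim_id, len(pts), float(np.mean(d2 <= d * d))))
    out = pd.DataFrame(rows, columns=["stim_id", "n", "frac_within"])
    out["expected"] = 1.0 - math.exp(-0.5 * d * d)
    return out
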