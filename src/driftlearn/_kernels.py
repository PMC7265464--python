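"""Numba-compiled first-passage and race simulation kernels.

All kernels simulate in the *shifted* frame ``x(t) = e(t) - b`` where the
particle starts at 0 and the absorbing barriers are ``a_up = theta(t) - b``
(upper, -> left choice) and ``-a_lo = -theta(t) - b`` (lower, -> right).

Constant barriers use coarse Euler proposals with Brownian-bridge crossing
probabilities at both barriers, which makes crossing *detection* unbiased (a
barrier hit inside a step is caught with the exact bridge probability); the
crossing time within the detected step is taken at the step midpoint, leaving
a bias well below the step size. Collapsing barriers use plain Euler with the
final position clamped to the crossed barrier.

Each kernel takes an explicit integer seed so per-trial noise streams can be
derived deterministically from a root seed (frozen-noise analyses).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BOUND_CONSTANT = 0
BOUND_LINEAR = 1
BOUND_EXPONENTIAL = 2


@njit(cache=False)
def _bridge_cross_prob(gap0: float, gap1: float, var_dt: float) -> float:
    # probability a Brownian bridge crossed a barrier it did not end beyond,
    # given positive start/end distances gap0, gap1 to the barrier
    return np.exp(-2.0 * gap0 * gap1 / var_dt)


@njit(cache=False)
def fpt_constant(mu: float, var: float, a_up: float, a_lo: float, dt: float,
                 t_max: float, seed: int):
    """First passage of a drifting Wiener particle between constant barriers.

    Returns (hit, t_d, x_d): hit = +1 upper, -1 lower, 0 capped at t_max.
    ``x_d`` lies exactly on the crossed barrier (or at the final position if
    capped). ``var`` is the diffusion variance per unit time.
    """
    np.random.seed(seed)
    x = 0.0
    t = 0.0
    sd = np.sqrt(var * dt)
    var_dt = var * dt
    # gap products above this make the bridge probability < e^-30: skip
    skip = 15.0 * var_dt
    n_max = int(t_max / dt)
    for _ in range(n_max):
        x1 = x + mu * dt + sd * np.random.normal()
        if x1 >= a_up:
            return 1, t + 0.5 * dt, a_up
        if x1 <= -a_lo:
            return -1, t + 0.5 * dt, -a_lo
        # bridge crossing checks (upper then lower; double-crossing negligible)
        g0 = (a_up - x) * (a_up - x1)
        if g0 < skip and np.random.random() < _bridge_cross_prob(a_up - x, a_up - x1, var_dt):
            return 1, t + 0.5 * dt, a_up
        g1 = (x + a_lo) * (x1 + a_lo)
        if g1 < skip and np.random.random() < _bridge_cross_prob(x + a_lo, x1 + a_lo, var_dt):
            return -1, t + 0.5 * dt, -a_lo
        x = x1
        t += dt
    return 0, t, x


@njit(cache=False)
def fpt_constant_batch(n: int, mu: float, var: float, a_up: float, a_lo: float,
                       dt: float, t_max: float, seed: int):
    """Batch of :func:`fpt_constant` trials with per-trial derived seeds.

    Each trial reseeds from ``seed + i`` so its noise stream is independent
    of how many draws earlier trials consumed — a requirement for smooth
    common-random-number likelihood surfaces.
    """
    hits = np.zeros(n, dtype=np.int64)
    times = np.zeros(n)
    xs = np.zeros(n)
    sd = np.sqrt(var * dt)
    var_dt = var * dt
    skip = 15.0 * var_dt
    n_max = int(t_max / dt)
    for i in range(n):
        np.random.seed((seed + i) & 0x7FFFFFFF)
        x = 0.0
        t = 0.0
        hit = 0
        xd = 0.0
        for _ in range(n_max):
            x1 = x + mu * dt + sd * np.random.normal()
            if x1 >= a_up:
                hit = 1
                t += 0.5 * dt
                xd = a_up
                break
            if x1 <= -a_lo:
                hit = -1
                t += 0.5 * dt
                xd = -a_lo
                break
            if (a_up - x) * (a_up - x1) < skip and np.random.random() < _bridge_cross_prob(a_up - x, a_up - x1, var_dt):
                hit = 1
                t += 0.5 * dt
                xd = a_up
                break
            if (x + a_lo) * (x1 + a_lo) < skip and np.random.random() < _bridge_cross_prob(x + a_lo, x1 + a_lo, var_dt):
                hit = -1
                t += 0.5 * dt
                xd = -a_lo
                break
            x = x1
            t += dt
        if hit == 0:
            xd = x
        hits[i] = hit
        times[i] = t
        xs[i] = xd
    return hits, times, xs


@njit(cache=False)
def _theta_at(t: float, shape: int, theta0: float, theta_slo: float,
              tau_collapse: float) -> float:
    if shape == BOUND_LINEAR:
        th = theta0 + theta_slo * t
        return th if th > 0.0 else 0.0
    if shape == BOUND_EXPONENTIAL:
        return theta0 * np.exp(-t / tau_collapse)
    return theta0


@njit(cache=False)
def fpt_collapsing(mu: float, var: float, b: float, shape: int, theta0: float,
                   theta_slo: float, tau_collapse: float, dt: float, t_max: float,
                   seed: int):
    """Euler first passage against collapsing barriers theta(t)-b / -theta(t)-b.

    Returns (hit, t_d, x_d) with x_d clamped onto the crossed barrier. If the
    barriers meet (theta(t) = 0) the trial terminates with the sign of x
    (fair coin on an exact tie).
    """
    np.random.seed(seed)
    x = 0.0
    t = 0.0
    sd = np.sqrt(var * dt)
    n_max = int(t_max / dt)
    for _ in range(n_max):
        t1 = t + dt
        th = _theta_at(t1, shape, theta0, theta_slo, tau_collapse)
        if th <= 0.0:
            if x > 0.0:
                return 1, t1, 0.0 - b
            if x < 0.0:
                return -1, t1, 0.0 - b
            if np.random.random() < 0.5:
                return 1, t1, 0.0 - b
            return -1, t1, 0.0 - b
        x = x + mu * dt + sd * np.random.normal()
        a_up = th - b
        a_lo = th + b
        if x >= a_up:
            return 1, t1, a_up
        if x <= -a_lo:
            return -1, t1, -a_lo
        t = t1
    return 0, t, x


@njit(cache=False)
def lca_trial(mu1: float, mu2: float, leak_inv: float, w_inh: float, b: float,
              shape: int, theta0: float, theta_slo: float, tau_collapse: float,
              dt: float, t_max: float, seed: int):
    """Leaky competing accumulator race between two rectified units.

    ds_i = (mu_i - s_i/tau_leak - w_inh * s_{3-i}) dt + dW_i, with s_i >= 0.
    The first accumulator to reach theta(t) triggers its choice (unit 1 ->
    left). A decision bias ``b`` shifts the effective threshold of unit 1 down
    and unit 2 up by b (leftward bias for b > 0). Returns
    (hit, t_d, s1, s2); hit = 0 if capped, in which case the larger
    accumulator is reported by the caller.
    """
    np.random.seed(seed)
    s1 = 0.0
    s2 = 0.0
    t = 0.0
    sd = np.sqrt(dt)
    n_max = int(t_max / dt)
    for _ in range(n_max):
        t1 = t + dt
        th = _theta_at(t1, shape, theta0, theta_slo, tau_collapse)
        d1 = (mu1 - leak_inv * s1 - w_inh * s2) * dt + sd * np.random.normal()
        d2 = (mu2 - leak_inv * s2 - w_inh * s1) * dt + sd * np.random.normal()
        s1 = max(s1 + d1, 0.0)
        s2 = max(s2 + d2, 0.0)
        hit1 = s1 >= th - b
        hit2 = s2 >= th + b
        if hit1 and hit2:
            # simultaneous crossings resolved by the larger overshoot
            if s1 - (th - b) >= s2 - (th + b):
                return 1, t1, th - b, s2
            return -1, t1, s1, th + b
        if hit1:
            return 1, t1, th - b, s2
        if hit2:
            return -1, t1, s1, th + b
        t = t1
    return 0, t, s1, s2
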