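"""Compiled kernels for Wiener first-passage-time (WFPT) numerics.

Everything in this module is numba-jitted and operates on plain floats and
arrays; the public, validated interface lives in :mod:`hardship_ddm.ddm_core`.

Conventions
-----------
* Diffusion coefficient fixed at s = 1 (scaling convention).
* Accuracy coding: the *upper* boundary is the correct response, the lower
  boundary the error.  The relative start point ``z`` in (0, 1) is measured
  from the lower (error) boundary, so z > 0.5 means a bias toward correct.
* Across-trial variabilities: drift ~ Normal(v, sv**2) marginalised
  analytically; start point ~ Uniform(z - sz/2, z + sz/2) and non-decision
  time ~ Uniform(t0 - st0/2, t0 + st0/2) marginalised by fixed-node
  Gauss-Legendre quadrature (nodes supplied by the caller).

The drift-free scaled density uses the standard dual-series representation
(small-time and large-time expansions) with the adaptive truncation bound on
the number of terms for a requested absolute error.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "f_lower_scaled",
    "density_one",
    "density_array",
    "loglike",
    "simulate",
    "am_sample",
    "gauss_legendre_nodes",
]


def gauss_legendre_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights rescaled to a uniform average on [-1/2, 1/2].

    Weights sum to one, so summing ``w_i * f(node_i)`` approximates the mean
    of ``f`` under a centred uniform distribution of unit width.
    """
    if n <= 1:
        return np.zeros(1), np.ones(1)
    x, w = np.polynomial.legendre.leggauss(n)
    return x / 2.0, w / 2.0


@njit(cache=True, fastmath=True)
def f_lower_scaled(tau: float, w: float, eps: float) -> float:
    """Scaled drift-free first-passage density at the lower boundary.

    Density of the first hit of 0 by a unit-diffusion starting at ``w`` in
    (0, 1) with absorbing boundaries {0, 1}, at scaled time ``tau = u / a**2``.
    Chooses the series (small-time vs large-time) that needs fewer terms for
    absolute truncation error ``eps``.
    """
    if tau <= 0.0:
        return 0.0
    # number of terms required by each branch
    if 2.0 * eps * math.sqrt(2.0 * math.pi * tau) < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tau)))
        if ks < math.sqrt(tau) + 1.0:
            ks = math.sqrt(tau) + 1.0
    else:
        ks = 2.0
    if math.pi * tau * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * eps) / (math.pi * math.pi * tau))
        if kl < 1.0 / (math.pi * math.sqrt(tau)):
            kl = 1.0 / (math.pi * math.sqrt(tau))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = K // 2
        inv2tau = 0.5 / tau
        s = 0.0
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            s += x * math.exp(-x * x * inv2tau)
        out = s / math.sqrt(2.0 * math.pi * tau * tau * tau)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        s = 0.0
        for k in range(1, K + 1):
            s += k * math.exp(-k * k * math.pi * math.pi * tau / 2.0) * math.sin(k * math.pi * w)
        out = math.pi * s
    if out < 0.0:  # truncation can leave a tiny negative residue
        out = 0.0
    return out


@njit(cache=True)
def _f_lower_scaled_branch(tau: float, w: float, eps: float, use_small: bool) -> float:
    """Force one series branch; used to test agreement on the overlap region."""
    if tau <= 0.0:
        return 0.0
    if use_small:
        if 2.0 * eps * math.sqrt(2.0 * math.pi * tau) < 1.0:
            ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tau)))
        else:
            ks = 2.0
        if ks < math.sqrt(tau) + 1.0:
            ks = math.sqrt(tau) + 1.0
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = K // 2
        s = 0.0
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            s += x * math.exp(-x * x / (2.0 * tau))
        out = s / math.sqrt(2.0 * math.pi * tau * tau * tau)
    else:
        if math.pi * tau * eps < 1.0:
            kl = math.sqrt(-2.0 * math.log(math.pi * tau * eps) / (math.pi * math.pi * tau))
        else:
            kl = 0.0
        if kl < 1.0 / (math.pi * math.sqrt(tau)):
            kl = 1.0 / (math.pi * math.sqrt(tau))
        K = int(math.ceil(kl))
        s = 0.0
        for k in range(1, K + 1):
            s += k * math.exp(-k * k * math.pi * math.pi * tau / 2.0) * math.sin(k * math.pi * w)
        out = math.pi * s
    if out < 0.0:
        out = 0.0
    return out


@njit(cache=True, fastmath=True)
def density_one(
    t: float,
    upper: bool,
    v: float,
    a: float,
    z: float,
    t0: float,
    sv: float,
    sz: float,
    st0: float,
    eps: float,
    nodes_w: np.ndarray,
    wts_w: np.ndarray,
    nodes_t: np.ndarray,
    wts_t: np.ndarray,
) -> float:
    """First-passage density at time ``t`` (seconds from stimulus onset).

    Drift variability is integrated out analytically; start-point and
    non-decision-time variability by the supplied quadrature rule.  Returns
    0 for ``t`` at or before the earliest possible non-decision time.
    """
    acc = 0.0
    a2 = a * a
    mu = -v if upper else v
    sv2 = sv * sv
    for i in range(nodes_t.size):
        t0i = t0 + st0 * nodes_t[i]
        u = t - t0i
        if u <= 1e-12:
            continue
        one_svu = 1.0 + sv2 * u
        inv_2svu = 0.5 / one_svu
        root_svu = math.sqrt(one_svu)
        tau = u / a2
        # series branch and term count depend on tau only; hoist out of
        # the start-point loop
        if 2.0 * eps * math.sqrt(2.0 * math.pi * tau) < 1.0:
            ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tau)))
            if ks < math.sqrt(tau) + 1.0:
                ks = math.sqrt(tau) + 1.0
        else:
            ks = 2.0
        if math.pi * tau * eps < 1.0:
            kl = math.sqrt(-2.0 * math.log(math.pi * tau * eps) / (math.pi * math.pi * tau))
            if kl < 1.0 / (math.pi * math.sqrt(tau)):
                kl = 1.0 / (math.pi * math.sqrt(tau))
        else:
            kl = 1.0 / (math.pi * math.sqrt(tau))
        use_small = ks < kl
        if use_small:
            K = int(math.ceil(ks))
            lo = -((K - 1) // 2)
            hi = K // 2
            inv2tau = 0.5 / tau
            norm = 1.0 / math.sqrt(2.0 * math.pi * tau * tau * tau)
        else:
            K = int(math.ceil(kl))
            lo = 1
            hi = K
            inv2tau = 0.0
            norm = math.pi
        for j in range(nodes_w.size):
            zj = z + sz * nodes_w[j]
            w = 1.0 - zj if upper else zj
            s = 0.0
            if use_small:
                for k in range(lo, hi + 1):
                    x = w + 2.0 * k
                    s += x * math.exp(-x * x * inv2tau)
            else:
                for k in range(1, hi + 1):
                    s += k * math.exp(-k * k * math.pi * math.pi * tau * 0.5) \
                        * math.sin(k * math.pi * w)
            g = s * norm
            if g <= 0.0:
                continue
            expo = (sv2 * a2 * w * w - 2.0 * mu * a * w - mu * mu * u) * inv_2svu
            acc += wts_t[i] * wts_w[j] * g * math.exp(expo) / (root_svu * a2)
    return acc


@njit(cache=True)
def density_array(
    ts: np.ndarray,
    upper: bool,
    v: float,
    a: float,
    z: float,
    t0: float,
    sv: float,
    sz: float,
    st0: float,
    eps: float,
    nodes_w: np.ndarray,
    wts_w: np.ndarray,
    nodes_t: np.ndarray,
    wts_t: np.ndarray,
) -> np.ndarray:
    out = np.empty(ts.size)
    for i in range(ts.size):
        out[i] = density_one(ts[i], upper, v, a, z, t0, sv, sz, st0, eps,
                             nodes_w, wts_w, nodes_t, wts_t)
    return out


@njit(cache=True)
def loglike(
    rt: np.ndarray,
    correct: np.ndarray,
    v: float,
    a: float,
    z: float,
    t0: float,
    sv: float,
    sz: float,
    st0: float,
    eps: float,
    nodes_w: np.ndarray,
    wts_w: np.ndarray,
    nodes_t: np.ndarray,
    wts_t: np.ndarray,
) -> float:
    """Sum of log first-passage densities over trials.

    A trial with rt at or below the earliest non-decision time has zero
    density and yields -inf (documented contract), not an exception.
    """
    total = 0.0
    for i in range(rt.size):
        d = density_one(rt[i], correct[i] == 1, v, a, z, t0, sv, sz, st0, eps,
                        nodes_w, wts_w, nodes_t, wts_t)
        if d <= 0.0:
            return -np.inf
        total += math.log(d)
    return total


@njit(cache=True)
def simulate(
    n: int,
    v: float,
    a: float,
    z: float,
    t0: float,
    sv: float,
    sz: float,
    st0: float,
    dt: float,
    deadline: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euler-Maruyama simulation of ``n`` trials with bridge correction.

    Between consecutive Euler points the probability that the Brownian
    bridge crossed a boundary unobserved is exp(-2 d0 d1 / dt) (d0, d1 the
    distances to that boundary); sampling this event removes the leading
    O(sqrt(dt)) discretisation bias of naive Euler boundary detection.

    Returns (rt, correct, omitted).  ``deadline <= 0`` means no deadline
    (a 20 s safety cap still applies; such trials come back omitted).
    ``correct`` is -1 for omitted trials.
    """
    np.random.seed(seed)
    rts = np.empty(n)
    correct = np.empty(n, dtype=np.int8)
    omitted = np.zeros(n, dtype=np.int8)
    sqdt = math.sqrt(dt)
    cap = deadline if deadline > 0.0 else 20.0
    guard = 6.0 * sqdt  # bridge-crossing odds are negligible farther out
    for i in range(n):
        vi = v + sv * np.random.randn()
        zi = z + sz * (np.random.rand() - 0.5)
        t0i = t0 + st0 * (np.random.rand() - 0.5)
        x = zi * a
        tdec = 0.0
        boundary = np.int8(-1)
        while True:
            xp = x
            x += vi * dt + sqdt * np.random.randn()
            tdec += dt
            if x >= a:
                boundary = 1
                break
            if x <= 0.0:
                boundary = 0
                break
            if a - xp < guard and a - x < guard:
                if np.random.rand() < math.exp(-2.0 * (a - xp) * (a - x) / dt):
                    boundary = 1
                    break
            if xp < guard and x < guard:
                if np.random.rand() < math.exp(-2.0 * xp * x / dt):
                    boundary = 0
                    break
            if t0i + tdec > cap:
                break
        rt = t0i + tdec
        if boundary < 0 or rt > cap:
            rts[i] = np.nan
            correct[i] = -1
            omitted[i] = 1
        else:
            rts[i] = rt
            correct[i] = boundary
    return rts, correct, omitted


@njit(cache=True)
def _logprior(
    th: np.ndarray,
    prior_mu: np.ndarray,
    prior_sd: np.ndarray,
    half: np.ndarray,
) -> float:
    """Weakly-informative prior over (v, a, z, t0, sv, sz, st0).

    Normal densities for the location parameters, half-normal for the
    variabilities, truncated to the parameter-invariant region.
    """
    v, a, z, t0, sv, sz, st0 = th[0], th[1], th[2], th[3], th[4], th[5], th[6]
    if a <= 0.05 or a > 10.0:
        return -np.inf
    if z <= 0.01 or z >= 0.99:
        return -np.inf
    if sv < 0.0 or sz < 0.0 or st0 < 0.0 or sv > 10.0:
        return -np.inf
    if z - sz / 2.0 <= 1e-3 or z + sz / 2.0 >= 1.0 - 1e-3:
        return -np.inf
    if t0 - st0 / 2.0 < 0.0 or t0 <= 0.0 or t0 > 5.0:
        return -np.inf
    lp = 0.0
    for k in range(7):
        x = th[k]
        if half[k] == 1:
            lp += -0.5 * (x / prior_sd[k]) ** 2
        else:
            r = (x - prior_mu[k]) / prior_sd[k]
            lp += -0.5 * r * r
    return lp


@njit(cache=True)
def am_sample(
    rt: np.ndarray,
    correct: np.ndarray,
    init: np.ndarray,
    prior_mu: np.ndarray,
    prior_sd: np.ndarray,
    half: np.ndarray,
    n_warmup: int,
    n_keep: int,
    seed: int,
    eps: float,
    nodes_w: np.ndarray,
    wts_w: np.ndarray,
    nodes_t: np.ndarray,
    wts_t: np.ndarray,
) -> tuple[np.ndarray, float]:
    """One adaptive-Metropolis chain over the 7-parameter space.

    Haario-style adaptation during warmup: the proposal is the empirical
    posterior covariance scaled by 2.38**2/d times a global factor tuned
    toward ~28% acceptance; the moment accumulators restart at one third
    of warmup so early transient states do not pollute the estimate.  The
    proposal is frozen at the end of warmup.  Returns (kept draws,
    acceptance rate over the kept phase).
    """
    np.random.seed(seed)
    d = 7
    th = init.copy()
    lp = _logprior(th, prior_mu, prior_sd, half)
    if lp > -np.inf:
        lp += loglike(rt, correct, th[0], th[1], th[2], th[3], th[4], th[5], th[6],
                      eps, nodes_w, wts_w, nodes_t, wts_t)
    mean = th.copy()
    cov = np.zeros((d, d))
    count = 1.0
    scale = 2.38 * 2.38 / d
    log_s = 0.0
    L = np.zeros((d, d))
    for k in range(d):
        L[k, k] = 0.05 * prior_sd[k]
    draws = np.empty((n_keep, d))
    n_total = n_warmup + n_keep
    reset_at = n_warmup // 3
    adapt_from = max(100, reset_at // 2)
    accepted_keep = 0
    accepted_window = 0
    window = 0
    for it in range(n_total):
        step = np.empty(d)
        for k in range(d):
            step[k] = np.random.randn()
        prop = th + math.exp(log_s) * (L @ step)
        lpp = _logprior(prop, prior_mu, prior_sd, half)
        if lpp > -np.inf:
            lpp += loglike(rt, correct, prop[0], prop[1], prop[2], prop[3],
                           prop[4], prop[5], prop[6],
                           eps, nodes_w, wts_w, nodes_t, wts_t)
        if lpp - lp > math.log(np.random.rand() + 1e-300):
            th = prop
            lp = lpp
            accepted_window += 1
            if it >= n_warmup:
                accepted_keep += 1
        window += 1
        if it == reset_at:       # drop transient from the moment estimate
            mean = th.copy()
            cov = np.zeros((d, d))
            count = 1.0
        else:
            count += 1.0
            delta = th - mean
            mean = mean + delta / count
            delta2 = th - mean
            for r in range(d):
                for c in range(d):
                    cov[r, c] += delta[r] * delta2[c]
        if it < n_warmup and (it + 1) % 25 == 0:
            rate = accepted_window / window
            if rate < 0.15:
                log_s -= 0.15
            elif rate > 0.40:
                log_s += 0.15
            accepted_window = 0
            window = 0
            if it >= adapt_from and count > 2 * d:
                C = cov / (count - 1.0)
                P = scale * C
                for k in range(d):
                    P[k, k] += 1e-9
                L = np.linalg.cholesky(P)
        if it >= n_warmup:
            draws[it - n_warmup] = th
    return draws, accepted_keep / max(n_keep, 1)
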