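"""Numba-compiled core of the posterior sampler.

The sampler is an adaptive Metropolis-within-Gibbs scan over the transformed
parameter vector and the free process-deviation vector.  Transformed
coordinates: (ln R_max, ln K, z, logit q, ln sigma2, ln tau2); the latent
coordinates are the free deviations U (one shared pre-equilibrium draw, then
one per post-equilibrium year), with the state path P a deterministic function
of (params, U, removals).  Every proposal re-evaluates the full joint log
density; a proposal whose pre-noise bracket goes non-positive has density
-inf and is rejected, which keeps the posterior proper without truncation.

Per-coordinate proposal scales adapt in batches toward an acceptance rate of
0.44 and are frozen at the end of burn-in.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# prior type codes (per transformed coordinate)
PRIOR_NORMAL_LOG = 0   # normal(a, b) on the coordinate (lognormal raw)
PRIOR_UNIF_EXP = 1     # uniform(a, b) on exp(coordinate)
PRIOR_BETA_LOGIT = 2   # beta(a, b) on expit(coordinate)
PRIOR_INVGAMMA_EXP = 3 # invgamma(shape=a, scale=b) on exp(coordinate)
PRIOR_UNIF_RAW = 4     # uniform(a, b) on the raw coordinate (z)
PRIOR_FIXED = 5        # coordinate never moves, zero prior contribution

LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _log_prior_coord(t, code, a, b):
    if code == PRIOR_NORMAL_LOG:
        d = (t - a) / b
        return -0.5 * d * d - math.log(b) - 0.5 * LOG2PI
    elif code == PRIOR_UNIF_EXP:
        r = math.exp(t)
        if r <= a or r >= b:
            return -np.inf
        return t - math.log(b - a)
    elif code == PRIOR_BETA_LOGIT:
        q = 1.0 / (1.0 + math.exp(-t))
        if q <= 0.0 or q >= 1.0:
            return -np.inf
        lbeta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
        return a * math.log(q) + b * math.log(1.0 - q) - lbeta
    elif code == PRIOR_INVGAMMA_EXP:
        return a * math.log(b) - math.lgamma(a) - a * t - b * math.exp(-t)
    elif code == PRIOR_UNIF_RAW:
        if t < a or t > b:
            return -np.inf
        return -math.log(b - a)
    return 0.0  # PRIOR_FIXED


@njit(cache=True)
def _trajectory(rmax, k, z, u, rem, n_pre, p_out):
    """Fill p_out with the state path; return False if any bracket <= 0.

    ``u`` is the free deviation vector (len 1 + T - n_pre); ``rem`` the
    removals in thousands per year index.
    """
    T = p_out.shape[0]
    p0 = math.exp(u[0])
    for t in range(n_pre):
        p_out[t] = p0
    start = n_pre if n_pre > 0 else 1
    if n_pre == 0:
        p_out[0] = p0
    for t in range(start, T):
        p_prev = p_out[t - 1]
        bracket = p_prev + rmax * p_prev * (1.0 - p_prev**z) - rem[t - 1] / k
        if not (bracket > 0.0):  # also catches NaN from overflow
            return False
        p_out[t] = bracket * math.exp(u[t - start + 1])
    return True


@njit(cache=True)
def _logpost(x, u, codes, pa, pb, rem, obs_idx, obs_logi, n_pre, p_work):
    """Joint log density and observation log-likelihood.

    Returns (logpost, obs_ll); logpost = -inf marks an invalid state.
    """
    lp = 0.0
    for j in range(6):
        c = _log_prior_coord(x[j], codes[j], pa[j], pb[j])
        if not np.isfinite(c):
            return -np.inf, 0.0
        lp += c

    rmax = math.exp(x[0])
    k = math.exp(x[1])
    z = x[2]
    q = 1.0 / (1.0 + math.exp(-x[3]))
    s2 = math.exp(x[4])
    t2 = math.exp(x[5])

    m = u.shape[0]
    su2 = 0.0
    for i in range(m):
        su2 += u[i] * u[i]
    lp += -0.5 * m * (LOG2PI + math.log(s2)) - su2 / (2.0 * s2)

    if not _trajectory(rmax, k, z, u, rem, n_pre, p_work):
        return -np.inf, 0.0

    lqk = math.log(q * k)
    obs_ll = 0.0
    for i in range(obs_idx.shape[0]):
        li = obs_logi[i]
        mu = lqk + math.log(p_work[obs_idx[i]])
        d = li - mu
        obs_ll += -li - 0.5 * (LOG2PI + math.log(t2)) - d * d / (2.0 * t2)
    return lp + obs_ll, obs_ll


@njit(cache=True)
def _traj_tail(rmax, k, z, u, rem, n_pre, p_cur, p_prop, t0):
    """Recompute the state path from index t0 onward into p_prop (head copied
    from p_cur).  Returns False on a non-positive bracket."""
    T = p_cur.shape[0]
    start = n_pre if n_pre > 0 else 1
    head_from_cur = t0 > 0
    if not head_from_cur:
        p0 = math.exp(u[0])
        for t in range(start):
            p_prop[t] = p0
        t0 = start
    for t in range(t0, T):
        if t == t0 and head_from_cur:
            p_prev = p_cur[t - 1]
        else:
            p_prev = p_prop[t - 1]
        bracket = p_prev + rmax * p_prev * (1.0 - p_prev**z) - rem[t - 1] / k
        if not (bracket > 0.0):  # also catches NaN from overflow
            return False
        p_prop[t] = bracket * math.exp(u[t - start + 1])
    return True


@njit(cache=True)
def _obs_ll_tail(p, obs_idx, obs_logi, lqk, t2, t0):
    """Observation log-likelihood summed over survey years at index >= t0."""
    s = 0.0
    for i in range(obs_idx.shape[0]):
        if obs_idx[i] < t0:
            continue
        li = obs_logi[i]
        mu = lqk + math.log(p[obs_idx[i]])
        d = li - mu
        s += -li - 0.5 * (LOG2PI + math.log(t2)) - d * d / (2.0 * t2)
    return s


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    burn_in,
    thin,
    x0,
    u0,
    codes,
    pa,
    pb,
    update,      # bool[6]: which parameter coordinates move
    fix_latents, # bool: freeze the U vector
    rem,
    obs_idx,
    obs_logi,
    n_pre,
    adapt_batch,
    target_accept,
):
    """One adaptive Metropolis-within-Gibbs chain.

    Returns (params_raw (n_keep, 6), u_draws, p_draws, deviance, accept_rate
    per coordinate post-burn-in).
    """
    np.random.seed(seed)
    T = rem.shape[0]
    m = u0.shape[0]
    # coordinates: 6 parameters, m latents, plus one global scale for the
    # joint all-parameter move (index 6 + m)
    n_coord = 6 + m + 1
    start = n_pre if n_pre > 0 else 1
    x = x0.copy()
    u = u0.copy()
    p = np.empty(T)
    p_prop = np.empty(T)
    lp, oll = _logpost(x, u, codes, pa, pb, rem, obs_idx, obs_logi, n_pre, p)
    su2 = 0.0
    for i in range(m):
        su2 += u[i] * u[i]
    x_old6 = np.empty(6)

    # running moments of the parameter vector feed an adaptive-covariance
    # joint move (the K-q and R_max-z ridges are strongly correlated)
    mean6 = np.zeros(6)
    cov_acc = np.zeros((6, 6))
    n_cov = 0
    chol6 = np.eye(6) * 0.1
    eta6 = np.empty(6)

    scales = np.full(n_coord, 0.1)
    scales[6 + m] = 0.3  # global factor of the joint parameter move
    batch_acc = np.zeros(n_coord)
    batch_try = np.zeros(n_coord)
    post_acc = np.zeros(n_coord)
    post_try = np.zeros(n_coord)

    n_keep = 0
    for it in range(burn_in, n_iter):
        if (it - burn_in) % thin == 0:
            n_keep += 1
    out_x = np.empty((n_keep, 6))
    out_u = np.empty((n_keep, m))
    out_p = np.empty((n_keep, T))
    out_dev = np.empty(n_keep)

    keep = 0
    batch_no = 0
    for it in range(n_iter):
        for j in range(6):
            if not update[j]:
                continue
            old = x[j]
            x[j] = old + scales[j] * np.random.normal()
            lp_new, oll_new = _logpost(
                x, u, codes, pa, pb, rem, obs_idx, obs_logi, n_pre, p_prop
            )
            batch_try[j] += 1.0
            accept = np.log(np.random.random()) < lp_new - lp
            if accept:
                lp = lp_new
                oll = oll_new
                tmp = p
                p = p_prop
                p_prop = tmp
                batch_acc[j] += 1.0
            else:
                x[j] = old
            if it >= burn_in:
                post_try[j] += 1.0
                if accept:
                    post_acc[j] += 1.0
        # joint move along all free parameter coordinates: single-site
        # updates mix slowly along correlated ridges (notably R_max with z)
        jslot = 6 + m
        n_free = 0
        for j in range(6):
            if update[j]:
                n_free += 1
        if n_free > 1:
            # accumulate running mean/covariance of the parameter vector
            n_cov += 1
            for j in range(6):
                eta6[j] = x[j] - mean6[j]
            for j in range(6):
                mean6[j] += eta6[j] / n_cov
            for j in range(6):
                for l2 in range(6):
                    cov_acc[j, l2] += eta6[j] * (x[l2] - mean6[l2])
            for j in range(6):
                eta6[j] = np.random.normal()
            for j in range(6):
                x_old6[j] = x[j]
                if update[j]:
                    step = 0.0
                    for l2 in range(6):
                        step += chol6[j, l2] * eta6[l2]
                    x[j] = x[j] + scales[jslot] * step
            lp_new, oll_new = _logpost(
                x, u, codes, pa, pb, rem, obs_idx, obs_logi, n_pre, p_prop
            )
            batch_try[jslot] += 1.0
            accept = np.log(np.random.random()) < lp_new - lp
            if accept:
                lp = lp_new
                oll = oll_new
                tmp = p
                p = p_prop
                p_prop = tmp
                batch_acc[jslot] += 1.0
            else:
                for j in range(6):
                    x[j] = x_old6[j]
            if it >= burn_in:
                post_try[jslot] += 1.0
                if accept:
                    post_acc[jslot] += 1.0
        if not fix_latents:
            rmax = math.exp(x[0])
            k = math.exp(x[1])
            z = x[2]
            q = 1.0 / (1.0 + math.exp(-x[3]))
            s2 = math.exp(x[4])
            t2 = math.exp(x[5])
            lqk = math.log(q * k)
            for l in range(m):
                old = u[l]
                u[l] = old + scales[6 + l] * np.random.normal()
                t0 = 0 if l == 0 else start + l - 1
                batch_try[6 + l] += 1.0
                accept = False
                dlp = 0.0
                old_tail = 0.0
                new_tail = 0.0
                if _traj_tail(rmax, k, z, u, rem, n_pre, p, p_prop, t0):
                    old_tail = _obs_ll_tail(p, obs_idx, obs_logi, lqk, t2, t0)
                    new_tail = _obs_ll_tail(p_prop, obs_idx, obs_logi, lqk, t2, t0)
                    dlp = (
                        new_tail
                        - old_tail
                        - (u[l] * u[l] - old * old) / (2.0 * s2)
                    )
                    accept = np.log(np.random.random()) < dlp
                if accept:
                    su2 += u[l] * u[l] - old * old
                    lp += dlp
                    oll += new_tail - old_tail
                    for t in range(t0, T):
                        p[t] = p_prop[t]
                    batch_acc[6 + l] += 1.0
                else:
                    u[l] = old
                if it >= burn_in:
                    post_try[6 + l] += 1.0
                    if accept:
                        post_acc[6 + l] += 1.0

        # batched scale adaptation with diminishing step (continues past
        # burn-in; the hard feasibility boundary can wedge a chain whose
        # scales are frozen too large, and a diminishing scheme keeps the
        # kernel ergodic while still allowing escape)
        if (it + 1) % adapt_batch == 0:
            batch_no += 1
            delta = min(0.1, 1.0 / math.sqrt(batch_no))
            if n_cov > 50:
                cov6 = cov_acc / (n_cov - 1)
                jitter = 1e-8 * (np.trace(cov6) / 6.0 + 1.0)
                for j in range(6):
                    cov6[j, j] += jitter
                chol6 = np.linalg.cholesky(cov6)
            for c in range(n_coord):
                if batch_try[c] > 0:
                    rate = batch_acc[c] / batch_try[c]
                    # multivariate moves target a lower acceptance rate
                    tgt = 0.234 if c == 6 + m else target_accept
                    if rate > tgt:
                        scales[c] *= math.exp(delta)
                    else:
                        scales[c] *= math.exp(-delta)
                batch_acc[c] = 0.0
                batch_try[c] = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_x[keep, 0] = math.exp(x[0])
            out_x[keep, 1] = math.exp(x[1])
            out_x[keep, 2] = x[2]
            out_x[keep, 3] = 1.0 / (1.0 + math.exp(-x[3]))
            out_x[keep, 4] = math.exp(x[4])
            out_x[keep, 5] = math.exp(x[5])
            for l in range(m):
                out_u[keep, l] = u[l]
            for t in range(T):
                out_p[keep, t] = p[t]
            out_dev[keep] = -2.0 * oll
            keep += 1

    acc_rate = np.full(n_coord, np.nan)
    for c in range(n_coord):
        if post_try[c] > 0:
            acc_rate[c] = post_acc[c] / post_try[c]
    return out_x, out_u, out_p, out_dev, acc_rate
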