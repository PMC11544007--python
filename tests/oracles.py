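"""Independent reference implementations used only as test oracles.

Each routine here deliberately takes a different computational path from the
package (direct PDE discretisation, brute-force enumeration, exhaustive
search, resampling) so that agreement is evidence of correctness rather than
of shared code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sangren_sheppard_tanks(f, ps, vp, ve, t_eval, t_aif, cp_aif, n_seg=200):
    """Direct numerical solution of the two-region axially distributed
    capillary-interstitium transport equations.

    The capillary is discretised into ``n_seg`` axial segments advected by
    exact plug-flow shifting (one segment per step, dt = Tc/n_seg, so the
    advection operator introduces no numerical diffusion); within each step
    the plasma-interstitium exchange ODE pair is advanced by its exact
    two-compartment solution.  Tissue concentration is the volume-weighted
    axial mean.
    """
    tc = vp / f
    dt = tc / n_seg
    n_steps = int(math.ceil(t_eval[-1] / dt))
    inlet = np.interp((np.arange(n_steps) + 0.5) * dt, t_aif, cp_aif)
    cp = np.zeros(n_seg)
    ce = np.zeros(n_seg)
    decay = math.exp(-(ps / vp + ps / ve) * dt)
    wp = vp / (vp + ve)
    we = ve / (vp + ve)
    ct = np.empty(n_steps)
    for k in range(n_steps):
        cp[1:] = cp[:-1]
        cp[0] = inlet[k]
        mean = wp * cp + we * ce
        d = (cp - ce) * decay
        cp = mean + we * d
        ce = mean - wp * d
        ct[k] = vp * cp.mean() + ve * ce.mean()
    t_steps = np.concatenate([[0.0], (np.arange(n_steps) + 1) * dt])
    return np.interp(t_eval, t_steps, np.concatenate([[0.0], ct]))


def tofts_highres_convolution(ktrans, ve, vp, t_eval, t_aif, cp_aif, upsample=100):
    """Extended-Tofts curve by trapezoid convolution on an ``upsample``-times
    finer uniform grid."""
    n = (len(t_eval) - 1) * upsample + 1
    tf = np.linspace(t_eval[0], t_eval[-1], n)
    dt = tf[1] - tf[0]
    cp = np.interp(tf, t_aif, cp_aif)
    kern = ktrans * np.exp(-(ktrans / ve) * (tf - tf[0]))
    conv = np.convolve(cp, kern)[:n] * dt
    conv -= 0.5 * dt * (cp[0] * kern + cp * kern[0])
    return vp * np.interp(t_eval, t_aif, cp_aif) + np.interp(t_eval, tf, conv)


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of the
    pooled values to the two groups. Returns (U_x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx_x):
        xs = pooled[list(idx_x)]
        ys = np.delete(pooled, list(idx_x))
        diff = xs[:, None] - ys[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_of(range(n1))
    center = n1 * (len(y)) / 2.0
    us = np.array([u_of(c) for c in itertools.combinations(range(len(pooled)), n1)])
    p = float(np.mean(np.abs(us - center) >= abs(u_obs - center) - 1e-12))
    return u_obs, p


def bh_stepup_by_hand(p):
    """Benjamini-Hochberg step-up written directly from its definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def youden_bruteforce(scores, labels, positive):
    """Best Youden J over *every* real threshold (scan all observed scores
    and offsets around them)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    eps = 1e-9 * max(1.0, np.ptp(scores))
    cands = np.unique(np.concatenate([scores - eps, scores, scores + eps]))
    best = -np.inf
    for c in cands:
        j = (pos >= c).mean() + (neg < c).mean() - 1.0
        best = max(best, j)
    return best


def _auc(pos, neg):
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0) + 0.5 * (diff == 0)).mean())


def bootstrap_delong_p(scores_a, scores_b, labels, positive, n_boot=100_000, seed=0):
    """Two-sided p for the paired AUC difference from a stratified bootstrap
    of subjects: z = observed difference / bootstrap SD of the difference."""
    rng = np.random.default_rng(seed)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    ip = np.flatnonzero(labels == positive)
    ineg = np.flatnonzero(labels != positive)
    d_obs = _auc(sa[ip], sa[ineg]) - _auc(sb[ip], sb[ineg])
    diffs = np.empty(n_boot)
    chunk = 2000
    for start in range(0, n_boot, chunk):
        k = min(chunk, n_boot - start)
        bp = ip[rng.integers(0, len(ip), (k, len(ip)))]
        bn = ineg[rng.integers(0, len(ineg), (k, len(ineg)))]
        for model, s in ((0, sa), (1, sb)):
            diff = s[bp][:, :, None] - s[bn][:, None, :]
            auc = ((diff > 0) + 0.5 * (diff == 0)).mean(axis=(1, 2))
            if model == 0:
                a0 = auc
            else:
                diffs[start:start + k] = a0 - auc
    sd = diffs.std(ddof=1)
    from scipy.stats import norm
    return float(2 * norm.sf(abs(d_obs) / sd)) if sd > 0 else 1.0


def spearman_perm_p(x, y):
    """Exact permutation p for Spearman rho computed pair-by-pair with
    scipy (practical for n <= 7)."""
    from scipy.stats import spearmanr
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_obs = abs(spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        r = abs(spearmanr(x, perm).statistic)
        count += r >= rho_obs - 1e-12
        total += 1
    return count / total


def t1_grid_search(signals, flip_angles_deg, tr_ms, t1_grid, m0_grid):
    """Exhaustive least-squares fit of the SPGR signal model over a
    (T1, M0) grid; independent of the linearised estimator."""
    a = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))
    e1 = np.exp(-tr_ms / np.asarray(t1_grid, dtype=float))
    shape_model = (np.sin(a)[None, :] * (1 - e1[:, None])
                   / (1 - e1[:, None] * np.cos(a)[None, :]))  # (n_t1, n_angles)
    best = (np.inf, None, None)
    for m0 in m0_grid:
        rss = ((m0 * shape_model - np.asarray(signals)[None, :]) ** 2).sum(axis=1)
        k = int(np.argmin(rss))
        if rss[k] < best[0]:
            best = (rss[k], t1_grid[k], m0)
    return best[1], best[2]


def random_search_rss(residual_fn, bounds, n_points, rng):
    """Best RSS over ``n_points`` uniform random draws inside ``bounds``."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = np.inf
    for _ in range(n_points):
        x = lo + (hi - lo) * rng.random(len(bounds))
        best = min(best, float(np.sum(residual_fn(x) ** 2)))
    return best
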