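"""Inner Gibbs kernels for the grouped spike-and-slab marker sweep.

Two implementations of the same per-marker conditional update are provided:
a numba-compiled kernel used for real runs, and a plain numpy reference used
in tests to check the fast path draw-for-draw (both consume the same
pre-generated uniform/normal variates, so their trajectories must coincide).

The per-marker conditional, for marker j in group g with slab component l of
prior variance v_l = sigma2_G[g] * C_l:

    r_j    = x_j' (residual + x_j beta_j_old)
    denom  = x_j'x_j + sigma2_eps / v_l
    beta_j | l  ~  N(r_j / denom, sigma2_eps / denom)

and the component indicator is drawn from a categorical with log-weights

    log pi_0                                     (spike)
    log pi_l - 0.5 log(1 + v_l x_j'x_j / sigma2_eps)
             + 0.5 r_j^2 / (sigma2_eps denom)    (slab l)

The residual vector is updated in place by x_j (beta_old - beta_new).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["sweep_markers_numba", "sweep_markers_numpy", "marker_conditional"]


def marker_conditional(rj, xx_j, comp_var_g, log_pi_g, sigma2_eps, rng=None):
    """Component log-weights (and optionally a draw) for one marker.

    ``rj`` is x_j'(residual + x_j beta_old); ``comp_var_g`` the slab prior
    variances sigma2_G * C for the marker's group; ``log_pi_g`` the log
    mixture proportions including the spike at index 0. Returns the
    unnormalized log posterior weights; with ``rng`` also returns a sampled
    (gamma_j, beta_j).
    """
    n_comp = len(log_pi_g)
    lw = np.full(n_comp, -np.inf)
    lw[0] = log_pi_g[0]
    for l in range(1, n_comp):
        v = comp_var_g[l - 1]
        if v <= 0.0 or log_pi_g[l] == -np.inf:
            continue
        denom = xx_j + sigma2_eps / v
        lw[l] = (log_pi_g[l] - 0.5 * np.log1p(v * xx_j / sigma2_eps)
                 + 0.5 * rj * rj / (sigma2_eps * denom))
    if rng is None:
        return lw
    w = np.exp(lw - lw.max())
    comp = int(rng.choice(n_comp, p=w / w.sum()))
    if comp == 0:
        return lw, 0, 0.0
    v = comp_var_g[comp - 1]
    denom = xx_j + sigma2_eps / v
    beta = rj / denom + math.sqrt(sigma2_eps / denom) * rng.standard_normal()
    return lw, comp, beta


@njit(cache=False, fastmath=True)
def _marker_pass(xt, xx, resid, beta, gamma, group_of, comp_var, log_pi,
                 sigma2_eps, order, u_comp, z_norm):
    p, n = xt.shape
    n_comp = log_pi.shape[1]  # L + 1 including the spike
    lw = np.empty(n_comp)
    for t in range(p):
        j = order[t]
        g = group_of[j]
        row = xt[j]
        dot = 0.0
        for i in range(n):
            dot += row[i] * resid[i]
        rj = dot + xx[j] * beta[j]

        lw[0] = log_pi[g, 0]
        best = lw[0]
        for l in range(1, n_comp):
            v = comp_var[g, l - 1]
            if v <= 0.0 or log_pi[g, l] == -np.inf:
                lw[l] = -np.inf
            else:
                denom = xx[j] + sigma2_eps / v
                lw[l] = (log_pi[g, l]
                         - 0.5 * math.log1p(v * xx[j] / sigma2_eps)
                         + 0.5 * rj * rj / (sigma2_eps * denom))
            if lw[l] > best:
                best = lw[l]
        # categorical draw by inverse CDF on the normalized weights
        total = 0.0
        for l in range(n_comp):
            lw[l] = math.exp(lw[l] - best)
            total += lw[l]
        target = u_comp[j] * total
        acc = 0.0
        comp = n_comp - 1
        for l in range(n_comp):
            acc += lw[l]
            if target <= acc:
                comp = l
                break

        if comp == 0:
            new_beta = 0.0
        else:
            v = comp_var[g, comp - 1]
            denom = xx[j] + sigma2_eps / v
            new_beta = rj / denom + math.sqrt(sigma2_eps / denom) * z_norm[j]
        diff = beta[j] - new_beta
        if diff != 0.0:
            for i in range(n):
                resid[i] += row[i] * diff
        beta[j] = new_beta
        gamma[j] = comp


def sweep_markers_numba(xt, xx, resid, beta, gamma, group_of, comp_var,
                        log_pi, sigma2_eps, order, u_comp, z_norm):
    """One full marker pass (numba kernel); mutates resid, beta, gamma."""
    _marker_pass(xt, xx, resid, beta, gamma, group_of, comp_var, log_pi,
                 float(sigma2_eps), order, u_comp, z_norm)


def sweep_markers_numpy(xt, xx, resid, beta, gamma, group_of, comp_var,
                        log_pi, sigma2_eps, order, u_comp, z_norm):
    """Reference implementation of the marker pass (same random stream)."""
    n_comp = log_pi.shape[1]
    for j in order:
        g = group_of[j]
        row = xt[j].astype(np.float64)
        rj = float(row @ resid) + xx[j] * beta[j]
        lw = np.full(n_comp, -np.inf)
        lw[0] = log_pi[g, 0]
        for l in range(1, n_comp):
            v = comp_var[g, l - 1]
            if v <= 0.0 or log_pi[g, l] == -np.inf:
                continue
            denom = xx[j] + sigma2_eps / v
            lw[l] = (log_pi[g, l]
                     - 0.5 * np.log1p(v * xx[j] / sigma2_eps)
                     + 0.5 * rj * rj / (sigma2_eps * denom))
        w = np.exp(lw - lw.max())
        cum = np.cumsum(w)
        comp = int(np.searchsorted(cum, u_comp[j] * cum[-1], side="left"))
        comp = min(comp, n_comp - 1)
        if comp == 0:
            new_beta = 0.0
        else:
            v = comp_var[g, comp - 1]
            denom = xx[j] + sigma2_eps / v
            new_beta = rj / denom + math.sqrt(sigma2_eps / denom) * z_norm[j]
        if beta[j] != new_beta:
            resid += row * (beta[j] - new_beta)
        beta[j] = new_beta
        gamma[j] = comp
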