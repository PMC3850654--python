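"""Numba-compiled inner loops for the two-state HMM.

The recursions (forward-backward with per-step scaling, Baum-Welch) are
inherently sequential in the chain index, so they live here as ``@njit``
kernels operating on plain float64 arrays.  Everything above this layer is
ordinary numpy/scipy code.

State convention: state 0 = null (emission fixed at N(0,1)), state 1 =
non-null (m-component normal mixture).  Transition parameters are the two
exit rates a01 = P(0 -> 1) and a10 = P(1 -> 0); the chain starts from its
stationary distribution pi0 = a10 / (a01 + a10).
"""

import numpy as np
from numba import njit

_LOG2PI = np.log(2.0 * np.pi)
_TINY = 1e-300


@njit(cache=True)
def emission_densities(z, xi, mu, sigma):
    """Per-site emission densities.

    Returns ``(b, comp)`` where ``b`` is (L, 2) with b[l, 0] = phi(z_l)
    (standard normal) and b[l, 1] the mixture density, and ``comp`` is
    (L, m) with comp[l, i] = xi_i * N(z_l; mu_i, sigma_i^2).
    """
    L = z.shape[0]
    m = xi.shape[0]
    b = np.empty((L, 2))
    comp = np.empty((L, m))
    c0 = 1.0 / np.sqrt(2.0 * np.pi)
    for l in range(L):
        b[l, 0] = c0 * np.exp(-0.5 * z[l] * z[l])
        s = 0.0
        for i in range(m):
            d = (z[l] - mu[i]) / sigma[i]
            v = xi[i] * c0 * np.exp(-0.5 * d * d) / sigma[i]
            comp[l, i] = v
            s += v
        b[l, 1] = s
    return b, comp


@njit(cache=True)
def forward_backward_core(b, a01, a10):
    """Scaled forward-backward pass.

    Parameters: emission density matrix ``b`` (L, 2) and the two exit
    rates.  Returns ``(gamma, xc, loglik)``: per-site state posteriors
    (L, 2), expected transition counts (2, 2) summed over the chain, and
    the log-likelihood accumulated from the scaling constants.
    """
    L = b.shape[0]
    a00 = 1.0 - a01
    a11 = 1.0 - a10
    pi0 = a10 / (a01 + a10)
    pi1 = 1.0 - pi0

    alpha = np.empty((L, 2))
    scale = np.empty(L)

    f0 = pi0 * b[0, 0]
    f1 = pi1 * b[0, 1]
    c = f0 + f1
    if c < _TINY:
        c = _TINY
    alpha[0, 0] = f0 / c
    alpha[0, 1] = f1 / c
    scale[0] = c
    for l in range(1, L):
        f0 = (alpha[l - 1, 0] * a00 + alpha[l - 1, 1] * a10) * b[l, 0]
        f1 = (alpha[l - 1, 0] * a01 + alpha[l - 1, 1] * a11) * b[l, 1]
        c = f0 + f1
        if c < _TINY:
            c = _TINY
        alpha[l, 0] = f0 / c
        alpha[l, 1] = f1 / c
        scale[l] = c

    beta = np.empty((L, 2))
    beta[L - 1, 0] = 1.0
    beta[L - 1, 1] = 1.0
    xc = np.zeros((2, 2))
    for l in range(L - 2, -1, -1):
        c = scale[l + 1]
        e0 = b[l + 1, 0] * beta[l + 1, 0]
        e1 = b[l + 1, 1] * beta[l + 1, 1]
        beta[l, 0] = (a00 * e0 + a01 * e1) / c
        beta[l, 1] = (a10 * e0 + a11 * e1) / c
        # expected transition counts for the Baum-Welch M-step
        xc[0, 0] += alpha[l, 0] * a00 * e0 / c
        xc[0, 1] += alpha[l, 0] * a01 * e1 / c
        xc[1, 0] += alpha[l, 1] * a10 * e0 / c
        xc[1, 1] += alpha[l, 1] * a11 * e1 / c

    gamma = np.empty((L, 2))
    for l in range(L):
        g0 = alpha[l, 0] * beta[l, 0]
        g1 = alpha[l, 1] * beta[l, 1]
        s = g0 + g1
        if s < _TINY:
            s = _TINY
        gamma[l, 0] = g0 / s
        gamma[l, 1] = g1 / s

    loglik = 0.0
    for l in range(L):
        loglik += np.log(scale[l])
    return gamma, xc, loglik


@njit(cache=True)
def em_core(z, a01, a10, xi, mu, sigma, tol, max_iter, sigma_floor, rate_floor):
    """Baum-Welch for the two-state HMM with fixed N(0,1) null emission.

    Nested E-step: state posteriors from forward-backward, then mixture
    component responsibilities within state 1.  M-step updates a01, a10
    and the mixture (weights, means, sds); the null emission is never
    touched.  Stops when the relative log-likelihood improvement drops
    below ``tol``.

    Returns ``(a01, a10, xi, mu, sigma, ll_trace, n_iter, n_degenerate)``
    where ``ll_trace[:n_iter]`` is the log-likelihood evaluated at the
    parameters entering each iteration (a non-decreasing sequence up to
    the stationary-start approximation) and ``n_degenerate`` counts
    component collapses that were floored.
    """
    L = z.shape[0]
    m = xi.shape[0]
    ll_trace = np.empty(max_iter)
    ll_prev = -np.inf
    n_iter = 0
    n_degenerate = 0

    for it in range(max_iter):
        b, comp = emission_densities(z, xi, mu, sigma)
        gamma, xc, ll = forward_backward_core(b, a01, a10)
        ll_trace[it] = ll
        n_iter = it + 1
        if it > 0 and ll - ll_prev < tol * (np.abs(ll_prev) + 1.0):
            break
        ll_prev = ll

        # M-step: transitions
        d0 = xc[0, 0] + xc[0, 1]
        d1 = xc[1, 0] + xc[1, 1]
        if d0 > _TINY:
            a01 = xc[0, 1] / d0
        if d1 > _TINY:
            a10 = xc[1, 0] / d1
        if a01 < rate_floor:
            a01 = rate_floor
        if a01 > 1.0 - rate_floor:
            a01 = 1.0 - rate_floor
        if a10 < rate_floor:
            a10 = rate_floor
        if a10 > 1.0 - rate_floor:
            a10 = 1.0 - rate_floor

        # M-step: mixture via component responsibilities r[l, i]
        Ni = np.zeros(m)
        Sz = np.zeros(m)
        for l in range(L):
            denom = b[l, 1]
            if denom < _TINY:
                denom = _TINY
            w = gamma[l, 1] / denom
            for i in range(m):
                r = w * comp[l, i]
                Ni[i] += r
                Sz[i] += r * z[l]
        Ntot = 0.0
        for i in range(m):
            Ntot += Ni[i]
        if Ntot < _TINY:
            Ntot = _TINY
        new_mu = np.empty(m)
        for i in range(m):
            if Ni[i] > 1e-8:
                new_mu[i] = Sz[i] / Ni[i]
            else:
                new_mu[i] = mu[i]
                n_degenerate += 1
        Sv = np.zeros(m)
        for l in range(L):
            denom = b[l, 1]
            if denom < _TINY:
                denom = _TINY
            w = gamma[l, 1] / denom
            for i in range(m):
                d = z[l] - new_mu[i]
                Sv[i] += w * comp[l, i] * d * d
        for i in range(m):
            xi[i] = Ni[i] / Ntot
            if xi[i] < 1e-10:
                xi[i] = 1e-10
            mu[i] = new_mu[i]
            if Ni[i] > 1e-8:
                s = np.sqrt(Sv[i] / Ni[i])
            else:
                s = sigma[i]
            if s < sigma_floor:
                s = sigma_floor
                n_degenerate += 1
            sigma[i] = s
        s = 0.0
        for i in range(m):
            s += xi[i]
        for i in range(m):
            xi[i] /= s

    return a01, a10, xi, mu, sigma, ll_trace[:n_iter].copy(), n_iter, n_degenerate


@njit(cache=True)
def simulate_chain(a01, a10, u_states):
    """Realize a stationary two-state chain from uniform draws (length L)."""
    L = u_states.shape[0]
    pi0 = a10 / (a01 + a10)
    theta = np.empty(L, dtype=np.int8)
    theta[0] = 0 if u_states[0] < pi0 else 1
    for l in range(1, L):
        if theta[l - 1] == 0:
            theta[l] = 1 if u_states[l] < a01 else 0
        else:
            theta[l] = 0 if u_states[l] < a10 else 1
    return theta
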