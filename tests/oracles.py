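"""Independent brute-force oracles used only by the test suite.

Each routine recomputes a quantity by direct enumeration or a plain
log-space implementation, sharing no code path with the package's
numba kernels or dynamic program.
"""

import itertools

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm


def enumerate_posterior(z, model):
    """Exact state posteriors and loglik by summing over all 2^L paths."""
    L = len(z)
    pi = model.pi
    A = model.A
    logp_paths = []
    paths = list(itertools.product((0, 1), repeat=L))
    for path in paths:
        lp = np.log(pi[path[0]])
        for l in range(1, L):
            lp += np.log(A[path[l - 1], path[l]])
        for l, s in enumerate(path):
            dens = norm.pdf(z[l]) if s == 0 else model.f1.pdf(z[l])[0]
            lp += np.log(dens)
        logp_paths.append(lp)
    logp_paths = np.asarray(logp_paths)
    loglik = logsumexp(logp_paths)
    gamma0 = np.empty(L)
    for l in range(L):
        mask = np.array([p[l] == 0 for p in paths])
        gamma0[l] = np.exp(logsumexp(logp_paths[mask]) - loglik)
    return gamma0, loglik


def enumerate_partitions(costs, K_max):
    """Best total cost per change-point count by subset enumeration."""
    nb = costs.shape[0]
    n = nb - 2
    best_cost = np.full(min(K_max, n) + 1, np.inf)
    best_w = [None] * (min(K_max, n) + 1)
    for k in range(len(best_cost)):
        for subset in itertools.combinations(range(1, n + 1), k):
            b = (0,) + subset + (nb - 1,)
            tot = sum(costs[b[i], b[i + 1]] for i in range(len(b) - 1))
            if tot < best_cost[k]:
                best_cost[k] = tot
                best_w[k] = np.asarray(subset, dtype=int)
    return best_cost, best_w


def reference_em_single(z, a01, a10, mu, sigma, n_iter):
    """Plain log-space Baum-Welch, m=1 non-null, null fixed at N(0,1).

    Written independently of the package kernels (log-space recursions,
    explicit loops) to cross-check likelihood ascent and final loglik.
    Returns (a01, a10, mu, sigma, loglik_trace).
    """
    z = np.asarray(z, float)
    L = len(z)
    trace = []
    for _ in range(n_iter):
        logb = np.stack([norm.logpdf(z), norm.logpdf(z, mu, sigma)], axis=1)
        logA = np.log(
            np.array([[1 - a01, a01], [a10, 1 - a10]])
        )
        pi0 = a10 / (a01 + a10)
        logpi = np.log([pi0, 1 - pi0])
        la = np.empty((L, 2))
        la[0] = logpi + logb[0]
        for l in range(1, L):
            for j in range(2):
                la[l, j] = logsumexp(la[l - 1] + logA[:, j]) + logb[l, j]
        lb = np.zeros((L, 2))
        for l in range(L - 2, -1, -1):
            for i in range(2):
                lb[l, i] = logsumexp(logA[i] + logb[l + 1] + lb[l + 1])
        ll = logsumexp(la[-1])
        trace.append(ll)
        lg = la + lb - ll
        g = np.exp(lg)
        # transition counts
        xc = np.zeros((2, 2))
        for l in range(L - 1):
            for i in range(2):
                for j in range(2):
                    xc[i, j] += np.exp(
                        la[l, i] + logA[i, j] + logb[l + 1, j] + lb[l + 1, j] - ll
                    )
        a01 = xc[0, 1] / xc[0].sum()
        a10 = xc[1, 0] / xc[1].sum()
        w = g[:, 1]
        mu = (w * z).sum() / w.sum()
        sigma = np.sqrt((w * (z - mu) ** 2).sum() / w.sum())
        sigma = max(sigma, 0.05)
    return a01, a10, mu, sigma, np.asarray(trace)
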