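"""Two-state stationary HMM for SNP z-values.

The hidden state of SNP ``l`` is theta_l in {0, 1}: 0 means the SNP is not
disease-associated, 1 means it is.  Given the state, the observed z-value
is drawn from the null density N(0, 1) (state 0) or from an m-component
normal mixture (state 1).  The chain is stationary: theta_1 follows the
stationary distribution pi implied by the transition matrix, with
pi_0 = a10 / (a01 + a10).

This module provides simulation, scaled forward-backward posteriors, EM
fitting (Baum-Welch with nested mixture responsibilities; the null
emission is fixed and never re-estimated), and the LIS statistic
LIS_l = P(theta_l = 0 | z_1..L), whose small values flag likely
disease-associated SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import em_core, emission_densities, forward_backward_core, simulate_chain

logger = logging.getLogger(__name__)

SIGMA_FLOOR_DEFAULT = 0.05
RATE_FLOOR = 1e-6


class FitError(RuntimeError):
    """All EM restarts failed for a series."""


@dataclass
class EmissionMixture:
    """Non-null emission density: sum_i xi_i N(mu_i, sigma_i^2)."""

    xi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.xi.shape == self.mu.shape == self.sigma.shape):
            raise ValueError("xi, mu, sigma must have equal length")
        if self.m < 1:
            raise ValueError("mixture needs at least one component")
        if np.any(self.xi < 0) or abs(self.xi.sum() - 1.0) > 1e-10:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if np.any(self.sigma <= 0):
            raise ValueError("mixture sds must be positive")

    @property
    def m(self) -> int:
        return len(self.xi)

    def pdf(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        d = (z[:, None] - self.mu[None, :]) / self.sigma[None, :]
        return (
            self.xi[None, :]
            * np.exp(-0.5 * d * d)
            / (np.sqrt(2 * np.pi) * self.sigma[None, :])
        ).sum(axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.m, size=n, p=self.xi)
        return rng.normal(self.mu[comp], self.sigma[comp])


@dataclass
class RegionHMM:
    """Parameter bundle for one homogeneous region.

    ``A`` is the 2x2 transition matrix with A[i, j] = P(theta_{l+1} = j |
    theta_l = i); the stationary distribution is always derived from A,
    never stored independently.  The null emission is fixed at N(0, 1).
    """

    A: np.ndarray
    f1: EmissionMixture

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (2, 2):
            raise ValueError("transition matrix must be 2x2")
        if np.any(self.A < 0) or np.any(self.A > 1):
            raise ValueError("transition entries must lie in [0, 1]")
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("transition matrix rows must sum to 1")

    @classmethod
    def from_rates(cls, a01: float, a10: float, f1: EmissionMixture) -> "RegionHMM":
        return cls(A=np.array([[1 - a01, a01], [a10, 1 - a10]]), f1=f1)

    @property
    def a01(self) -> float:
        return float(self.A[0, 1])

    @property
    def a10(self) -> float:
        return float(self.A[1, 0])

    @property
    def pi(self) -> np.ndarray:
        """Stationary distribution (pi0, pi1), pi0 = a10 / (a01 + a10)."""
        denom = self.a01 + self.a10
        if denom <= 0:
            raise ValueError("chain has no unique stationary distribution")
        p0 = self.a10 / denom
        return np.array([p0, 1.0 - p0])

    @property
    def n_free_parameters(self) -> int:
        """a01, a10, m means, m sds, m-1 free weights (pi is derived)."""
        return 3 * self.f1.m + 1


@dataclass
class ZSeries:
    """One chromosome's ordered z-values, optionally with simulation truth."""

    chrom: str
    z: np.ndarray
    theta_truth: np.ndarray | None = None
    snp_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1:
            raise ValueError("z must be one-dimensional")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z-values must be finite")
        if self.theta_truth is not None:
            self.theta_truth = np.asarray(self.theta_truth, dtype=np.int8)
            if self.theta_truth.shape != self.z.shape:
                raise ValueError("theta_truth must align with z")
            if not np.all(np.isin(self.theta_truth, (0, 1))):
                raise ValueError("theta_truth entries must be 0 or 1")

    def __len__(self) -> int:
        return len(self.z)

    def slice(self, start: int, stop: int) -> "ZSeries":
        """Contiguous sub-series over the half-open index window [start, stop)."""
        truth = None if self.theta_truth is None else self.theta_truth[start:stop]
        ids = None if self.snp_ids is None else self.snp_ids[start:stop]
        return ZSeries(self.chrom, self.z[start:stop], truth, ids)


def simulate_hmm(model: RegionHMM, length: int, seed) -> ZSeries:
    """Draw one stationary realization of the HMM.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The hidden
    path is stored in ``theta_truth``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    theta = simulate_chain(model.a01, model.a10, rng.uniform(size=length))
    z = rng.standard_normal(length)
    idx1 = np.flatnonzero(theta == 1)
    if len(idx1):
        z[idx1] = model.f1.sample(len(idx1), rng)
    return ZSeries(chrom="sim", z=z, theta_truth=theta)


def _emissions(z: np.ndarray, model: RegionHMM) -> np.ndarray:
    b, _ = emission_densities(
        np.ascontiguousarray(z, dtype=float), model.f1.xi, model.f1.mu, model.f1.sigma
    )
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite emission density; check mixture parameters")
    return b


def forward_backward(z: ZSeries | np.ndarray, model: RegionHMM):
    """Posterior null probabilities and log-likelihood.

    Returns ``(gamma0, loglik)`` with gamma0_l = P(theta_l = 0 | z, Psi).
    Scaled (normalized) recursions keep the pass stable for chains up to
    millions of sites.
    """
    zv = z.z if isinstance(z, ZSeries) else np.asarray(z, dtype=float)
    b = _emissions(zv, model)
    gamma, _, loglik = forward_backward_core(b, model.a01, model.a10)
    return gamma[:, 0].copy(), float(loglik)


def lis(z: ZSeries | np.ndarray, model: RegionHMM) -> np.ndarray:
    """LIS_l = P(theta_l = 0 | all z in the region) under the fitted model."""
    gamma0, _ = forward_backward(z, model)
    return gamma0


def min_fit_length(m: int) -> int:
    """Smallest series length accepted by em_fit: twice the parameter count."""
    return 2 * (3 * m + 1)


def _initial_params(z: np.ndarray, m: int, rng: np.random.Generator, jitter: bool):
    """Moment-free EM start: fixed exit rates, tail-quantile means."""
    a01, a10 = 0.05, 0.3
    cut = np.quantile(z, 0.8)
    tail = z[z > cut]
    if len(tail) < m:
        tail = np.sort(z)[-max(m, 2):]
    qs = (np.arange(m) + 0.5) / m
    mu = np.quantile(tail, qs)
    sigma = np.ones(m)
    xi = np.full(m, 1.0 / m)
    if jitter:
        a01 = float(np.clip(a01 * np.exp(rng.normal(0, 0.5)), 1e-4, 0.5))
        a10 = float(np.clip(a10 * np.exp(rng.normal(0, 0.5)), 1e-4, 0.9))
        mu = mu + rng.normal(0, 0.5, size=m)
    return a01, a10, xi, mu, sigma


def em_fit(
    z: ZSeries | np.ndarray,
    m: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 3,
    seed=0,
    sigma_floor: float = SIGMA_FLOOR_DEFAULT,
    return_trace: bool = False,
):
    """Maximum-likelihood fit by Baum-Welch.

    The E-step computes state posteriors and, within the non-null state,
    mixture component responsibilities; the M-step updates a01, a10 and
    the mixture (the null N(0,1) is fixed).  Restarts use jittered
    initializations; the best final log-likelihood wins.

    Returns ``(model, loglik, n_iter)``; with ``return_trace=True`` a
    fourth element gives the per-iteration log-likelihood trace of the
    winning restart.
    """
    zv = np.ascontiguousarray(z.z if isinstance(z, ZSeries) else z, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if len(zv) < min_fit_length(m):
        raise ValueError(
            f"series of length {len(zv)} too short to fit m={m} "
            f"(need >= {min_fit_length(m)})"
        )
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        a01, a10, xi, mu, sigma = _initial_params(zv, m, rng, jitter=(r > 0))
        try:
            a01, a10, xi, mu, sigma, trace, n_iter, n_deg = em_core(
                zv, a01, a10, xi.copy(), mu.copy(), sigma.copy(),
                tol, max_iter, sigma_floor, RATE_FLOOR,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        ll = trace[-1]
        if not np.isfinite(ll):
            continue
        if n_deg:
            # routine when m is over-specified for the segment
            logger.debug(
                "EM restart %d: %d degenerate component updates floored", r, n_deg
            )
        if best is None or ll > best[1]:
            best = ((a01, a10, xi, mu, sigma), ll, n_iter, trace)
    if best is None:
        raise FitError("all EM restarts failed")
    (a01, a10, xi, mu, sigma), ll, n_iter, trace = best
    order = np.argsort(mu)  # canonical component order
    model = RegionHMM.from_rates(
        a01, a10, EmissionMixture(xi[order] / xi.sum(), mu[order], sigma[order])
    )
    if return_trace:
        return model, float(ll), int(n_iter), trace
    return model, float(ll), int(n_iter)
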