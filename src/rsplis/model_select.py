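"""Adaptive criterion-based partitioning (ACP).

Joint selection, per chromosome, of a change-point set w (a subset of a
candidate set) and the non-null mixture size m shared by all regions.
The selection minimizes the penalized criterion

    crit_lambda(m, w) = -loglik(z | Psi_hat, m, w) + lambda * (|w| + 1) * D_m,

where D_m = 3m + 1 counts the free parameters of one region (two
transition exits, m means, m sds, m - 1 weights; the stationary
distribution is derived).  At lambda = ln(L)/2 the penalty is exactly the
BIC penalty, which defines the BICP comparator.  The operational lambda
is calibrated from the data by a sliding-window dimension jump: scan a
log-spaced lambda grid, find the largest drop of the selected model
dimension across a window of width h, and set lambda_opt to a multiple
(default 2) of the post-jump grid point.

The partition search is exact over the candidate set: segment costs
(-max loglik per candidate segment, from EM fits) feed a Bellman
recursion over the number of change points.  Costs do not depend on
lambda, so one cost table serves the whole grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .hmm_core import RegionHMM, ZSeries, em_fit, min_fit_length

logger = logging.getLogger(__name__)

INFEASIBLE = np.inf


@dataclass
class CandidateSet:
    """Interior candidate change points, 1-based SNP indices.

    A change point at ``i`` puts the region boundary after SNP ``i``:
    region r covers the half-open index interval (b_{r-1}, b_r].
    """

    positions: np.ndarray
    L: int
    Lmin: int = 300

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        if len(self.positions):
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("candidate positions must be strictly increasing")
            if self.positions[0] < 1 or self.positions[-1] >= self.L:
                raise ValueError("candidate positions must be interior to [1, L)")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def boundaries(self) -> np.ndarray:
        """0, candidates..., L — the n+2 segment boundary values."""
        return np.concatenate(([0], self.positions, [self.L]))


def candidate_grid(L: int, spacing: int = 300) -> CandidateSet:
    """Uniform candidate grid {spacing * i : spacing * i <= L - spacing}.

    A chromosome too short for any interior candidate yields an empty set
    (the model is then forced to a single region).
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    n = (L - spacing) // spacing
    positions = spacing * np.arange(1, max(n, 0) + 1)
    return CandidateSet(positions=positions, L=L, Lmin=spacing)


@dataclass
class ChromosomeModel:
    """Selected partition of one chromosome and its per-region HMMs."""

    chrom: str
    w: np.ndarray                      # change-point SNP indices, 1-based
    m: int
    regions: list[RegionHMM]
    total_loglik: float
    lambda_used: float
    selection: "PenalizedSelection | None" = None

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=int)
        if len(self.regions) != len(self.w) + 1:
            raise ValueError("need exactly |w| + 1 regions")

    def region_bounds(self, L: int) -> list[tuple[int, int]]:
        """Half-open 0-based (start, stop) index windows of the regions."""
        b = np.concatenate(([0], self.w, [L]))
        return [(int(b[r]), int(b[r + 1])) for r in range(len(self.regions))]


def segment_costs(
    z: ZSeries,
    cand: CandidateSet,
    m: int,
    config: AnalysisConfig | None = None,
    seed=0,
) -> np.ndarray:
    """-max loglik of every candidate segment at mixture size m.

    ``cost[i, j]`` (0 <= i < j <= n+1, boundary indices) is the negative
    maximized log-likelihood of z over (b_i, b_j], from an EM fit with the
    segment restart budget.  Segments too short to fit are +inf.  Costs do
    not depend on lambda and are reused across the whole lambda grid.
    """
    config = config or AnalysisConfig()
    b = cand.boundaries
    nb = len(b)
    cost = np.full((nb, nb), INFEASIBLE)
    ss = np.random.SeedSequence(entropy=_entropy(seed))
    seeds = ss.generate_state(nb * nb)
    for i in range(nb - 1):
        for j in range(i + 1, nb):
            seg = z.slice(int(b[i]), int(b[j]))
            if len(seg) < max(min_fit_length(m), config.min_segment_length):
                continue
            try:
                _, ll, _ = em_fit(
                    seg, m,
                    tol=config.segment_em_tol,
                    max_iter=config.segment_em_max_iter,
                    n_restarts=config.segment_restarts,
                    seed=int(seeds[i * nb + j]),
                    sigma_floor=config.sigma_floor,
                )
            except Exception as exc:
                logger.warning("segment (%d, %d] unfit at m=%d: %s", b[i], b[j], m, exc)
                continue
            cost[i, j] = -ll
    return cost


def _entropy(seed) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31))
    return int(seed)


def dp_partition(costs: np.ndarray, K_max: int):
    """Exact best partition for every change-point count k = 0..K_max.

    Bellman recursion over suffixes: S_k(i) = min_{j>i} cost(i, j) +
    S_{k-1}(j), with S_0(i) = cost(i, n+1).  Returns
    ``(best_cost_by_k, best_w_by_k)`` where w is a list of boundary
    indices (1..n, positions into the candidate set); infeasible k have
    cost +inf and w None.  Ties resolve to the lexicographically smallest
    w via greedy left-to-right reconstruction.
    """
    nb = costs.shape[0]
    n = nb - 2
    K_max = min(K_max, n) if n >= 0 else 0
    S = np.full((K_max + 1, nb), INFEASIBLE)
    S[0, : nb - 1] = costs[: nb - 1, nb - 1]
    for k in range(1, K_max + 1):
        for i in range(nb - 1):
            # last boundary index usable as the k-th remaining split is n
            best = INFEASIBLE
            for j in range(i + 1, n + 1):
                v = costs[i, j] + S[k - 1, j]
                if v < best:
                    best = v
            S[k, i] = best
    best_cost_by_k = S[:, 0].copy()
    best_w_by_k: list[np.ndarray | None] = []
    for k in range(K_max + 1):
        if not np.isfinite(best_cost_by_k[k]):
            best_w_by_k.append(None)
            continue
        w = []
        i, kk = 0, k
        while kk > 0:
            for j in range(i + 1, n + 1):
                if costs[i, j] + S[kk - 1, j] == S[kk, i]:
                    w.append(j)
                    i, kk = j, kk - 1
                    break
            else:  # pragma: no cover - guarded by feasibility
                raise RuntimeError("DP backtrack failed")
        best_w_by_k.append(np.asarray(w, dtype=int))
    return best_cost_by_k, best_w_by_k


def model_dimension(m: int, k: int) -> int:
    """D(m, w) = (|w| + 1) * D_m with D_m = 3m + 1."""
    return (k + 1) * (3 * m + 1)


def criterion(loglik: float, m: int, k: int, lambda_: float) -> float:
    """Penalized criterion -loglik + lambda * (k+1) * (3m+1)."""
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    return -loglik + lambda_ * model_dimension(m, k)


def bic_lambda(L: int) -> float:
    """lambda = ln(L)/2, at which the penalty is exactly BIC's."""
    return np.log(L) / 2.0


@dataclass
class PartitionTables:
    """Lambda-independent DP output per mixture size, reused across the grid."""

    neg_loglik_by_k: dict[int, np.ndarray]       # m -> array over k
    w_by_k: dict[int, list[np.ndarray | None]]   # m -> per-k change points
    K_max: int
    m_max: int


def fit_partition_tables(
    z: ZSeries,
    cand: CandidateSet,
    K_max: int,
    m_max: int,
    config: AnalysisConfig | None = None,
    seed=0,
) -> PartitionTables:
    """Segment EM fits + DP for every m in 1..m_max (the expensive part)."""
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(entropy=_entropy(seed))
    seeds = ss.generate_state(m_max)
    neg_ll, ws = {}, {}
    for m in range(1, m_max + 1):
        costs = segment_costs(z, cand, m, config, seed=int(seeds[m - 1]))
        neg_ll[m], ws[m] = dp_partition(costs, K_max)
    return PartitionTables(neg_ll, ws, K_max=K_max, m_max=m_max)


def select_from_tables(tables: PartitionTables, lambda_: float):
    """Minimize the criterion over (m, k, w) at a fixed lambda.

    Ties break to the smallest k, then the smallest m (w is then unique
    from the DP's lexicographic tie-break).  Returns
    ``(m_hat, w_hat, crit_value, D)``.
    """
    best = None
    for m in range(1, tables.m_max + 1):
        neg_ll = tables.neg_loglik_by_k[m]
        for k in range(len(neg_ll)):
            if not np.isfinite(neg_ll[k]):
                continue
            c = neg_ll[k] + lambda_ * model_dimension(m, k)
            key = (c, k, m)
            if best is None or key < best[0]:
                best = (key, m, k)
    if best is None:
        raise RuntimeError("no feasible model")
    _, m, k = best
    w = tables.w_by_k[m][k]
    crit_value = float(tables.neg_loglik_by_k[m][k] + lambda_ * model_dimension(m, k))
    return m, w, crit_value, model_dimension(m, k)


def algorithm1(
    z: ZSeries,
    cand: CandidateSet,
    lambda_: float,
    K_max: int,
    m_max: int,
    config: AnalysisConfig | None = None,
    seed=0,
    tables: PartitionTables | None = None,
):
    """Joint (m, w) selection at a given lambda.

    Returns ``(m_hat, w_hat, crit_value, D)`` with ``w_hat`` expressed as
    1-based SNP positions.  ``tables`` may carry precomputed DP output.
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    if tables is None:
        tables = fit_partition_tables(z, cand, K_max, m_max, config, seed)
    m, w_idx, crit_value, D = select_from_tables(tables, lambda_)
    w = cand.positions[w_idx - 1] if len(w_idx) else np.empty(0, dtype=int)
    return m, w, crit_value, D


@dataclass
class PenalizedSelection:
    """Per-lambda selection trace and the calibrated penalty."""

    lambda_grid: np.ndarray
    m_by_lambda: np.ndarray
    k_by_lambda: np.ndarray
    dimension_by_lambda: np.ndarray
    crit_by_lambda: np.ndarray
    h: int
    lambda_jump: float
    lambda_opt: float
    fell_back_to_bic: bool = False
    w_by_lambda: list = field(default_factory=list, repr=False)


def lambda_grid_default(L: int, T: int) -> np.ndarray:
    """Log-spaced grid bracketing the BIC value ln(L)/2 by >10x each way."""
    lo = np.log(L) / (2.0 * T)
    hi = 10.0 * np.log(L)
    return np.geomspace(lo, hi, T)


def dimension_jump(
    z: ZSeries,
    cand: CandidateSet,
    T: int = 50,
    h: int = 2,
    K_max: int = 8,
    m_max: int = 5,
    config: AnalysisConfig | None = None,
    seed=0,
    tables: PartitionTables | None = None,
    lambda_factor: float | None = None,
) -> PenalizedSelection:
    """Sliding-window dimension jump calibration of lambda.

    Runs the (m, w) selection on a log-spaced lambda grid of length T;
    the selected dimension D(lambda) is non-increasing.  The windowed
    jumps J_t = D(lambda_t) - D(lambda_{t+h}) aggregate up to h
    successive drops so that staircases of small jumps are not missed;
    h = 1 recovers the plain dimension-jump method.  The largest jump
    (earliest on ties) locates lambda_jump = lambda_{t*+h}, and the
    operational penalty is lambda_opt = lambda_factor * lambda_jump.  A
    flat trace falls back to the BIC value ln(L)/2 with a warning.
    """
    if T < 2 or not (1 <= h < T):
        raise ValueError("need T >= 2 and 1 <= h < T")
    config = config or AnalysisConfig()
    if lambda_factor is None:
        lambda_factor = config.lambda_factor
    if tables is None:
        tables = fit_partition_tables(z, cand, K_max, m_max, config, seed)
    grid = lambda_grid_default(len(z), T)
    ms = np.empty(T, dtype=int)
    ks = np.empty(T, dtype=int)
    Ds = np.empty(T, dtype=int)
    crits = np.empty(T)
    ws = []
    for t, lam in enumerate(grid):
        m, w_idx, c, D = select_from_tables(tables, lam)
        ms[t], ks[t] = m, len(w_idx)
        Ds[t], crits[t] = D, c
        ws.append(w_idx)
    jumps = Ds[: T - h] - Ds[h:]
    t_star = int(np.argmax(jumps))  # argmax takes the smallest index on ties
    if jumps[t_star] <= 0:
        logger.warning("flat dimension trace: falling back to BIC lambda")
        lam_jump = bic_lambda(len(z))
        lam_opt = lam_jump
        fallback = True
    else:
        lam_jump = float(grid[t_star + h])
        lam_opt = lambda_factor * lam_jump
        fallback = False
    return PenalizedSelection(
        lambda_grid=grid, m_by_lambda=ms, k_by_lambda=ks,
        dimension_by_lambda=Ds, crit_by_lambda=crits, h=h,
        lambda_jump=float(lam_jump), lambda_opt=float(lam_opt),
        fell_back_to_bic=fallback, w_by_lambda=ws,
    )


def acp_select(
    z: ZSeries,
    cand: CandidateSet,
    config: AnalysisConfig | None = None,
    mode: str = "acp",
    seed=0,
) -> ChromosomeModel:
    """Full per-chromosome model selection and region refits.

    ``mode='acp'`` calibrates lambda by the sliding-window dimension jump;
    ``mode='bicp'`` fixes lambda = ln(L)/2 (the BIC-penalty comparator).
    The selected regions are refit with the larger restart budget.
    """
    if mode not in ("acp", "bicp"):
        raise ValueError("mode must be 'acp' or 'bicp'")
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(entropy=_entropy(seed))
    s_tables, s_refit = (int(x) for x in ss.generate_state(2))
    tables = fit_partition_tables(z, cand, config.K_max, config.m_max, config, s_tables)
    selection = None
    if mode == "acp":
        selection = dimension_jump(
            z, cand, T=config.T, h=config.h, K_max=config.K_max,
            m_max=config.m_max, config=config, tables=tables,
        )
        lam = selection.lambda_opt
    else:
        lam = bic_lambda(len(z))
    m, w, _, _ = algorithm1(
        z, cand, lam, config.K_max, config.m_max, config, tables=tables
    )
    bounds = np.concatenate(([0], w, [len(z)]))
    refit_seeds = np.random.SeedSequence(entropy=s_refit).generate_state(len(bounds))
    regions, total_ll = [], 0.0
    for r in range(len(bounds) - 1):
        seg = z.slice(int(bounds[r]), int(bounds[r + 1]))
        model, ll, _ = em_fit(
            seg, m,
            tol=config.em_tol, max_iter=config.em_max_iter,
            n_restarts=config.refit_restarts, seed=int(refit_seeds[r]),
            sigma_floor=config.sigma_floor,
        )
        regions.append(model)
        total_ll += ll
    return ChromosomeModel(
        chrom=z.chrom, w=w, m=m, regions=regions,
        total_loglik=float(total_ll), lambda_used=float(lam), selection=selection,
    )
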