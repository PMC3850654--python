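"""Simulation designs for benchmarking ACP, RSPLIS and PLIS.

Three study families:

* a five-region single-chromosome design for change-point / component
  selection (regions share the null-exit rate 0.02 but differ in the
  non-null exit rate and in a two-component non-null mixture);
* two-chromosome, two-region designs for FDR/FNR comparison, one varying
  the dependence of region 2 (``upsilon1`` added to the non-null exit
  rate) and one varying the non-null mean separation (``upsilon2``);
* a case-control genotype design in which subjects are drawn from a
  synthetic haplotype pool with blockwise LD and disease status follows
  a logistic model on eight causal SNPs.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .config import AnalysisConfig
from .fdr import evaluate_decisions, plis_run, rsplis_run
from .hmm_core import EmissionMixture, RegionHMM, ZSeries, simulate_hmm
from .model_select import (
    bic_lambda,
    candidate_grid,
    dimension_jump,
    fit_partition_tables,
    select_from_tables,
)
from .ztransform import GenotypeMatrix, genotypes_to_z

logger = logging.getLogger(__name__)


@dataclass
class RegionSpec:
    """One stationary region: length, exit rates, non-null mixture."""

    length: int
    a01: float
    a10: float
    f1: EmissionMixture

    def model(self) -> RegionHMM:
        return RegionHMM.from_rates(self.a01, self.a10, self.f1)


@dataclass
class SimScenario:
    """A full multi-chromosome design plus its ground truth."""

    name: str
    chromosomes: list[list[RegionSpec]]
    m_true: int
    replications: int = 100
    seed: int = 0

    def true_changepoints(self, c: int = 0) -> np.ndarray:
        lengths = np.array([r.length for r in self.chromosomes[c]])
        return np.cumsum(lengths)[:-1]

    def chrom_length(self, c: int = 0) -> int:
        return int(sum(r.length for r in self.chromosomes[c]))


def _mix(spec: list[tuple[float, float]]) -> EmissionMixture:
    """[(weight, mean), ...] with unit sds."""
    w = np.array([s[0] for s in spec])
    mu = np.array([s[1] for s in spec])
    return EmissionMixture(xi=w, mu=mu, sigma=np.ones(len(w)))


# The five-region selection benchmark: same null-exit rate everywhere,
# region-specific non-null exit rates and two-component mixtures.
_FIVE_REGION_ROWS = [
    (0.02, 0.20, [(0.1, 1.0), (0.9, 3.0)]),
    (0.02, 0.95, [(0.8, 1.5), (0.2, 4.5)]),
    (0.02, 0.45, [(0.4, 1.5), (0.6, 3.5)]),
    (0.02, 0.15, [(0.2, 1.0), (0.8, 3.0)]),
    (0.02, 0.15, [(0.2, 1.0), (0.8, 3.0)]),
]


def make_scenario(
    table: str | int,
    L0: int = 600,
    upsilon1: float = 0.0,
    upsilon2: float = 0.5,
    mu_base: float = 1.0,
    replications: int = 100,
    seed: int = 0,
) -> SimScenario:
    """Build one of the named designs.

    ``table=1`` — five regions of equal length ``L0`` on one chromosome.
    ``table=4`` (``'case1'``) — two chromosomes x two 2000-SNP regions;
    ``upsilon1`` perturbs region-2 non-null exit rates and the non-null
    means chain as mu21 = mu11 + 1.5 (chrom 1), mu11' = mu11 + 0.5,
    mu21' = mu11' + 2.0 from the base mean ``mu_base``.
    ``table=5`` (``'case2'``) — same layout with all exit rates fixed at
    (0.02, 0.025) and mean separations mu21 = mu11 + ``upsilon2``.
    """
    key = str(table).lower()
    if key in ("1", "table1"):
        chroms = [[RegionSpec(L0, a01, a10, _mix(mx)) for a01, a10, mx in _FIVE_REGION_ROWS]]
        return SimScenario(f"table1_L{L0}", chroms, m_true=2,
                           replications=replications, seed=seed)
    if key in ("4", "case1"):
        if not 0 <= upsilon1 <= 0.45:
            raise ValueError("upsilon1 must lie in [0, 0.45]")
        mu11 = mu_base
        mu11_2 = mu11 + 0.5
        chroms = [
            [
                RegionSpec(2000, 0.02, 0.03, _mix([(1.0, mu11)])),
                RegionSpec(2000, 0.02, 0.03 + upsilon1, _mix([(1.0, mu11 + 1.5)])),
            ],
            [
                RegionSpec(2000, 0.02, 0.05, _mix([(1.0, mu11_2)])),
                RegionSpec(2000, 0.02, 0.05 + upsilon1, _mix([(1.0, mu11_2 + 2.0)])),
            ],
        ]
        return SimScenario(f"case1_u{upsilon1}_mu{mu_base}", chroms, m_true=1,
                           replications=replications, seed=seed)
    if key in ("5", "case2"):
        if not 0 < upsilon2 <= 2:
            raise ValueError("upsilon2 must lie in (0, 2]")
        mu11 = mu_base
        mu11_2 = mu11 + 0.5
        chroms = [
            [
                RegionSpec(2000, 0.02, 0.025, _mix([(1.0, mu11)])),
                RegionSpec(2000, 0.02, 0.025, _mix([(1.0, mu11 + upsilon2)])),
            ],
            [
                RegionSpec(2000, 0.02, 0.025, _mix([(1.0, mu11_2)])),
                RegionSpec(2000, 0.02, 0.025, _mix([(1.0, mu11_2 + upsilon2)])),
            ],
        ]
        return SimScenario(f"case2_u{upsilon2}_mu{mu_base}", chroms, m_true=1,
                           replications=replications, seed=seed)
    raise ValueError(f"unknown scenario table: {table!r}")


def simulate_scenario(scenario: SimScenario, seed) -> list[ZSeries]:
    """One replication: independent stationary regions, concatenated."""
    ss = np.random.SeedSequence(entropy=int(seed))
    out = []
    for c, regions in enumerate(scenario.chromosomes):
        child = ss.spawn(1)[0]
        region_seeds = child.generate_state(len(regions))
        z_parts, t_parts = [], []
        for spec, s in zip(regions, region_seeds):
            zs = simulate_hmm(spec.model(), spec.length, int(s))
            z_parts.append(zs.z)
            t_parts.append(zs.theta_truth)
        out.append(
            ZSeries(
                chrom=f"chr{c + 1}",
                z=np.concatenate(z_parts),
                theta_truth=np.concatenate(t_parts),
            )
        )
    return out


def score_changepoints(
    w_hat: np.ndarray, w_true: np.ndarray, candidates: np.ndarray
) -> tuple[float, float]:
    """(sensitivity, specificity) of a selected change-point set.

    Sensitivity: fraction of true change points present in ``w_hat``.
    Specificity: fraction of non-true candidates absent from ``w_hat``.
    """
    w_hat = set(np.asarray(w_hat, dtype=int).tolist())
    w_true = set(np.asarray(w_true, dtype=int).tolist())
    false_cand = set(np.asarray(candidates, dtype=int).tolist()) - w_true
    sens = len(w_hat & w_true) / max(1, len(w_true))
    spec = len(false_cand - w_hat) / max(1, len(false_cand))
    return sens, spec


def run_changepoint_study(
    scenario: SimScenario,
    methods=("acp", "bicp"),
    h: int = 2,
    reps: int | None = None,
    seed: int = 0,
    config: AnalysisConfig | None = None,
    spacing: int = 300,
) -> dict:
    """Change-point and component-count selection benchmark.

    Per replication, simulate the scenario's single chromosome, run the
    penalized selection for each method (they share one segment-cost
    table, differing only in how lambda is set), and score change-point
    sensitivity/specificity and the rate of selecting the true m.
    Returns per-method means plus per-replication arrays.
    """
    if isinstance(methods, str):
        methods = (methods,)
    reps = reps or scenario.replications
    config = config or AnalysisConfig()
    w_true = scenario.true_changepoints(0)
    L = scenario.chrom_length(0)
    cand = candidate_grid(L, spacing)
    ss = np.random.SeedSequence(entropy=int(seed))
    per = {meth: {"sens": [], "spec": [], "m_correct": [], "lambda": []} for meth in methods}
    for rep in range(reps):
        sim_seed, fit_seed = ss.spawn(1)[0].generate_state(2)
        z = simulate_scenario(scenario, int(sim_seed))[0]
        tables = fit_partition_tables(
            z, cand, config.K_max, config.m_max, config, int(fit_seed)
        )
        for meth in methods:
            if meth == "acp":
                sel = dimension_jump(
                    z, cand, T=config.T, h=h, K_max=config.K_max,
                    m_max=config.m_max, config=config, tables=tables,
                )
                lam = sel.lambda_opt
            elif meth == "bicp":
                lam = bic_lambda(L)
            else:
                raise ValueError(f"unknown method {meth!r}")
            m_hat, w_idx, _, _ = select_from_tables(tables, lam)
            w_hat = cand.positions[w_idx - 1] if len(w_idx) else np.empty(0, int)
            sens, spec = score_changepoints(w_hat, w_true, cand.positions)
            per[meth]["sens"].append(sens)
            per[meth]["spec"].append(spec)
            per[meth]["m_correct"].append(float(m_hat == scenario.m_true))
            per[meth]["lambda"].append(lam)
    out = {}
    for meth in methods:
        out[meth] = {
            "sensitivity": float(np.mean(per[meth]["sens"])),
            "specificity": float(np.mean(per[meth]["spec"])),
            "m_correct_rate": float(np.mean(per[meth]["m_correct"])),
            "per_rep": {k: np.asarray(v) for k, v in per[meth].items()},
        }
    out["reps"] = reps
    return out


def run_fdr_study(
    scenario: SimScenario,
    alpha: float = 0.1,
    reps: int | None = None,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> dict:
    """FDR/FNR comparison of RSPLIS vs PLIS on a two-chromosome design.

    Returns per-method mean FDR, FNR and sensitivity with per-replication
    arrays.  The default configuration for this design is K_max=4,
    m_max=3, h=2 over a 300-spaced candidate grid.
    """
    reps = reps or scenario.replications
    config = config or AnalysisConfig(K_max=4, m_max=3, h=2)
    ss = np.random.SeedSequence(entropy=int(seed))
    per = {meth: {"fdp": [], "fnp": [], "sens": []} for meth in ("rsplis", "plis")}
    for rep in range(reps):
        sim_seed, rs_seed, pl_seed = ss.spawn(1)[0].generate_state(3)
        chroms = simulate_scenario(scenario, int(sim_seed))
        truth = {z.chrom: z.theta_truth for z in chroms}
        results = {
            "rsplis": rsplis_run(chroms, alpha, config, seed=int(rs_seed)),
            "plis": plis_run(chroms, alpha, config, seed=int(pl_seed)),
        }
        for meth, res in results.items():
            fdp, fnp, sens = evaluate_decisions(res, truth)
            per[meth]["fdp"].append(fdp)
            per[meth]["fnp"].append(fnp)
            per[meth]["sens"].append(sens)
    out = {"reps": reps, "alpha": alpha}
    for meth in per:
        out[meth] = {
            "fdr": float(np.mean(per[meth]["fdp"])),
            "fnr": float(np.mean(per[meth]["fnp"])),
            "sensitivity": float(np.mean(per[meth]["sens"])),
            "per_rep": {k: np.asarray(v) for k, v in per[meth].items()},
        }
    return out


# ---------------------------------------------------------------------------
# Genotype-based study


@dataclass
class HaplotypePool:
    """Binary haplotypes (haplotypes x SNPs) with blockwise LD.

    Within a block, each allele copies its left neighbour with the block
    copy probability and is otherwise redrawn at the SNP's allele
    frequency; blocks are independent, mimicking haplotype-block LD.
    """

    haplotypes: np.ndarray
    block_starts: np.ndarray
    freqs: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


def build_synthetic_pool(
    n_haplotypes: int = 120,
    n_snps: int = 8000,
    block_length: int = 25,
    copy_prob: float = 0.9,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> HaplotypePool:
    """Seeded synthetic haplotype pool with first-order Markov LD.

    Synthetic stand-in for a phased reference panel: allele frequencies
    are uniform on ``maf_range`` (bounded away from 0), and within each
    block allele ``l`` equals allele ``l-1`` with probability
    ``copy_prob``, else an independent Bernoulli(freq_l) draw.
    """
    if not 0 <= copy_prob <= 1:
        raise ValueError("copy_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=n_snps)
    fresh = (rng.uniform(size=(n_haplotypes, n_snps)) < freqs).astype(np.int8)
    copy = rng.uniform(size=(n_haplotypes, n_snps)) < copy_prob
    block_starts = np.arange(0, n_snps, block_length)
    hap = np.empty_like(fresh)
    for j in range(n_snps):
        if j in block_starts or j % block_length == 0:
            hap[:, j] = fresh[:, j]
        else:
            hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
    return HaplotypePool(haplotypes=hap, block_starts=block_starts, freqs=freqs)


@dataclass
class GenotypeStudySpec:
    """Layout of the genotype-based benchmark.

    Two chromosomes; the causal SNPs are four well-separated positions on
    chromosome 1 and four positions spaced 3 apart on chromosome 2
    (1-based within-chromosome indices).  Causal SNPs are removed from
    the released data; the relevant set is their 3-adjacent neighbours on
    each side, deduplicated.
    """

    chrom_lengths: tuple[int, ...] = (4000, 4000)
    causal: tuple[tuple[int, ...], ...] = (
        (400, 900, 1750, 3200),
        (3600, 3604, 3608, 3612),
    )
    relative_risk: float = 1.5
    beta0: float = -9.5425
    disease_rate: float = 0.03
    n_cases: int = 1000
    n_controls: int = 1000

    def causal_flat(self) -> np.ndarray:
        """0-based causal indices in the concatenated SNP coordinate."""
        offs = np.concatenate(([0], np.cumsum(self.chrom_lengths)[:-1]))
        return np.concatenate(
            [np.asarray(c, dtype=int) - 1 + o for c, o in zip(self.causal, offs)]
        )

    def relevant_flat(self) -> np.ndarray:
        """0-based relevant indices (causal +-1..3, minus causal, dedup)."""
        causal = self.causal_flat()
        total = sum(self.chrom_lengths)
        rel = set()
        for c in causal:
            for d in range(1, 4):
                for j in (c - d, c + d):
                    if 0 <= j < total:
                        rel.add(int(j))
        return np.array(sorted(rel - set(causal.tolist())), dtype=int)


def calibrate_beta0(
    pool: HaplotypePool,
    spec: GenotypeStudySpec,
    n_mc: int = 20000,
    seed: int = 0,
) -> float:
    """Solve the logistic intercept for the target disease rate.

    The printed intercept targets the rate under a particular reference
    pool; prevalence depends on the genotype distribution, so for a
    synthetic pool the intercept is re-solved by Monte Carlo + brentq.
    """
    rng = np.random.default_rng(seed)
    causal = spec.causal_flat()
    beta = np.log(spec.relative_risk)
    hap_idx = rng.integers(0, pool.n_haplotypes, size=(n_mc, 2))
    x = (
        pool.haplotypes[hap_idx[:, 0]][:, causal]
        + pool.haplotypes[hap_idx[:, 1]][:, causal]
    ).astype(float)
    score = beta * x.sum(axis=1)

    def rate(b0):
        return special.expit(b0 + score).mean() - spec.disease_rate

    return float(optimize.brentq(rate, -30.0, 10.0))


def _sample_case_control(
    pool: HaplotypePool,
    spec: GenotypeStudySpec,
    beta0: float,
    rng: np.random.Generator,
    max_draws: int = 10_000_000,
    batch: int = 20000,
) -> GenotypeMatrix:
    """Rejection-sample subjects until the case/control quotas are met."""
    causal = spec.causal_flat()
    beta = np.log(spec.relative_risk)
    cases, controls = [], []
    drawn = 0
    while (len(cases) < spec.n_cases or len(controls) < spec.n_controls):
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control quotas unreachable within {max_draws} draws"
            )
        n = min(batch, max_draws - drawn)
        drawn += n
        hap_idx = rng.integers(0, pool.n_haplotypes, size=(n, 2))
        x = pool.haplotypes[hap_idx[:, 0]] + pool.haplotypes[hap_idx[:, 1]]
        p = special.expit(beta0 + beta * x[:, causal].sum(axis=1))
        y = rng.uniform(size=n) < p
        need_cases = spec.n_cases - len(cases)
        need_controls = spec.n_controls - len(controls)
        if need_cases:
            cases.extend(x[y][:need_cases])
        if need_controls:
            controls.extend(x[~y][:need_controls])
    codes = np.array(cases + controls, dtype=float)
    status = np.array([1] * spec.n_cases + [0] * spec.n_controls)
    return GenotypeMatrix(codes=codes, status=status)


def run_genotype_study(
    pool: HaplotypePool,
    spec: GenotypeStudySpec | None = None,
    reps: int = 1,
    seed: int = 0,
    config: AnalysisConfig | None = None,
    M_grid: np.ndarray | None = None,
    recalibrate_beta0: bool = True,
    max_draws: int = 10_000_000,
) -> dict:
    """Top-M sensitivity of RSPLIS vs PLIS on case-control genotype data.

    Per replication: draw genotypes from the pool, assign disease status
    by the logistic model, sample to the case/control quotas, drop the
    causal SNPs, run allele tests -> z -> both pipelines, and record the
    fraction of the relevant SNPs among the top M by pooled LIS rank.
    """
    spec = spec or GenotypeStudySpec()
    config = config or AnalysisConfig(K_max=5, m_max=6, h=2)
    if pool.n_snps != sum(spec.chrom_lengths):
        raise ValueError("pool size must match the study's total SNP count")
    beta0 = (
        calibrate_beta0(pool, spec, seed=seed) if recalibrate_beta0 else spec.beta0
    )
    causal = spec.causal_flat()
    relevant = spec.relevant_flat()
    keep = np.setdiff1d(np.arange(pool.n_snps), causal)
    rel_kept = np.searchsorted(keep, relevant)  # post-removal coordinates
    if M_grid is None:
        M_grid = np.array([25, 50, 100, 200, 400])
    offs = np.concatenate(([0], np.cumsum(spec.chrom_lengths)))
    ss = np.random.SeedSequence(entropy=int(seed))
    curves = {"rsplis": [], "plis": []}
    for rep in range(reps):
        s_sim, s_rs, s_pl = ss.spawn(1)[0].generate_state(3)
        rng = np.random.default_rng(int(s_sim))
        g = _sample_case_control(pool, spec, beta0, rng, max_draws=max_draws)
        g = GenotypeMatrix(codes=g.codes[:, keep], status=g.status)
        _, z = genotypes_to_z(g)
        chroms = []
        kept_pos = keep  # original coordinate of each kept column
        for c in range(len(spec.chrom_lengths)):
            in_c = (kept_pos >= offs[c]) & (kept_pos < offs[c + 1])
            chroms.append(ZSeries(chrom=f"chr{c + 1}", z=z[in_c]))
        results = {
            "rsplis": rsplis_run(chroms, config.alpha, config, seed=int(s_rs)),
            "plis": plis_run(chroms, config.alpha, config, seed=int(s_pl)),
        }
        # global post-removal index of each record row
        chrom_offsets = {}
        pos = 0
        for c in range(len(spec.chrom_lengths)):
            chrom_offsets[f"chr{c + 1}"] = pos
            pos += int(((kept_pos >= offs[c]) & (kept_pos < offs[c + 1])).sum())
        rel_set = set(rel_kept.tolist())
        for meth, res in results.items():
            df = res.records
            gidx = df["index"].to_numpy() + np.array(
                [chrom_offsets[ch] for ch in df["chrom"]]
            )
            order = np.argsort(df["rank"].to_numpy())
            ranked = gidx[order]
            sens = [
                len(set(ranked[:M].tolist()) & rel_set) / len(rel_set)
                for M in M_grid
            ]
            curves[meth].append(sens)
    return {
        "M": np.asarray(M_grid),
        "beta0": beta0,
        "n_relevant": len(relevant),
        "rsplis": np.asarray(curves["rsplis"]).mean(axis=0),
        "plis": np.asarray(curves["plis"]).mean(axis=0),
        "reps": reps,
    }
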