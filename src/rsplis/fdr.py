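"""Pooled LIS FDR control across regions and chromosomes.

RSPLIS in three steps: (1) partition each chromosome into homogeneous
regions by ACP and compute, per region, the plug-in LIS statistic
LIS_l = P(theta_l = 0 | region z-values) under the fitted region HMM;
(2) pool and rank the LIS values from all regions of all chromosomes;
(3) reject the largest prefix of the ranking whose running mean stays at
or below the nominal level alpha:

    l = max{ i : (1/i) * sum_{j<=i} LIS_(j) <= alpha }.

The running mean of the smallest LIS values estimates the false
discovery proportion of the corresponding rejection set, so the rule
controls the global FDR at alpha.  PLIS is the single-HMM-per-chromosome
baseline: same pooling rule, no partitioning, m chosen per chromosome by
BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .hmm_core import ZSeries, em_fit, lis
from .model_select import (
    ChromosomeModel,
    acp_select,
    bic_lambda,
    candidate_grid,
    model_dimension,
)


@dataclass
class RegionTrack:
    """LIS values of one region with provenance (chromosome, region, index)."""

    chrom: str
    region: int
    indices: np.ndarray       # 0-based SNP positions within the chromosome
    lis: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.lis = np.asarray(self.lis, dtype=float)
        if self.indices.shape != self.lis.shape:
            raise ValueError("indices and lis must align")
        if np.any(self.lis < 0) or np.any(self.lis > 1):
            raise ValueError("LIS values must lie in [0, 1]")


@dataclass
class DecisionResult:
    """Global ranking and rejection decisions at level alpha.

    ``records`` has one row per SNP with columns chrom, region, index,
    lis, rank (1-based global rank after pooling) and rejected; the
    rejected set is always the prefix rank <= l_cut.
    """

    alpha: float
    l_cut: int
    records: pd.DataFrame
    models: dict = field(default_factory=dict, repr=False)

    @property
    def n_rejected(self) -> int:
        return self.l_cut


def pool_and_decide(tracks: list[RegionTrack], alpha: float) -> DecisionResult:
    """Steps 2-3: pool, rank, and threshold the running mean at alpha.

    Sorting is ascending in LIS with a stable (chrom, index) tie-break so
    results are deterministic.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not tracks:
        return DecisionResult(
            alpha=alpha, l_cut=0,
            records=pd.DataFrame(
                columns=["chrom", "region", "index", "lis", "rank", "rejected"]
            ),
        )
    df = pd.concat(
        [
            pd.DataFrame(
                {"chrom": t.chrom, "region": t.region, "index": t.indices, "lis": t.lis}
            )
            for t in tracks
        ],
        ignore_index=True,
    )
    df = df.sort_values(["lis", "chrom", "index"], kind="stable").reset_index(drop=True)
    running_mean = df["lis"].cumsum().to_numpy() / np.arange(1, len(df) + 1)
    below = np.flatnonzero(running_mean <= alpha)
    l_cut = int(below[-1] + 1) if len(below) else 0
    df["rank"] = np.arange(1, len(df) + 1)
    df["rejected"] = df["rank"] <= l_cut
    return DecisionResult(alpha=alpha, l_cut=l_cut, records=df)


def _tracks_from_model(z: ZSeries, model: ChromosomeModel) -> list[RegionTrack]:
    tracks = []
    for r, (start, stop) in enumerate(model.region_bounds(len(z))):
        tracks.append(
            RegionTrack(
                chrom=z.chrom, region=r,
                indices=np.arange(start, stop),
                lis=lis(z.slice(start, stop), model.regions[r]),
            )
        )
    return tracks


def rsplis_run(
    chromosomes: list[ZSeries],
    alpha: float = 0.1,
    config: AnalysisConfig | None = None,
    seed=0,
    mode: str = "acp",
    candidates: dict | None = None,
) -> DecisionResult:
    """The full region-specific pipeline over several chromosomes.

    Per chromosome: ACP partition (or BICP with ``mode='bicp'``), region
    refits, per-region LIS; then one pooled decision over everything.
    ``candidates`` may map chromosome id to a user CandidateSet; the
    default is the uniform grid with spacing ``config.L_min``.
    """
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(entropy=int(seed))
    seeds = ss.generate_state(len(chromosomes))
    tracks, models = [], {}
    for z, s in zip(chromosomes, seeds):
        cand = (candidates or {}).get(z.chrom) or candidate_grid(len(z), config.L_min)
        model = acp_select(z, cand, config, mode=mode, seed=int(s))
        models[z.chrom] = model
        tracks.extend(_tracks_from_model(z, model))
    result = pool_and_decide(tracks, alpha)
    result.models = models
    return result


def plis_run(
    chromosomes: list[ZSeries],
    alpha: float = 0.1,
    config: AnalysisConfig | None = None,
    seed=0,
) -> DecisionResult:
    """PLIS baseline: one HMM per whole chromosome, m chosen by BIC."""
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(entropy=int(seed))
    seeds = ss.generate_state(len(chromosomes) * config.m_max)
    tracks, models = [], {}
    for ci, z in enumerate(chromosomes):
        lam = bic_lambda(len(z))
        best = None
        for m in range(1, config.m_max + 1):
            model, ll, _ = em_fit(
                z, m,
                tol=config.em_tol, max_iter=config.em_max_iter,
                n_restarts=config.refit_restarts,
                seed=int(seeds[ci * config.m_max + m - 1]),
                sigma_floor=config.sigma_floor,
            )
            bic = -ll + lam * model_dimension(m, 0)
            if best is None or bic < best[0]:
                best = (bic, m, model)
        _, m, model = best
        models[z.chrom] = model
        tracks.append(
            RegionTrack(
                chrom=z.chrom, region=0,
                indices=np.arange(len(z)), lis=lis(z, model),
            )
        )
    result = pool_and_decide(tracks, alpha)
    result.models = models
    return result


def evaluate_decisions(
    result: DecisionResult, truth: dict[str, np.ndarray]
) -> tuple[float, float, float]:
    """(FDP, FNP, sensitivity) of a decision against simulation truth.

    ``truth`` maps chromosome id to the 0/1 hidden-state vector; rows of
    the result are matched by (chrom, index).  FDP = false rejections /
    rejections, FNP = false acceptances / acceptances, sensitivity =
    true rejections / non-nulls (each denominator floored at 1).
    """
    df = result.records
    theta = np.empty(len(df), dtype=int)
    for chrom, sub in df.groupby("chrom"):
        t = np.asarray(truth[chrom])
        idx = sub["index"].to_numpy()
        if idx.max(initial=-1) >= len(t):
            raise ValueError(f"truth for {chrom} shorter than the decision records")
        theta[sub.index.to_numpy()] = t[idx]
    rej = df["rejected"].to_numpy()
    n_rej = int(rej.sum())
    n_acc = len(df) - n_rej
    false_rej = int((rej & (theta == 0)).sum())
    false_acc = int((~rej & (theta == 1)).sum())
    n_nonnull = int((theta == 1).sum())
    fdp = false_rej / max(1, n_rej)
    fnp = false_acc / max(1, n_acc)
    sensitivity = (n_nonnull - false_acc) / max(1, n_nonnull)
    return fdp, fnp, sensitivity
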