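"""Analysis configuration shared across the pipeline."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass


@dataclass
class AnalysisConfig:
    """Tuning knobs for ACP selection, EM fitting and FDR control.

    Defaults follow the method's recommended practice: candidate blocks
    of at least ``L_min = 300`` SNPs, a lambda grid of ``T = 50`` points,
    a sliding window ``h = 2`` (values above 10 degrade the calibration
    and trigger a warning), ``m_max = 5`` mixture components, and nominal
    FDR level ``alpha = 0.1``.
    """

    alpha: float = 0.1
    K_max: int = 8
    m_max: int = 5
    h: int = 2
    T: int = 50
    L_min: int = 300
    lambda_factor: float = 2.0
    mode: str = "rsplis"

    # EM budgets: segment fits inside the partition search use a lighter
    # budget than the final per-region refits.
    em_tol: float = 1e-6
    em_max_iter: int = 500
    segment_em_tol: float = 1e-6
    segment_em_max_iter: int = 500
    segment_restarts: int = 2
    refit_restarts: int = 3
    sigma_floor: float = 0.05
    min_segment_length: int = 0

    p_floor: float = 1e-15
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.K_max < 0 or self.m_max < 1:
            raise ValueError("K_max must be >= 0 and m_max >= 1")
        if self.T < 2 or not (1 <= self.h < self.T):
            raise ValueError("need T >= 2 and 1 <= h < T")
        if self.h > 10:
            warnings.warn(
                "window h > 10 is not recommended for the dimension jump",
                stacklevel=2,
            )
        if self.L_min < 1 or self.lambda_factor <= 0:
            raise ValueError("L_min must be >= 1 and lambda_factor > 0")
        if self.mode not in ("rsplis", "plis", "acp", "bicp"):
            raise ValueError("mode must be one of rsplis, plis, acp, bicp")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
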