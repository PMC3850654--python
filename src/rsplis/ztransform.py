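"""Case-control genotypes to per-SNP p-values and z-values.

Each SNP gets a 1-df Pearson chi-square allele test (each genotype
contributes two alleles: ``dose`` copies of the minor allele and
``2 - dose`` of the major), and the p-value is mapped to a z-value by the
upper-tail transform z = Phi^{-1}(1 - p), so that null SNPs have
standard-normal z-values and associated SNPs shift to positive z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

P_FLOOR_DEFAULT = 1e-15


@dataclass
class GenotypeMatrix:
    """Allele-dose matrix (subjects x SNPs, codes 0/1/2, NaN = missing)."""

    codes: np.ndarray
    status: np.ndarray
    snp_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-dimensional (subjects x snps)")
        if len(self.status) != self.codes.shape[0]:
            raise ValueError("status length must equal the number of subjects")
        if not np.all(np.isin(self.status, (0, 1))):
            raise ValueError("status must be binary (1=case, 0=control)")
        if self.status.sum() == 0 or self.status.sum() == len(self.status):
            raise ValueError("need at least one case and one control")
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")
        if self.snp_ids is not None and len(self.snp_ids) != self.codes.shape[1]:
            raise ValueError("snp_ids length must equal the number of SNPs")

    @property
    def n_subjects(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]


def _allele_table(g: GenotypeMatrix, snp_index: int) -> np.ndarray | None:
    """2x2 allele-count table [[case minor, case major], [control ...]]."""
    dose = g.codes[:, snp_index]
    keep = ~np.isnan(dose)
    table = np.empty((2, 2))
    for row, grp in enumerate((1, 0)):  # cases first
        sel = keep & (g.status == grp)
        if not sel.any():
            return None
        minor = dose[sel].sum()
        table[row] = (minor, 2 * sel.sum() - minor)
    return table


def allele_chisq_test(g: GenotypeMatrix, snp_index: int) -> float:
    """Pearson chi-square allele-test p-value (1 df, no continuity correction).

    Missing genotypes are dropped for the SNP.  Degenerate tables (a SNP
    with all genotypes missing in a status group, or monomorphic in both
    groups) are flagged with a warning and return p = 1.
    """
    table = _allele_table(g, snp_index)
    if table is None:
        logger.warning("SNP %d: no non-missing genotypes in a status group", snp_index)
        return 1.0
    if np.any(table.sum(axis=0) == 0):
        logger.warning("SNP %d: monomorphic in both groups; p set to 1", snp_index)
        return 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def allele_tests(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP allele-test p-values for the whole matrix."""
    return np.array([allele_chisq_test(g, j) for j in range(g.n_snps)])


def p_to_z(p: np.ndarray, p_floor: float = P_FLOOR_DEFAULT) -> np.ndarray:
    """Upper-tail transform z = Phi^{-1}(1 - p).

    Null p-values (uniform on (0, 1)) map to standard-normal z.  Values
    numerically at the boundaries are clipped into [p_floor, 1 - p_floor]
    so the output stays finite.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.norm.isf(np.clip(p, p_floor, 1.0 - p_floor))


def genotypes_to_z(
    g: GenotypeMatrix, p_floor: float = P_FLOOR_DEFAULT
) -> tuple[np.ndarray, np.ndarray]:
    """Allele tests then the p-to-z transform; returns ``(p, z)``."""
    p = allele_tests(g)
    return p, p_to_z(p, p_floor=p_floor)
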