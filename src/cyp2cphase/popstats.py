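"""Population statistics: allele frequencies, Hardy-Weinberg
goodness-of-fit, and chi-square comparisons of haplotype and phenotype
distributions between cohorts.

Conventions: haplotype comparisons count chromosomes (2n), phenotype
comparisons count individuals; no continuity correction is applied
anywhere (switchable per call); significance level defaults to 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic SNP."""

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_alt_hom) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total == 0:
            raise ValueError("genotype counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    alpha: float = ALPHA
    valid: bool = True
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.valid and self.p_value < self.alpha


def allele_frequency(counts: GenotypeCounts) -> float:
    """Variant (ALT) allele frequency by genotype counting."""
    return (counts.n_het + 2 * counts.n_alt_hom) / (2 * counts.total)


def hwe_test(counts: GenotypeCounts, alpha: float = ALPHA) -> TestResult:
    """Goodness-of-fit chi-square against Hardy-Weinberg proportions.

    Expected counts are p^2 n, 2pq n, q^2 n at the counted allele
    frequency; df = 1.  A monomorphic locus trivially fits HWE and
    returns statistic 0, p 1.
    """
    n = counts.total
    q = allele_frequency(counts)
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        return TestResult(0.0, 1, 1.0, alpha)
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([counts.n_ref_hom, counts.n_het, counts.n_alt_hom], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return TestResult(statistic, 1, float(stats.chi2.sf(statistic, 1)), alpha)


def compare_haplotype_freq(
    count_a: tuple[int, int],
    count_b: tuple[int, int],
    alpha: float = ALPHA,
    continuity_correction: bool = False,
) -> TestResult:
    """2x2 chi-square for one haplotype's chromosome counts in two cohorts.

    ``count_a`` and ``count_b`` are (haplotype count, total chromosomes
    2n).  The table is focal haplotype vs all others, cohort A vs B.
    """
    k_a, n_a = count_a
    k_b, n_b = count_b
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("haplotype count exceeds chromosome total")
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        return TestResult(
            float("nan"), 1, float("nan"), alpha, valid=False,
            note="zero margin: haplotype absent (or fixed) in both cohorts",
        )
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue), alpha)


def compare_phenotype_distributions(
    dist_a: Mapping[str, int],
    dist_b: Mapping[str, int],
    alpha: float = ALPHA,
    continuity_correction: bool = False,
) -> TestResult:
    """r x 2 contingency chi-square over phenotype counts (individuals).

    Phenotype categories with zero counts in both cohorts are dropped;
    at least two usable categories are required.
    """
    cats = sorted(set(dist_a) | set(dist_b))
    rows = [
        (dist_a.get(c, 0), dist_b.get(c, 0))
        for c in cats
        if dist_a.get(c, 0) + dist_b.get(c, 0) > 0
    ]
    if len(rows) < 2:
        raise ValueError("need at least 2 phenotype categories with nonzero totals")
    table = np.array(rows, dtype=float)
    if (table.sum(axis=0) == 0).any():
        raise ValueError("one cohort has no individuals")
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue), alpha)


def counts_from_frequency(freq: float, n_chromosomes: int) -> int:
    """Reconstruct a haplotype count from a printed frequency: round(f * 2n)."""
    return int(round(freq * n_chromosomes))


def genotype_counts_from_dosages(dosages: np.ndarray, snp_index: int) -> GenotypeCounts:
    """Genotype counts at one panel SNP from a dosage matrix (missing dropped)."""
    col = dosages[:, snp_index]
    col = col[col >= 0]
    return GenotypeCounts(
        int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
    )
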