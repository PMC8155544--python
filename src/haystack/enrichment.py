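"""Allele-level loss-of-function burden statistics.

A cohort's LoF-affected and unaffected allele counts are compared with a
reference population (gnomAD-like) in a 2x2 table using

* the exact conditional two-sided Fisher test, summing hypergeometric point
  probabilities (margins fixed) over all tables at most as likely as the
  observed one, with a 1e-7 relative tolerance guarding floating-point ties;
* the Woolf logit confidence interval for the odds ratio,
  exp(log OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)), with the Haldane-Anscombe
  +0.5 correction applied to every cell whenever any cell is zero.

Alleles are counted as 2 per individual (autosomal): a heterozygous carrier
contributes one affected allele, a homozygous carrier two.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .errors import DataError

logger = logging.getLogger(__name__)

#: relative tolerance for "at most as likely as observed" point-probability ties
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 allele counts: cohort (a affected, b unaffected) vs reference (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise DataError(f"contingency cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise DataError("contingency table is all-zero")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    p_two_sided: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    conf_level: float
    correction_applied: bool


def alleles_from_individuals(
    n_individuals: int, het_carriers: int, hom_carriers: int, ploidy: int = 2
) -> tuple[int, int]:
    """(affected, unaffected) allele counts from carrier counts."""
    if min(n_individuals, het_carriers, hom_carriers) < 0:
        raise DataError("carrier and individual counts must be non-negative")
    if het_carriers + hom_carriers > n_individuals:
        raise DataError("more carriers than individuals")
    affected = het_carriers + ploidy * hom_carriers
    return affected, ploidy * n_individuals - affected


_LOG_FACT = np.zeros(1)  # cached log-factorial table, grown on demand


def _log_factorials(n: int) -> np.ndarray:
    global _LOG_FACT
    if len(_LOG_FACT) <= n:
        _LOG_FACT = gammaln(np.arange(max(n + 1, 1024), dtype=float) + 1.0)
    return _LOG_FACT


def _log_hypergeom_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(X = k) for the 2x2 table's first cell, margins (r1, r2, c1)."""
    lf = _log_factorials(r1 + r2)

    def log_comb(n, j):
        return lf[n] - lf[j] - lf[n - j]

    return log_comb(r1, k) + log_comb(r2, c1 - k) - log_comb(r1 + r2, c1)


def fisher_two_sided(table: ContingencyTable) -> float:
    """Exact conditional two-sided p by minimum-likelihood summation.

    Degenerate margins (an empty row or column) return p = 1 by convention.
    """
    a, b, c, d = table.cells
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        logger.debug("degenerate margin in %s; p = 1 by convention", table)
        return 1.0
    k = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    logp = _log_hypergeom_pmf(k, r1, r2, c1)
    observed = logp[a - k[0]]
    included = logp <= observed + math.log1p(TIE_RTOL)
    return float(min(np.exp(logp[included]).sum(), 1.0))


def woolf_logit_interval(
    table: ContingencyTable, conf_level: float = 0.95
) -> tuple[float, float, float, bool]:
    """(odds ratio, ci_low, ci_high, correction_applied) by the Woolf method."""
    if not 0.0 < conf_level < 1.0:
        raise DataError(f"conf_level must lie in (0,1), got {conf_level}")
    cells = [float(x) for x in table.cells]
    corrected = any(x == 0 for x in cells)
    if corrected:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    odds_ratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + conf_level / 2)
    log_or = math.log(odds_ratio)
    return (
        odds_ratio,
        math.exp(log_or - z * se),
        math.exp(log_or + z * se),
        corrected,
    )


def lof_burden_test(
    cohort_individuals: int,
    cohort_het_carriers: int,
    cohort_hom_carriers: int,
    reference_individuals: int,
    reference_het_carriers: int,
    reference_hom_carriers: int,
    conf_level: float = 0.95,
    ploidy: int = 2,
    reference_allele_number: int | None = None,
) -> EnrichmentResult:
    """Full burden comparison: Fisher p plus Woolf interval in one result.

    ``reference_allele_number`` optionally overrides the 2N reference allele
    total (population databases can report fewer called alleles per site).
    """
    a, b = alleles_from_individuals(cohort_individuals, cohort_het_carriers, cohort_hom_carriers, ploidy)
    c, d = alleles_from_individuals(
        reference_individuals, reference_het_carriers, reference_hom_carriers, ploidy
    )
    if reference_allele_number is not None:
        if reference_allele_number < c:
            raise DataError("reference allele number smaller than affected alleles")
        d = reference_allele_number - c
    table = ContingencyTable(a, b, c, d)
    odds_ratio, lo, hi, corrected = woolf_logit_interval(table, conf_level)
    return EnrichmentResult(
        table=table,
        p_two_sided=fisher_two_sided(table),
        odds_ratio=odds_ratio,
        ci_low=lo,
        ci_high=hi,
        conf_level=conf_level,
        correction_applied=corrected,
    )
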