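"""Minimizer-proportion significance test for taxon presence.

A taxonomic classifier reports, per taxon, the number of distinct
database minimizers observed (``m`` of ``M`` available) and the reads
assigned (``n`` of ``N`` evaluated).  Under the null, each of the
``M`` minimizers is discovered independently with probability
``p0 = n/N`` — a taxon's minimizer discovery chance proportional to
its share of the sample's reads — so ``m ~ Binomial(M, p0)``.  The
upper-tail probability P(X >= m) screens for enrichment (presence);
the normal approximation with continuity correction is used when
``M*p0*(1-p0)`` is large enough, the exact binomial tail otherwise.
p-values are Benjamini-Hochberg adjusted across the taxa of one
sample, and taxa with adjusted p below alpha are flagged significant.

The null success probability is injectable (``p0`` argument) for
alternative null models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import TaxonMinimizerRecord

log = logging.getLogger(__name__)


@dataclass
class TaxonTestConfig:
    """Settings for the minimizer-proportion test.

    ``approx_validity_min`` is the floor on ``M*p0*(1-p0)`` below which
    the exact binomial tail replaces the normal approximation.  The
    default of 25 is the smallest round floor at which the
    continuity-corrected normal tail agrees with the exact binomial
    tail within 0.01 absolute over a swept (M, p0) grid; below it the
    exact tail is cheap anyway.
    """

    alpha: float = 0.05
    approx_validity_min: float = 25.0
    continuity_correction: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def taxon_pvalue(
    record: TaxonMinimizerRecord,
    cfg: TaxonTestConfig | None = None,
    p0: float | None = None,
) -> float:
    """One-sided upper-tail p-value P(X >= m) under X ~ Binomial(M, p0)."""
    cfg = cfg or TaxonTestConfig()
    if p0 is None:
        p0 = record.n / record.N
    if p0 >= 1.0:
        raise ValueError(f"taxon {record.taxon_id}: degenerate null p0 >= 1")
    if p0 == 0.0:
        if record.m > 0:
            warnings.warn(
                f"taxon {record.taxon_id}: m > 0 with null p0 = 0; returning p = 0"
            )
            return 0.0
        return 1.0
    M, m = record.M, record.m
    var = M * p0 * (1.0 - p0)
    if var >= cfg.approx_validity_min:
        cc = 0.5 if cfg.continuity_correction else 0.0
        z = (m - M * p0 - cc) / np.sqrt(var)
        p = float(stats.norm.sf(z))
    else:
        p = float(stats.binom.sf(m - 1, M, p0))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def flag_significant(
    records: Sequence[TaxonMinimizerRecord],
    cfg: TaxonTestConfig | None = None,
) -> list[TaxonMinimizerRecord]:
    """Compute p per taxon, BH-adjust within this report (one sample's
    taxa form the correction family) and flag q < alpha (strict)."""
    cfg = cfg or TaxonTestConfig()
    if not records:
        return []
    p_values = [taxon_pvalue(r, cfg) for r in records]
    q_values = bh_adjust(p_values)
    return [
        replace(r, p_value=p, q_value=q, significant=bool(q < cfg.alpha))
        for r, p, q in zip(records, p_values, q_values)
    ]
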