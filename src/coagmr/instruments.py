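"""Instrument selection, strength quantification and study power.

Candidate SNPs pass a genome-wide-significance screen (default P < 5e-7,
strict), are pruned to LD independence by greedy p-value-ordered clumping
(default r² > 0.1 within ±10 Mb discards), and instruments absent from the
outcome data may be rescued through proxy SNPs (r² > 0.8).  Strength is
summarised per SNP as F = z² with r² = z²/(z² + n − 2), and for the set as
the multi-instrument F = R²(n − k − 1)/(k(1 − R²)); both conventions are
standard and both are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import LDMatrix, ProxyRecord, SummaryStatRecord
from .gwas_io import _chrom_sort_key  # shared ordering for deterministic ties

logger = logging.getLogger("coagmr")

P_SELECT_DEFAULT = 5e-7
CLUMP_R2_DEFAULT = 0.1
CLUMP_WINDOW_BP_DEFAULT = 10_000_000
PROXY_R2_DEFAULT = 0.8


@dataclass
class InstrumentSet:
    """LD-independent instruments for one exposure, with per-SNP provenance.

    ``provenance`` maps every candidate SNP id to its fate: "kept",
    "clumped_out_by:<index snp>", "not_significant", or later
    "proxied_by:<snp>" / "dropped:<reason>" once harmonization runs.
    """

    exposure: str
    records: list[SummaryStatRecord]
    f_per_snp: dict[str, float] = field(default_factory=dict)
    f_overall: float = float("nan")
    r2_explained: float = float("nan")
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.records)


@dataclass
class PowerEstimate:
    """Analytic power of an MR test against a binary outcome."""

    power: float
    n: int
    r2: float
    case_ratio: float
    beta_alt: float
    alpha: float


def select_significant(
    records: list[SummaryStatRecord],
    p_threshold: float = P_SELECT_DEFAULT,
) -> list[SummaryStatRecord]:
    """Keep records with pval strictly below the threshold, order preserved."""
    kept = [r for r in records if r.pval < p_threshold]
    if not kept:
        logger.warning("no SNP passes P < %g (%d candidates)",
                       p_threshold, len(records))
    return kept


def clump(
    records: list[SummaryStatRecord],
    ld: LDMatrix,
    r2_max: float = CLUMP_R2_DEFAULT,
    window_bp: int = CLUMP_WINDOW_BP_DEFAULT,
    provenance: dict[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping: repeatedly index on the lowest-p remaining SNP.

    A remaining SNP is discarded when it sits on the index SNP's chromosome
    within ±window_bp and its r² with the index exceeds ``r2_max`` (strict).
    SNPs absent from the LD matrix are treated as independent and logged.
    Ties on p break by (chromosome, position, id).  Output is sorted by p.
    """
    order = sorted(records,
                   key=lambda r: (r.pval, _chrom_sort_key(r.chrom), r.pos, r.snp_id))
    for r in order:
        if r.snp_id not in ld:
            logger.warning("clump: %s absent from LD matrix, treated as independent",
                           r.snp_id)
    kept: list[SummaryStatRecord] = []
    remaining = list(order)
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        if provenance is not None:
            provenance[index.snp_id] = "kept"
        survivors = []
        for r in remaining:
            discard = (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_bp
                and r.snp_id in ld and index.snp_id in ld
                and ld.r2_between(r.snp_id, index.snp_id) > r2_max
            )
            if discard:
                if provenance is not None:
                    provenance[r.snp_id] = f"clumped_out_by:{index.snp_id}"
            else:
                survivors.append(r)
        remaining = survivors
    return kept


def find_proxy(
    missing_snp: str,
    proxy_table: list[ProxyRecord],
    available_in_outcome: set[str],
    r2_min: float = PROXY_R2_DEFAULT,
) -> ProxyRecord | None:
    """Best proxy for a SNP absent from the outcome data, or None.

    Eligible proxies have r² strictly above ``r2_min`` and exist in the
    outcome; the maximal-r² one wins, ties broken by smaller distance then
    lexicographic id.
    """
    candidates = [p for p in proxy_table
                  if p.target_snp == missing_snp
                  and p.r2 > r2_min
                  and p.proxy_snp in available_in_outcome]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (-p.r2, p.distance, p.proxy_snp))


def instrument_strength(
    records: list[SummaryStatRecord],
    n: int | None = None,
) -> tuple[dict[str, float], float, float]:
    """Per-SNP F (= z²), overall multi-instrument F, and total r² explained.

    r²_j = z_j²/(z_j² + n − 2); R² = Σ r²_j capped just below 1;
    F_overall = R²(n − k − 1)/(k(1 − R²)).
    """
    if not records:
        raise ValueError("empty instrument set")
    if n is None:
        ns = {r.n for r in records if r.n is not None}
        if not ns:
            raise ValueError("exposure sample size unknown; cannot compute F")
        n = max(ns)
    k = len(records)
    z2 = np.array([(r.beta / r.se) ** 2 for r in records])
    r2 = z2 / (z2 + n - 2)
    r2_explained = min(float(r2.sum()), 1.0 - 1e-12)
    f_per_snp = {r.snp_id: float(z) for r, z in zip(records, z2)}
    f_overall = r2_explained * (n - k - 1) / (k * (1.0 - r2_explained))
    return f_per_snp, float(f_overall), r2_explained


def build_instrument_set(
    exposure: str,
    records: list[SummaryStatRecord],
    ld: LDMatrix,
    p_threshold: float = P_SELECT_DEFAULT,
    r2_max: float = CLUMP_R2_DEFAULT,
    window_bp: int = CLUMP_WINDOW_BP_DEFAULT,
    n: int | None = None,
) -> InstrumentSet:
    """Significance screen + clumping + strength, with full provenance."""
    provenance: dict[str, str] = {}
    significant = select_significant(records, p_threshold)
    sig_ids = {r.snp_id for r in significant}
    for r in records:
        if r.snp_id not in sig_ids:
            provenance[r.snp_id] = "not_significant"
    independent = clump(significant, ld, r2_max, window_bp, provenance)
    iset = InstrumentSet(exposure=exposure, records=independent,
                         provenance=provenance)
    if independent:
        iset.f_per_snp, iset.f_overall, iset.r2_explained = instrument_strength(
            independent, n=n)
    return iset


def mr_power(
    n: int,
    r2: float,
    case_ratio: float,
    beta_alt: float,
    alpha: float = 0.05,
) -> PowerEstimate:
    """Analytic power of a two-sided MR test against a binary outcome.

    With case fraction phi = ratio/(1+ratio), the IVW z statistic under the
    alternative log-OR ``beta_alt`` has mean |beta_alt|·sqrt(n·r2·phi(1−phi)),
    giving power = Phi(that − z_{1−alpha/2}).  Returns alpha/2 at
    beta_alt = 0.
    """
    if n <= 0 or not (0.0 < r2 < 1.0) or case_ratio <= 0 or not (0 < alpha < 1):
        raise ValueError(
            f"invalid power inputs: n={n}, r2={r2}, case_ratio={case_ratio}, "
            f"alpha={alpha}")
    phi = case_ratio / (1.0 + case_ratio)
    ncp = abs(beta_alt) * np.sqrt(n * r2 * phi * (1.0 - phi))
    power = float(stats.norm.cdf(ncp - stats.norm.ppf(1.0 - alpha / 2.0)))
    return PowerEstimate(power=power, n=n, r2=r2, case_ratio=case_ratio,
                         beta_alt=beta_alt, alpha=alpha)
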