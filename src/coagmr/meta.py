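"""Fixed-effect, standard-error-weighted meta-analysis of per-SNP statistics.

Combines two (or more) cohorts' outcome summary statistics SNP by SNP before
MR, in the manner of METAL's STDERR scheme: weights 1/se², combined beta the
weighted mean, combined variance the reciprocal summed weight.  Cohorts are
first placed on a consensus effect allele using the same swap / strand-flip /
palindrome logic as exposure–outcome harmonization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gwas_io import SummaryStatRecord
from .harmonize import Dropped, harmonize_pair, EAF_TOLERANCE_DEFAULT
from .pvalues import two_sided_p

logger = logging.getLogger("coagmr")


@dataclass
class MetaRecord:
    """One SNP's inverse-variance-combined association across cohorts."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_meta: float
    se_meta: float
    pval_meta: float
    n_total: int | None
    contributions: list[str] = field(default_factory=list)


def align_cohorts(
    records_a: list[SummaryStatRecord],
    records_b: list[SummaryStatRecord],
    eaf_tolerance: float = EAF_TOLERANCE_DEFAULT,
) -> tuple[list[tuple[SummaryStatRecord, SummaryStatRecord]], list[Dropped]]:
    """Pair overlapping SNPs with cohort b re-expressed on cohort a's alleles.

    Unresolvable SNPs (non-concordant alleles, ambiguous palindromes) are
    dropped with reasons.  An empty overlap is fatal.
    """
    by_id_b = {r.snp_id: r for r in records_b}
    overlap = [r for r in records_a if r.snp_id in by_id_b]
    if not overlap:
        raise ValueError("cohorts share no SNPs; nothing to meta-analyze")
    pairs, drops = [], []
    for ra in overlap:
        res = harmonize_pair(ra, by_id_b[ra.snp_id], eaf_tolerance=eaf_tolerance)
        if isinstance(res, Dropped):
            drops.append(res)
            logger.info("meta alignment dropped %s (%s)", res.snp_id, res.reason)
            continue
        rb = by_id_b[ra.snp_id]
        rb_aligned = rb.copy(
            effect_allele=res.effect_allele, other_allele=res.other_allele,
            beta=res.beta_out, eaf=res.eaf_out)
        pairs.append((ra, rb_aligned))
    return pairs, drops


def meta_fixed(
    pairs: list[tuple[SummaryStatRecord, ...]],
) -> list[MetaRecord]:
    """Inverse-variance fixed-effect combination of aligned per-SNP records."""
    out = []
    for group in pairs:
        betas = np.array([r.beta for r in group])
        ses = np.array([r.se for r in group])
        w = 1.0 / ses**2
        beta = float(np.sum(w * betas) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        ns = [r.n for r in group]
        lead = group[0]
        out.append(MetaRecord(
            snp_id=lead.snp_id,
            effect_allele=lead.effect_allele, other_allele=lead.other_allele,
            beta_meta=beta, se_meta=se, pval_meta=two_sided_p(beta / se),
            n_total=None if any(n is None for n in ns) else int(sum(ns)),
            contributions=[f"beta={r.beta:.6g},se={r.se:.6g}" for r in group]))
    return out


def meta_sumstats(
    records_a: list[SummaryStatRecord],
    records_b: list[SummaryStatRecord],
    eaf_tolerance: float = EAF_TOLERANCE_DEFAULT,
) -> tuple[list[SummaryStatRecord], list[Dropped]]:
    """Meta-analyze two cohorts into MR-ready summary-statistic records.

    Positions/chromosomes and case/control counts come from cohort a's
    records (counts summed where both cohorts report them), so the output
    slots directly into the harmonization and MR stages.
    """
    pairs, drops = align_cohorts(records_a, records_b, eaf_tolerance)
    meta = meta_fixed(pairs)
    by_id_a = {r.snp_id: r for r in records_a}
    by_id_b = {r.snp_id: r for r in records_b}
    out = []
    for m in meta:
        ra, rb = by_id_a[m.snp_id], by_id_b[m.snp_id]

        def _sum(x, y):
            return None if x is None or y is None else x + y

        out.append(SummaryStatRecord(
            snp_id=m.snp_id, chrom=ra.chrom, pos=ra.pos,
            effect_allele=m.effect_allele, other_allele=m.other_allele,
            beta=m.beta_meta, se=m.se_meta, pval=m.pval_meta,
            eaf=ra.eaf, n=m.n_total,
            n_case=_sum(ra.n_case, rb.n_case),
            n_control=_sum(ra.n_control, rb.n_control)))
    return out, drops
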