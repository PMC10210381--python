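"""Place exposure and outcome effects on the same effect allele.

Non-palindromic SNPs are aligned by direct match, allele swap (beta sign
flips, eaf mirrors), strand complement, or both.  Palindromic SNPs (A/T or
G/C) cannot be resolved from alleles alone: orientation is inferred from
effect-allele frequencies when both sides sit clearly away from 0.5
(|eaf − 0.5| > tolerance, default 0.08), otherwise the SNP is dropped as
strand-ambiguous.  SNPs whose alleles admit no mapping are dropped as
non-concordant.  Drops are results, not errors, and are fully audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .gwas_io import ProxyRecord, SummaryStatRecord
from .instruments import InstrumentSet, find_proxy

logger = logging.getLogger("coagmr")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

EAF_TOLERANCE_DEFAULT = 0.08


def is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome effects of one SNP on a shared effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    action_taken: str          # as_is | swapped | strand_flipped | swapped_and_flipped
    palindromic: bool
    proxied_by: str | None = None


@dataclass
class Dropped:
    snp_id: str
    reason: str               # non_concordant | palindromic_ambiguous | ...


@dataclass
class HarmonizationAudit:
    """Bookkeeping for one harmonization run: kept + Σ dropped = input."""

    kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def record_drop(self, snp_id: str, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1
        self.log.append(f"{snp_id}\tdropped\t{reason}")

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())


def _eaf_unambiguous(eaf: float | None, tol: float) -> bool:
    return eaf is not None and abs(eaf - 0.5) > tol


def harmonize_pair(
    exp: SummaryStatRecord,
    out: SummaryStatRecord,
    eaf_tolerance: float = EAF_TOLERANCE_DEFAULT,
    ambiguity_check: str = "both",
) -> HarmonizedInstrument | Dropped:
    """Harmonize one exposure/outcome record pair onto the exposure's alleles.

    ``ambiguity_check`` selects which panel's frequency must sit clearly away
    from 0.5 for palindrome resolution ("both", "exposure" or "outcome");
    whichever frequencies are required must also be present, otherwise the
    palindrome is dropped.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    e2, o2 = out.effect_allele, out.other_allele

    if is_palindromic(ea, oa):
        if {e2, o2} != {ea, oa}:
            return Dropped(exp.snp_id, "non_concordant")
        # Nominal orientation by allele label; swap vs strand flip are
        # indistinguishable for palindromes, so labels fix only the sign
        # convention and frequencies decide the actual orientation.
        if e2 == ea:
            beta_out, eaf_out, action = out.beta, out.eaf, "as_is"
        else:
            beta_out = -out.beta
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
            action = "swapped"
        need_exp = ambiguity_check in ("both", "exposure")
        need_out = ambiguity_check in ("both", "outcome")
        if (need_exp and not _eaf_unambiguous(exp.eaf, eaf_tolerance)) or \
           (need_out and not _eaf_unambiguous(eaf_out, eaf_tolerance)) or \
           exp.eaf is None or eaf_out is None:
            return Dropped(exp.snp_id, "palindromic_ambiguous")
        if (exp.eaf < 0.5) != (eaf_out < 0.5):
            # Frequencies disagree across the 0.5 mirror: true orientation is
            # the strand-flipped one.
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            action = "strand_flipped" if action == "as_is" else "swapped_and_flipped"
        return HarmonizedInstrument(
            snp_id=exp.snp_id, effect_allele=ea, other_allele=oa,
            beta_exp=exp.beta, se_exp=exp.se,
            beta_out=beta_out, se_out=out.se,
            eaf_exp=exp.eaf, eaf_out=eaf_out,
            action_taken=action, palindromic=True)

    ce2, co2 = COMPLEMENT[e2], COMPLEMENT[o2]
    if (e2, o2) == (ea, oa):
        action, sign, mirror = "as_is", 1.0, False
    elif (e2, o2) == (oa, ea):
        action, sign, mirror = "swapped", -1.0, True
    elif (ce2, co2) == (ea, oa):
        action, sign, mirror = "strand_flipped", 1.0, False
    elif (ce2, co2) == (oa, ea):
        action, sign, mirror = "swapped_and_flipped", -1.0, True
    else:
        return Dropped(exp.snp_id, "non_concordant")
    eaf_out = out.eaf
    if mirror and eaf_out is not None:
        eaf_out = 1.0 - eaf_out
    return HarmonizedInstrument(
        snp_id=exp.snp_id, effect_allele=ea, other_allele=oa,
        beta_exp=exp.beta, se_exp=exp.se,
        beta_out=sign * out.beta, se_out=out.se,
        eaf_exp=exp.eaf, eaf_out=eaf_out,
        action_taken=action, palindromic=False)


def _translate_proxy_outcome(out: SummaryStatRecord, proxy: ProxyRecord,
                             ) -> SummaryStatRecord | None:
    """Re-express the proxy SNP's outcome record in the target SNP's alleles."""
    amap = proxy.allele_map
    ea, oa = out.effect_allele, out.other_allele
    if ea in amap and oa in amap:
        return out.copy(snp_id=proxy.target_snp,
                        effect_allele=amap[ea], other_allele=amap[oa])
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if cea in amap and coa in amap:
        return out.copy(snp_id=proxy.target_snp,
                        effect_allele=amap[cea], other_allele=amap[coa])
    return None


def harmonize_set(
    instrument_set: InstrumentSet,
    outcome_records: list[SummaryStatRecord],
    proxy_table: list[ProxyRecord] | None = None,
    eaf_tolerance: float = EAF_TOLERANCE_DEFAULT,
    proxy_r2_min: float = 0.8,
    ambiguity_check: str = "both",
) -> tuple[list[HarmonizedInstrument], HarmonizationAudit]:
    """Harmonize every instrument against the outcome, proxying missing SNPs.

    Instruments absent from the outcome are first routed through
    :func:`find_proxy`; those without a qualifying proxy are dropped as
    ``missing_in_outcome_no_proxy``.
    """
    by_id = {r.snp_id: r for r in outcome_records}
    audit = HarmonizationAudit()
    harmonized: list[HarmonizedInstrument] = []

    for exp in instrument_set.records:
        proxied_by = None
        out = by_id.get(exp.snp_id)
        if out is None:
            proxy = None
            if proxy_table:
                proxy = find_proxy(exp.snp_id, proxy_table, set(by_id),
                                   r2_min=proxy_r2_min)
            if proxy is None:
                audit.record_drop(exp.snp_id, "missing_in_outcome_no_proxy")
                instrument_set.provenance[exp.snp_id] = "dropped:no_proxy"
                continue
            out = _translate_proxy_outcome(by_id[proxy.proxy_snp], proxy)
            if out is None:
                audit.record_drop(exp.snp_id, "missing_in_outcome_no_proxy")
                instrument_set.provenance[exp.snp_id] = "dropped:proxy_allele_mismatch"
                continue
            proxied_by = proxy.proxy_snp
            audit.log.append(f"{exp.snp_id}\tproxied_by\t{proxy.proxy_snp}")
            instrument_set.provenance[exp.snp_id] = f"proxied_by:{proxy.proxy_snp}"
        result = harmonize_pair(exp, out, eaf_tolerance=eaf_tolerance,
                                ambiguity_check=ambiguity_check)
        if isinstance(result, Dropped):
            audit.record_drop(result.snp_id, result.reason)
            instrument_set.provenance[exp.snp_id] = f"dropped:{result.reason}"
        else:
            result.proxied_by = proxied_by
            harmonized.append(result)
            audit.kept += 1
            audit.log.append(f"{exp.snp_id}\tkept\t{result.action_taken}")

    if not harmonized:
        logger.warning("harmonization for %s left zero SNPs; MR will refuse",
                       instrument_set.exposure)
    return harmonized, audit
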