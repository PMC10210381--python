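import numpy as np
import pytest

from coagmr.gwas_io import SummaryStatRecord
from coagmr.harmonize import HarmonizedInstrument


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                beta=0.1, se=0.02, pval=None, eaf=0.3, n=20000,
                n_case=None, n_control=None) -> SummaryStatRecord:
    if pval is None:
        from scipy import stats
        pval = float(2 * stats.norm.sf(abs(beta) / se))
    return SummaryStatRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                             effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, pval=pval, eaf=eaf, n=n,
                             n_case=n_case, n_control=n_control)


def make_harmonized(bx, sx, by, sy) -> list[HarmonizedInstrument]:
    return [
        HarmonizedInstrument(
            snp_id=f"rs{j}", effect_allele="A", other_allele="G",
            beta_exp=float(bx[j]), se_exp=float(sx[j]),
            beta_out=float(by[j]), se_out=float(sy[j]),
            eaf_exp=0.3, eaf_out=0.3, action_taken="as_is", palindromic=False)
        for j in range(len(bx))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_harmonized(rng):
    """An 8-SNP harmonized set with heterogeneous effects and SEs."""
    k = 8
    bx = rng.uniform(0.05, 0.2, k)
    sx = rng.uniform(0.005, 0.02, k)
    by = 0.4 * bx + rng.normal(0, 0.01, k)
    sy = rng.uniform(0.01, 0.05, k)
    return make_harmonized(bx, sx, by, sy)
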