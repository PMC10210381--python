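"""Synthetic GWAS summary statistics with known ground truth.

The generator works at summary level: per-SNP exposure effects are drawn so
that the instruments jointly explain a chosen fraction R² of a unit-variance
exposure, and outcome effects follow the structural model
``gamma_j = theta * b_j + alpha_j`` where ``theta`` is the causal log odds
ratio per unit exposure and ``alpha_j`` is a horizontal-pleiotropy term drawn
independently of instrument strength (so a zero pleiotropy mean satisfies the
InSIDE condition by construction).  Standard errors use the exact
large-sample forms — ``sqrt((1-R²)/(2 p (1-p) n))`` for a quantitative
exposure, ``1/sqrt(2 p (1-p) n phi (1-phi))`` for a binary outcome with case
fraction ``phi`` — which makes analytic power and simulated power directly
comparable.

Defaults mirror the study conditions the pipeline is aimed at: 3–13
genome-wide-significant instruments per exposure with per-SNP F far above 10,
a continuous coagulation-factor exposure measured in ~20k individuals, and a
binary endometriosis outcome with case:control shapes of 4354:217500 (UK
Biobank) or 8288:68969 (FinnGen).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .gwas_io import SummaryStatRecord
from .pvalues import two_sided_p

#: Non-palindromic effect/other allele pairs used for simulated instruments.
_SAFE_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                      ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters for one simulated exposure→outcome study.

    theta
        True causal effect: log odds of the outcome per unit (1 SD) exposure.
    k
        Number of true instruments.
    maf_range
        Interval for uniform minor-allele-frequency draws, within (0, 0.5].
    r2_total
        Exposure variance jointly explained by the k instruments.
    n_exposure
        Exposure GWAS sample size.
    n_case, n_control
        Outcome GWAS case/control counts (FinnGen-shaped by default).
    pleio_mean, pleio_sd
        Mean and SD of the per-SNP direct (pleiotropic) outcome effect;
        mean 0 gives balanced pleiotropy, nonzero mean directional
        pleiotropy with InSIDE still holding.
    n_null_snps
        Background SNPs with no exposure effect, for selection testing.
    palindrome_fraction
        Fraction of instruments drawn with A/T or G/C alleles, to exercise
        strand-ambiguity handling (0 by default so harmonization keeps all
        k instruments).
    """

    theta: float = 0.0
    k: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    r2_total: float = 0.02
    n_exposure: int = 20_000
    n_case: int = 8_288
    n_control: int = 68_969
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    n_null_snps: int = 0
    palindrome_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.r2_total < 1.0):
            raise ValueError("r2_total must lie strictly between 0 and 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_exposure <= 2 or self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("sample sizes must be positive (n_exposure > 2)")

    @property
    def n_outcome(self) -> int:
        return self.n_case + self.n_control

    @property
    def case_fraction(self) -> float:
        return self.n_case / self.n_outcome

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ExposureTruth:
    """Per-SNP generating values carried from exposure to outcome simulation."""

    snp_ids: list[str]
    maf: np.ndarray
    beta_true: np.ndarray          # true per-allele exposure effects b_j
    is_instrument: np.ndarray      # False for background null SNPs
    alleles: list[tuple[str, str]] = field(default_factory=list)
    chrom: list[str] = field(default_factory=list)
    pos: list[int] = field(default_factory=list)


def _assign_positions(m: int) -> tuple[list[str], list[int]]:
    # Spread SNPs over chromosomes, >10 Mb apart, so default clumping windows
    # never merge distinct instruments.
    chroms, positions = [], []
    for j in range(m):
        chroms.append(str(j % 22 + 1))
        positions.append(1_000_000 + 20_000_000 * (j // 22 + 1) + 13 * j)
    return chroms, positions


def simulate_exposure_sumstats(
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
    add_noise: bool = True,
) -> tuple[list[SummaryStatRecord], ExposureTruth]:
    """Simulate the exposure GWAS: k instruments plus optional null SNPs.

    True effects are scaled so that ``sum 2 p_j (1-p_j) b_j² = r2_total`` on
    the unit-variance exposure scale; observed betas add N(0, se²) noise
    unless ``add_noise`` is False (the reported SEs are unchanged, only the
    sampling noise is suppressed).
    """
    rng = truth.rng() if rng is None else rng
    k, m = truth.k, truth.k + truth.n_null_snps

    maf = rng.uniform(truth.maf_range[0], truth.maf_range[1], size=m)
    # Effect alleles are coded exposure-increasing (the convention used when
    # reporting instruments), so true effects are positive, and per-SNP
    # explained-variance shares are mildly heterogeneous rather than tied to
    # MAF: each instrument contributes r2_total * raw_j^2 / sum(raw^2) with
    # raw ~ U(0.7, 1.3).  This keeps every instrument's expected per-SNP F
    # comfortably above 10 at the default R² and sample size and gives
    # directional pleiotropy a well-defined sign.
    raw = rng.uniform(0.7, 1.3, size=k)
    het = 2.0 * maf[:k] * (1.0 - maf[:k])
    per_snp_r2 = truth.r2_total * raw**2 / np.sum(raw**2)
    b = np.zeros(m)
    b[:k] = np.sqrt(per_snp_r2 / het)
    if np.any(per_snp_r2 >= 1.0):
        raise ValueError("infeasible r2_total: a single SNP would explain >= 100% "
                         "of exposure variance")

    se = np.sqrt((1.0 - truth.r2_total)
                 / (2.0 * maf * (1.0 - maf) * truth.n_exposure))
    noise = rng.normal(0.0, 1.0, size=m) * se if add_noise else np.zeros(m)
    beta_obs = b + noise
    pvals = two_sided_p(beta_obs / se)

    snp_ids = [f"rs{1000 + j}" for j in range(m)]
    chroms, positions = _assign_positions(m)
    n_pal = int(round(truth.palindrome_fraction * m))
    alleles = []
    for j in range(m):
        pool = _PALINDROMIC_PAIRS if j < n_pal else _SAFE_ALLELE_PAIRS
        alleles.append(pool[int(rng.integers(len(pool)))])

    records = [
        SummaryStatRecord(
            snp_id=snp_ids[j], chrom=chroms[j], pos=positions[j],
            effect_allele=alleles[j][0], other_allele=alleles[j][1],
            beta=float(beta_obs[j]), se=float(se[j]),
            pval=float(pvals[j]),
            eaf=float(maf[j]), n=truth.n_exposure,
        )
        for j in range(m)
    ]
    exposure_truth = ExposureTruth(
        snp_ids=snp_ids, maf=maf, beta_true=b,
        is_instrument=np.arange(m) < k,
        alleles=alleles, chrom=chroms, pos=positions)
    return records, exposure_truth


def outcome_se(maf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    """Large-sample SE of a per-allele log-OR from a binary-trait GWAS."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n
                         * case_fraction * (1.0 - case_fraction))


def simulate_outcome_sumstats(
    exposure_truth: ExposureTruth,
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
    add_noise: bool = True,
    n_case: int | None = None,
    n_control: int | None = None,
) -> list[SummaryStatRecord]:
    """Simulate the outcome GWAS on the SNPs of an exposure simulation.

    True outcome effects are ``gamma_j = theta b_j + alpha_j`` with the
    pleiotropy term alpha drawn N(pleio_mean, pleio_sd²) for instruments and
    zero for null SNPs.
    """
    rng = np.random.default_rng(truth.seed + 1) if rng is None else rng
    n_case = truth.n_case if n_case is None else n_case
    n_control = truth.n_control if n_control is None else n_control
    n = n_case + n_control
    phi = n_case / n

    m = len(exposure_truth.snp_ids)
    alpha = np.where(
        exposure_truth.is_instrument,
        rng.normal(truth.pleio_mean, truth.pleio_sd, size=m)
        if truth.pleio_sd > 0 else truth.pleio_mean * exposure_truth.is_instrument,
        0.0)
    gamma = truth.theta * exposure_truth.beta_true + alpha
    se = outcome_se(exposure_truth.maf, n, phi)
    noise = rng.normal(0.0, 1.0, size=m) * se if add_noise else np.zeros(m)
    beta_obs = gamma + noise
    pvals = two_sided_p(beta_obs / se)

    return [
        SummaryStatRecord(
            snp_id=exposure_truth.snp_ids[j],
            chrom=exposure_truth.chrom[j], pos=exposure_truth.pos[j],
            effect_allele=exposure_truth.alleles[j][0],
            other_allele=exposure_truth.alleles[j][1],
            beta=float(beta_obs[j]), se=float(se[j]),
            pval=float(pvals[j]),
            eaf=float(exposure_truth.maf[j]),
            n=n, n_case=n_case, n_control=n_control,
        )
        for j in range(m)
    ]


@dataclass
class FlipKey:
    """Record of the allele scrambling applied to a simulated cohort.

    ``swapped`` exchanges effect/other allele (negating beta and mirroring
    eaf); ``strand_flipped`` complements both alleles without changing beta.
    """

    swapped: dict[str, bool]
    strand_flipped: dict[str, bool]

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "FlipKey":
        return cls({s: False for s in snp_ids}, {s: False for s in snp_ids})


def apply_flip_key(records: Sequence[SummaryStatRecord], key: FlipKey,
                   ) -> list[SummaryStatRecord]:
    """Re-express records under the swaps/strand flips in ``key``.

    Applying the same key twice is the identity, which is what makes the
    recorded key a round-trip oracle for harmonization.
    """
    out = []
    for r in records:
        ea, oa, beta, eaf = r.effect_allele, r.other_allele, r.beta, r.eaf
        if key.strand_flipped.get(r.snp_id, False):
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        if key.swapped.get(r.snp_id, False):
            ea, oa = oa, ea
            beta = -beta
            eaf = None if eaf is None else 1.0 - eaf
        out.append(r.copy(effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf))
    return out


def simulate_cohort_pair(
    exposure_truth: ExposureTruth,
    truth: SimulationTruth,
    second_cohort: tuple[int, int] = (4_354, 217_500),
    rng: np.random.Generator | None = None,
    scramble_second: bool = True,
    add_noise: bool = True,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], FlipKey]:
    """Two independent outcome GWAS draws sharing the same true effects.

    The second cohort's case:control shape defaults to the UK Biobank
    endometriosis GWAS (4354:217500); its allele columns are randomly
    swapped/strand-flipped with the returned :class:`FlipKey` so cross-cohort
    alignment can be verified against a known key.
    """
    rng = np.random.default_rng(truth.seed + 2) if rng is None else rng
    cohort_a = simulate_outcome_sumstats(exposure_truth, truth, rng=rng,
                                         add_noise=add_noise)
    cohort_b = simulate_outcome_sumstats(
        exposure_truth, truth, rng=rng, add_noise=add_noise,
        n_case=second_cohort[0], n_control=second_cohort[1])
    if scramble_second:
        ids = exposure_truth.snp_ids
        key = FlipKey(
            swapped={s: bool(rng.integers(2)) for s in ids},
            strand_flipped={s: bool(rng.integers(2)) for s in ids})
    else:
        key = FlipKey.identity(exposure_truth.snp_ids)
    return cohort_a, apply_flip_key(cohort_b, key), key


def simulate_harmonized(
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
    add_noise: bool = True,
) -> list:
    """One exposure draw and one outcome draw paired into harmonized form.

    Simulated exposure and outcome records share SNP ids and alleles, so
    harmonization is the identity pairing; building the harmonized
    instruments directly keeps Monte-Carlo replication cheap.  Equivalence
    with the full :func:`coagmr.harmonize.harmonize_set` route is covered by
    the test suite.
    """
    from .harmonize import HarmonizedInstrument, is_palindromic

    rng = truth.rng() if rng is None else rng
    exp_records, exp_truth = simulate_exposure_sumstats(truth, rng=rng,
                                                        add_noise=add_noise)
    out_records = simulate_outcome_sumstats(exp_truth, truth, rng=rng,
                                            add_noise=add_noise)
    return [
        HarmonizedInstrument(
            snp_id=e.snp_id, effect_allele=e.effect_allele,
            other_allele=e.other_allele,
            beta_exp=e.beta, se_exp=e.se, beta_out=o.beta, se_out=o.se,
            eaf_exp=e.eaf, eaf_out=o.eaf, action_taken="as_is",
            palindromic=is_palindromic(e.effect_allele, e.other_allele))
        for e, o in zip(exp_records, out_records)
        if exp_truth.is_instrument[exp_truth.snp_ids.index(e.snp_id)]
    ]


def identity_ld(snp_ids: Sequence[str],
                positions: Sequence[int] | None = None) -> "LDMatrix":
    """LD matrix with no correlation between distinct SNPs."""
    from .gwas_io import LDMatrix
    n = len(snp_ids)
    return LDMatrix(snp_ids=list(snp_ids), r2=np.eye(n),
                    positions=None if positions is None else np.asarray(positions))
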