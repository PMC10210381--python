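"""Causal estimators and sensitivity analyses for one exposure–outcome pair.

Estimators operate on harmonized per-SNP effect pairs (beta_exp, beta_out):

* Wald ratio per SNP, beta_out/beta_exp, SE by the first-order delta method.
* Fixed-effects IVW: inverse-variance-weighted mean of Wald ratios, which is
  algebraically the zero-intercept weighted regression of beta_out on
  beta_exp with weights 1/se_out².
* Multiplicative random-effects IVW: same point estimate, SE inflated by
  sqrt(max(1, Q/(k−1))).
* MR-Egger: weighted regression with a free intercept after orienting all
  SNPs to beta_exp ≥ 0; a nonzero intercept indicates directional
  horizontal pleiotropy.  SEs inflated by sqrt(max(1, Q_egger/(k−2))).
* Weighted median of the Wald ratios (consistent when valid instruments
  carry a majority of weight), SE by seeded parametric bootstrap.

Sensitivity: Cochran's Q against the IVW and Egger fits, leave-one-out IVW,
and the Steiger directionality test comparing variance explained in the
exposure versus the outcome.  All p-values use the normal (or chi-square)
reference; the 95% CI multiplier is 1.959964.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument
from .pvalues import two_sided_p

logger = logging.getLogger("coagmr")

CI_Z = 1.959964


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class MRResult:
    """One method's causal estimate for one exposure–outcome pair."""

    method: str                 # wald | ivw_fixed | ivw_random | egger | weighted_median
    nsnp: int
    beta: float
    se: float
    pval: float
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    or_: float = field(init=False)
    or_ci_low: float = field(init=False)
    or_ci_high: float = field(init=False)
    pval_adjusted: float | None = None

    def __post_init__(self) -> None:
        self.ci_low = self.beta - CI_Z * self.se
        self.ci_high = self.beta + CI_Z * self.se
        self.or_ = math.exp(self.beta)
        self.or_ci_low = math.exp(self.ci_low)
        self.or_ci_high = math.exp(self.ci_high)


@dataclass
class EggerIntercept:
    intercept: float
    se: float
    pval: float


@dataclass
class LeaveOneOutEntry:
    snp_id: str
    beta: float
    se: float
    pval: float


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy, stability and directionality diagnostics."""

    q_ivw: float | None = None
    q_ivw_df: int | None = None
    q_ivw_pval: float | None = None
    q_egger: float | None = None
    q_egger_df: int | None = None
    q_egger_pval: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    loo: list[LeaveOneOutEntry] = field(default_factory=list)
    steiger_r2_exp: float | None = None
    steiger_r2_out: float | None = None
    steiger_direction: bool | None = None   # True: exposure -> outcome
    steiger_pval: float | None = None


@dataclass
class MRConfig:
    """Knobs shared by the composite analysis."""

    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    m_tests: int | None = None
    n_exposure: int | None = None
    n_outcome: int | None = None
    egger_inflate_se: bool = True


@dataclass
class MRAnalysis:
    results: list[MRResult]
    sensitivity: SensitivityReport
    skipped: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _arrays(harmonized: list[HarmonizedInstrument]):
    bx = np.array([h.beta_exp for h in harmonized])
    sx = np.array([h.se_exp for h in harmonized])
    by = np.array([h.beta_out for h in harmonized])
    sy = np.array([h.se_out for h in harmonized])
    return bx, sx, by, sy


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               ) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp with first-order delta SE."""
    if beta_exp == 0:
        raise ValueError("Wald ratio undefined for beta_exp = 0")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def _ratios(harmonized):
    bx, sx, by, sy = _arrays(harmonized)
    if np.any(bx == 0):
        bad = [h.snp_id for h in harmonized if h.beta_exp == 0]
        raise ValueError(f"Wald ratio undefined for beta_exp = 0: {bad}")
    return by / bx, sy / np.abs(bx)


def ivw_fixed(harmonized: list[HarmonizedInstrument]) -> MRResult:
    """Fixed-effects IVW: precision-weighted mean of the Wald ratios.

    Computed both as the weighted mean and as the zero-intercept weighted
    regression of outcome on exposure effects; the two closed forms are
    algebraically identical and are cross-checked here.
    """
    if not harmonized:
        raise ValueError("IVW requires at least 1 SNP")
    r, rse = _ratios(harmonized)
    w = 1.0 / rse**2
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    bx, _, by, sy = _arrays(harmonized)
    beta_reg = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    if abs(beta - beta_reg) > 1e-10 * max(1.0, abs(beta)):
        raise AssertionError(
            f"IVW formulations disagree: {beta} vs {beta_reg}")
    return MRResult("ivw_fixed", len(harmonized), beta, se,
                    two_sided_p(beta / se))


def cochran_q(harmonized: list[HarmonizedInstrument], model: str = "ivw",
              ) -> tuple[float, int, float]:
    """Cochran's Q of the Wald ratios around the IVW or Egger fit."""
    k = len(harmonized)
    df = k - 1 if model == "ivw" else k - 2
    if df < 1:
        raise ValueError(f"Q undefined: {k} SNPs leaves df={df} for {model}")
    r, rse = _ratios(harmonized)
    w = 1.0 / rse**2
    if model == "ivw":
        fitted = np.full(k, ivw_fixed(harmonized).beta)
    elif model == "egger":
        slope, intercept = _egger_fit(harmonized)[:2]
        bx = np.array([h.beta_exp for h in harmonized])
        # fitted ratio = (intercept + slope*|bx|)/bx on the oriented scale
        fitted = slope + intercept / np.abs(bx)
    else:
        raise ValueError(f"unknown Q model: {model}")
    q = float(np.sum(w * (r - fitted) ** 2))
    return q, df, float(stats.chi2.sf(q, df))


def ivw_random(harmonized: list[HarmonizedInstrument]) -> MRResult:
    """Multiplicative random-effects IVW: same estimate, Q-inflated SE."""
    if len(harmonized) < 2:
        raise ValueError("random-effects IVW requires at least 2 SNPs")
    fixed = ivw_fixed(harmonized)
    q, df, _ = cochran_q(harmonized, "ivw")
    se = fixed.se * math.sqrt(max(1.0, q / df))
    return MRResult("ivw_random", fixed.nsnp, fixed.beta, se,
                    two_sided_p(fixed.beta / se))


def _egger_fit(harmonized):
    """Weighted-least-squares Egger fit on beta_exp-oriented data.

    Returns (slope, intercept, se_slope, se_intercept, sigma) where sigma is
    the dispersion scale sqrt(Q_egger/(k−2)) before flooring.
    """
    bx, _, by, sy = _arrays(harmonized)
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    intercept, slope = coef
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    cov = np.linalg.inv(xtwx)
    sigma = math.sqrt(q / (len(x) - 2))
    return slope, intercept, math.sqrt(cov[1, 1]), math.sqrt(cov[0, 0]), sigma


def mr_egger(harmonized: list[HarmonizedInstrument],
             inflate_se: bool = True) -> tuple[MRResult, EggerIntercept]:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    SNPs are oriented to beta_exp ≥ 0 before fitting.  With ``inflate_se``
    (default) both parameter SEs are scaled by max(1, sqrt(Q_egger/(k−2))).
    """
    if len(harmonized) < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    slope, intercept, se_s, se_i, sigma = _egger_fit(harmonized)
    scale = max(1.0, sigma) if inflate_se else 1.0
    se_s, se_i = se_s * scale, se_i * scale
    result = MRResult("egger", len(harmonized), float(slope), float(se_s),
                      two_sided_p(slope / se_s))
    return result, EggerIntercept(float(intercept), float(se_i),
                                  two_sided_p(intercept / se_i))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Value at cumulative normalized weight 0.5, linearly interpolated."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def weighted_median(harmonized: list[HarmonizedInstrument],
                    n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Implements the estimator commonly abbreviated WM in applied two-sample
    MR reports: the value at half the cumulative inverse-variance weight of
    the ordered Wald ratios.  The SE perturbs per-SNP exposure and outcome
    betas by their SEs over ``n_boot`` seeded replicates.
    """
    if len(harmonized) < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    r, rse = _ratios(harmonized)
    beta = _weighted_median(r, 1.0 / rse**2)

    bx, sx, by, sy = _arrays(harmonized)
    rng = np.random.default_rng(seed)
    k = len(bx)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        xb = bx_b[i]
        if np.any(xb == 0):
            xb = np.where(xb == 0, 1e-300, xb)
        rb = by_b[i] / xb
        boot[i] = _weighted_median(rb, (xb / sy) ** 2)
    se = float(np.std(boot, ddof=1))
    return MRResult("weighted_median", k, beta, se, two_sided_p(beta / se))


def leave_one_out(harmonized: list[HarmonizedInstrument],
                  ) -> list[LeaveOneOutEntry]:
    """Fixed-effects IVW re-estimated with each SNP excluded in turn."""
    if len(harmonized) < 2:
        raise ValueError("leave-one-out requires at least 2 SNPs")
    entries = []
    for j, h in enumerate(harmonized):
        subset = harmonized[:j] + harmonized[j + 1:]
        res = ivw_fixed(subset)
        entries.append(LeaveOneOutEntry(h.snp_id, res.beta, res.se, res.pval))
    return entries


def steiger(harmonized: list[HarmonizedInstrument], n_exp: int, n_out: int,
            ) -> tuple[float, float, bool, float]:
    """Steiger directionality: variance explained in exposure vs outcome.

    Per-SNP r² = z²/(z² + n − 2) on each side; the causal direction is
    exposure→outcome when the instruments explain more exposure than outcome
    variance.  The p-value tests the difference of the summed
    Fisher-transformed per-SNP correlations.
    """
    if n_exp is None or n_out is None:
        raise ValueError("Steiger test needs both sample sizes")
    bx, sx, by, sy = _arrays(harmonized)
    zx2, zy2 = (bx / sx) ** 2, (by / sy) ** 2
    r2x = zx2 / (zx2 + n_exp - 2)
    r2y = zy2 / (zy2 + n_out - 2)
    k = len(bx)
    zdiff = (np.sum(np.arctanh(np.sqrt(r2x))) - np.sum(np.arctanh(np.sqrt(r2y)))) \
        / math.sqrt(k / (n_exp - 3) + k / (n_out - 3))
    return (float(r2x.sum()), float(r2y.sum()),
            bool(r2x.sum() > r2y.sum()), two_sided_p(zdiff))


def adjust_pvalues(pvals, m: int) -> list[float]:
    """Bonferroni adjustment across a family of ``m`` tests, order preserved."""
    pvals = list(pvals)
    if m < len(pvals):
        raise ValueError(f"family size m={m} smaller than {len(pvals)} p-values")
    return [min(1.0, p * m) for p in pvals]


# ---------------------------------------------------------------------------
# Composite analysis
# ---------------------------------------------------------------------------

def run_all_methods(harmonized: list[HarmonizedInstrument],
                    config: MRConfig | None = None) -> MRAnalysis:
    """Run every applicable estimator and sensitivity analysis.

    Fixed-effects IVW always runs; weighted median and MR-Egger require 3
    SNPs; random-effects IVW is added exactly when the IVW Cochran's Q
    p-value falls below ``config.alpha``.  Skipped components are recorded
    with reasons, never silently absent.
    """
    config = config or MRConfig()
    if not harmonized:
        raise ValueError("MR refuses to run on zero harmonized SNPs")
    k = len(harmonized)
    results: list[MRResult] = []
    skipped: dict[str, str] = {}
    sens = SensitivityReport()

    if k == 1:
        r, rse = _ratios(harmonized)
        results.append(MRResult("wald", 1, float(r[0]), float(rse[0]),
                                two_sided_p(r[0] / rse[0])))
    results.append(ivw_fixed(harmonized))

    if k >= 2:
        sens.q_ivw, sens.q_ivw_df, sens.q_ivw_pval = cochran_q(harmonized, "ivw")
    else:
        skipped["cochran_q_ivw"] = "needs >=2 SNPs"

    if k >= 3:
        results.append(weighted_median(harmonized, n_boot=config.n_boot,
                                       seed=config.seed))
        egger_res, egger_int = mr_egger(harmonized,
                                        inflate_se=config.egger_inflate_se)
        results.append(egger_res)
        sens.egger_intercept = egger_int.intercept
        sens.intercept_se = egger_int.se
        sens.intercept_pval = egger_int.pval
        sens.q_egger, sens.q_egger_df, sens.q_egger_pval = cochran_q(
            harmonized, "egger")
    else:
        skipped["weighted_median"] = skipped["egger"] = \
            skipped["cochran_q_egger"] = "needs >=3 SNPs"

    if sens.q_ivw_pval is not None and sens.q_ivw_pval < config.alpha:
        results.append(ivw_random(harmonized))

    if k >= 2:
        sens.loo = leave_one_out(harmonized)
    else:
        skipped["leave_one_out"] = "needs >=2 SNPs"

    if config.n_exposure and config.n_outcome:
        (sens.steiger_r2_exp, sens.steiger_r2_out,
         sens.steiger_direction, sens.steiger_pval) = steiger(
            harmonized, config.n_exposure, config.n_outcome)
    else:
        skipped["steiger"] = "sample sizes not provided"

    if config.m_tests:
        for res in results:
            res.pval_adjusted = min(1.0, res.pval * config.m_tests)

    for name, why in skipped.items():
        logger.info("skipped %s: %s", name, why)
    return MRAnalysis(results=results, sensitivity=sens, skipped=skipped)
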