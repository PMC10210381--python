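"""Causal estimators and sensitivity analyses against independent oracles."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from coagmr.mr import (
    MRConfig,
    adjust_pvalues,
    cochran_q,
    ivw_fixed,
    ivw_random,
    leave_one_out,
    mr_egger,
    run_all_methods,
    steiger,
    wald_ratio,
    weighted_median,
)
from coagmr.simulate import SimulationTruth, simulate_harmonized

from conftest import make_harmonized


class TestWaldRatio:
    @pytest.mark.parametrize("by,expected", [(0.0, 0.0), (0.1, 1.0)])
    def test_simple_ratios(self, by, expected):
        ratio, _ = wald_ratio(0.1, 0.01, by, 0.02)
        assert ratio == expected

    def test_zero_exposure_effect_fatal(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_first_order_se_close_to_monte_carlo(self, rng):
        # (0.1, 0.01, 0.05, 0.02): first-order delta SE = 0.02/0.1 = 0.2;
        # full sampling propagation at these z's agrees within a few percent.
        ratio, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert (ratio, se) == (0.5, pytest.approx(0.2))
        bx = rng.normal(0.1, 0.01, 1_000_000)
        by = rng.normal(0.05, 0.02, 1_000_000)
        mc_sd = np.std(by / bx)
        # the second-order delta method adds the exposure-noise term
        second = math.sqrt(0.02**2 / 0.1**2 + 0.05**2 * 0.01**2 / 0.1**4)
        assert abs(second - mc_sd) / mc_sd < 0.02
        assert abs(se - mc_sd) / mc_sd < 0.05


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        res = ivw_fixed(h)
        assert res.beta == pytest.approx(0.5) and res.se == pytest.approx(0.2)

    def test_hand_computed_weighted_mean(self):
        # ratios (0.5, 1.0) with ratio SEs (0.1, 0.2): weights 100 and 25,
        # so beta = (100*0.5 + 25*1.0)/125 = 0.6 and se = 1/sqrt(125).
        h = make_harmonized([1.0, 1.0], [0.01, 0.01], [0.5, 1.0], [0.1, 0.2])
        res = ivw_fixed(h)
        assert res.beta == pytest.approx(0.6, abs=1e-12)
        assert res.se == pytest.approx(1 / math.sqrt(125), abs=1e-12)

    def test_exact_proportional_data_recovered_to_machine_precision(self):
        truth = SimulationTruth(theta=0.5, k=6, seed=2)
        h = simulate_harmonized(truth, add_noise=False)
        assert ivw_fixed(h).beta == pytest.approx(0.5, rel=1e-12)

    def test_two_formulations_agree(self, random_harmonized):
        # the ratio-meta-analysis and zero-intercept weighted-regression
        # closed forms are cross-checked to 1e-10 inside ivw_fixed
        res = ivw_fixed(random_harmonized)
        bx = np.array([h.beta_exp for h in random_harmonized])
        by = np.array([h.beta_out for h in random_harmonized])
        sy = np.array([h.se_out for h in random_harmonized])
        reg = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
        assert abs(res.beta - reg) < 1e-10

    def test_random_effects_same_estimate_wider_se(self):
        h = make_harmonized([1, 1, 1, 1], [0.01] * 4,
                            [0.1, 0.9, -0.4, 1.4], [0.1] * 4)
        fixed, random_ = ivw_fixed(h), ivw_random(h)
        assert random_.beta == fixed.beta
        q, df, _ = cochran_q(h, "ivw")
        assert random_.se == pytest.approx(fixed.se * math.sqrt(q / df))
        assert random_.ci_high - random_.ci_low > fixed.ci_high - fixed.ci_low

    def test_random_effects_floor_at_fixed(self):
        # homogeneous data: Q < df, so no inflation
        h = make_harmonized([1, 1, 1], [0.01] * 3,
                            [0.500, 0.501, 0.499], [0.1] * 3)
        assert ivw_random(h).se == ivw_fixed(h).se

    def test_ci_and_or_transforms(self, random_harmonized):
        res = ivw_fixed(random_harmonized)
        assert res.ci_low < res.beta < res.ci_high
        assert res.or_ == pytest.approx(math.exp(res.beta))
        assert res.or_ci_low < res.or_ < res.or_ci_high
        assert res.ci_high - res.beta == pytest.approx(1.959964 * res.se)


class TestEgger:
    def test_exact_affine_data_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        h = make_harmonized(bx, [0.01] * 4, 0.5 * bx, [0.02] * 4)
        res, intercept = mr_egger(h)
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.intercept == pytest.approx(0.0, abs=1e-10)

        h2 = make_harmonized(bx, [0.01] * 4, 0.5 * bx + 0.02, [0.02] * 4)
        res2, intercept2 = mr_egger(h2)
        assert res2.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept2.intercept == pytest.approx(0.02, abs=1e-10)

    def test_against_weighted_least_squares_oracle(self, random_harmonized):
        import statsmodels.api as sm
        bx = np.array([h.beta_exp for h in random_harmonized])
        by = np.array([h.beta_out for h in random_harmonized])
        sy = np.array([h.se_out for h in random_harmonized])
        sign = np.where(bx < 0, -1, 1)
        x, y, w = bx * sign, by * sign, 1 / sy**2
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        res, intercept = mr_egger(random_harmonized)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-8)
        assert intercept.intercept == pytest.approx(fit.params[0], abs=1e-8)
        # SE oracle: (X'WX)^-1 scaled by max(1, sqrt(Q/(k-2)))
        X = np.column_stack([np.ones_like(x), x])
        cov = np.linalg.inv(X.T @ (w[:, None] * X))
        q = float(np.sum(w * (y - X @ fit.params) ** 2))
        scale = max(1.0, math.sqrt(q / (len(x) - 2)))
        assert intercept.se == pytest.approx(math.sqrt(cov[0, 0]) * scale, abs=1e-8)
        assert res.se == pytest.approx(math.sqrt(cov[1, 1]) * scale, abs=1e-8)

    def test_orientation_invariance(self, random_harmonized):
        flipped = [dataclasses.replace(h, beta_exp=-h.beta_exp,
                                       beta_out=-h.beta_out)
                   for h in random_harmonized]
        a, ia = mr_egger(random_harmonized)
        b, ib = mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert ia.intercept == pytest.approx(ib.intercept, rel=1e-12)

    def test_too_few_snps_fatal(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(ValueError):
            mr_egger(h)


class TestWeightedMedian:
    def test_constant_ratios_returned_exactly(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                            [0.07, 0.14, 0.28], [0.02, 0.03, 0.05])
        assert weighted_median(h).beta == pytest.approx(0.7, rel=1e-10)

    def test_outlier_robustness(self):
        # equal weights, ratios (1, 2, 100): median 2, mean would be ~34.3
        h = make_harmonized([1, 1, 1], [0.01] * 3, [1, 2, 100], [1, 1, 1])
        res = weighted_median(h, seed=1)
        assert res.beta == pytest.approx(2.0)
        assert ivw_fixed(h).beta == pytest.approx(103 / 3)

    def test_against_cumulative_weight_scan(self, rng):
        # independent oracle: scan the weight-ordered ratios for the 0.5
        # crossing of (cumsum(w) - w/2)/sum(w) and interpolate linearly
        bx = rng.uniform(0.05, 0.3, 5)
        by = rng.normal(0.1, 0.05, 5)
        sy = rng.uniform(0.02, 0.08, 5)
        h = make_harmonized(bx, [0.01] * 5, by, sy)
        ratios = by / bx
        weights = (bx / sy) ** 2
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order] / weights.sum()
        cum = np.cumsum(w) - w / 2
        i = int(np.searchsorted(cum, 0.5))
        oracle = r[i - 1] + (r[i] - r[i - 1]) * (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
        assert weighted_median(h).beta == pytest.approx(oracle, rel=1e-12)

    def test_bootstrap_se_deterministic_under_seed(self, random_harmonized):
        a = weighted_median(random_harmonized, seed=11)
        b = weighted_median(random_harmonized, seed=11)
        c = weighted_median(random_harmonized, seed=12)
        assert a.se == b.se
        assert a.se != c.se  # different seed, different bootstrap draw

    def test_consistent_with_minority_invalid_instruments(self):
        # 40% of instruments carry strong directional pleiotropy; the
        # weighted median (valid majority) still recovers theta.
        theta, reps = 0.3, 500
        rng = np.random.default_rng(99)
        # outcome noise kept small relative to the planted pleiotropy so the
        # valid-majority consistency property is visible at finite samples
        truth = SimulationTruth(theta=theta, k=10, r2_total=0.05,
                                n_exposure=50_000, n_case=828_800,
                                n_control=6_896_900, seed=99)
        estimates = []
        for _ in range(reps):
            h = simulate_harmonized(truth, rng=rng)
            for bad in h[:4]:  # plant 4/10 invalid instruments
                bad.beta_out += 0.03
            estimates.append(weighted_median(h, n_boot=1, seed=1).beta)
        assert abs(np.mean(estimates) - theta) < 0.05


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        h = make_harmonized([1, 1], [0.01] * 2, [0.5, 0.5], [0.1, 0.1])
        q, df, p = cochran_q(h, "ivw")
        assert q == pytest.approx(0.0, abs=1e-20) and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_two_snp_case(self):
        # ratios (0, 2) with unit ratio SEs: IVW estimate 1, Q = 1 + 1 = 2,
        # df = 1, p = P(chi2_1 > 2) ~ 0.157
        h = make_harmonized([1, 1], [0.01] * 2, [0.0, 2.0], [1.0, 1.0])
        q, df, p = cochran_q(h, "ivw")
        assert q == pytest.approx(2.0, abs=1e-12) and df == 1
        assert p == pytest.approx(stats.chi2.sf(2, 1), abs=1e-12)
        assert p == pytest.approx(0.157, abs=5e-4)

    def test_egger_variant_uses_its_own_fit_and_df(self, random_harmonized):
        q_i, df_i, _ = cochran_q(random_harmonized, "ivw")
        q_e, df_e, _ = cochran_q(random_harmonized, "egger")
        k = len(random_harmonized)
        assert (df_i, df_e) == (k - 1, k - 2)
        assert q_e <= q_i + 1e-9  # adding an intercept cannot raise RSS

    def test_df_below_one_fatal(self):
        h = make_harmonized([1], [0.01], [0.5], [0.1])
        with pytest.raises(ValueError):
            cochran_q(h, "ivw")


class TestLeaveOneOut:
    def test_two_snp_reduction(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.04], [0.02, 0.02])
        loo = leave_one_out(h)
        assert loo[0].beta == pytest.approx(0.04 / 0.2)
        assert loo[1].beta == pytest.approx(0.05 / 0.1)

    def test_homogeneous_data_all_entries_equal_full(self):
        truth = SimulationTruth(theta=0.4, k=6, seed=5)
        h = simulate_harmonized(truth, add_noise=False)
        full = ivw_fixed(h).beta
        for entry in leave_one_out(h):
            assert entry.beta == pytest.approx(full, rel=1e-10)

    def test_planted_outlier_identified(self):
        truth = SimulationTruth(theta=0.2, k=8, r2_total=0.05,
                                n_exposure=100_000, seed=14)
        h = simulate_harmonized(truth)
        h[3].beta_out += 0.12  # plant one strongly pleiotropic SNP
        full = ivw_fixed(h)
        loo = leave_one_out(h)
        moves = {e.snp_id: abs(e.beta - full.beta) for e in loo}
        # the entry omitting the outlier moves most, back toward truth
        top = max(moves, key=moves.get)
        assert top == h[3].snp_id
        omitting = next(e for e in loo if e.snp_id == top)
        assert abs(omitting.beta - 0.2) < abs(full.beta - 0.2)


class TestSteiger:
    def test_zero_outcome_effects_point_forward(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.02, 0.02])
        r2x, r2y, direction, p = steiger(h, 20_000, 77_257)
        assert r2y == 0.0 and direction is True

    def test_antisymmetric_under_exposure_outcome_swap(self, random_harmonized):
        fwd = steiger(random_harmonized, 20_000, 77_257)
        swapped = [dataclasses.replace(h, beta_exp=h.beta_out, se_exp=h.se_out,
                                       beta_out=h.beta_exp, se_out=h.se_exp)
                   for h in random_harmonized]
        rev = steiger(swapped, 77_257, 20_000)
        assert fwd[2] != rev[2]
        assert fwd[3] == pytest.approx(rev[3], rel=1e-12)

    def test_forward_direction_under_default_design(self):
        truth = SimulationTruth(theta=0.2, k=10, seed=23)
        rng = truth.rng()
        forward = sum(
            steiger(simulate_harmonized(truth, rng=rng), truth.n_exposure,
                    truth.n_outcome)[2]
            for _ in range(500))
        assert forward >= 495  # >= 99% of replicates


class TestAdjustPvalues:
    def test_printed_adjustments_reproduced(self):
        # 1.25e-4 * 11 = 1.375e-3 (printed 1.38e-3);
        # 5.31e-4 * 11 = 5.841e-3 (printed 5.8e-3)
        adj = adjust_pvalues([1.25e-4, 5.31e-4], m=11)
        assert adj[0] == pytest.approx(1.375e-3, rel=1e-12)
        assert adj[1] == pytest.approx(5.841e-3, rel=1e-12)
        assert adj[0] == pytest.approx(1.38e-3, abs=5.1e-6)
        assert adj[1] == pytest.approx(5.8e-3, abs=5e-5)

    def test_capped_at_one(self):
        assert adjust_pvalues([0.5], m=11) == [1.0]

    def test_family_smaller_than_collection_fatal(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 0.2, 0.3], m=2)


class TestRunAllMethods:
    def test_homogeneous_fixture_has_no_random_effects_row(self):
        truth = SimulationTruth(theta=0.3, k=8, seed=31)
        h = simulate_harmonized(truth, add_noise=False)
        analysis = run_all_methods(h, MRConfig(n_exposure=20_000,
                                               n_outcome=77_257))
        methods = {r.method for r in analysis.results}
        assert "ivw_random" not in methods
        assert {"ivw_fixed", "weighted_median", "egger"} <= methods

    def test_heterogeneous_fixture_adds_random_effects(self):
        h = make_harmonized([1.0, 1.2, 0.8, 1.1], [0.01] * 4,
                            [0.1, 0.9, -0.4, 1.4], [0.1] * 4)
        analysis = run_all_methods(h)
        assert analysis.sensitivity.q_ivw_pval < 0.05
        assert "ivw_random" in {r.method for r in analysis.results}

    def test_single_snp_skips_are_logged_not_silent(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        analysis = run_all_methods(h)
        assert {r.method for r in analysis.results} == {"wald", "ivw_fixed"}
        assert "weighted_median" in analysis.skipped
        assert "egger" in analysis.skipped
        assert "leave_one_out" in analysis.skipped

    def test_composes_from_constituents(self):
        truth = SimulationTruth(theta=0.25, k=9, seed=33)
        h = simulate_harmonized(truth)
        cfg = MRConfig(seed=7, n_exposure=20_000, n_outcome=77_257, m_tests=11)
        analysis = run_all_methods(h, cfg)
        by_method = {r.method: r for r in analysis.results}
        assert by_method["ivw_fixed"].beta == ivw_fixed(h).beta
        wm = weighted_median(h, n_boot=cfg.n_boot, seed=cfg.seed)
        assert by_method["weighted_median"].se == wm.se
        egger_res, egger_int = mr_egger(h)
        assert by_method["egger"].beta == egger_res.beta
        assert analysis.sensitivity.egger_intercept == egger_int.intercept
        q, df, p = cochran_q(h, "ivw")
        assert analysis.sensitivity.q_ivw == q
        s = steiger(h, 20_000, 77_257)
        assert analysis.sensitivity.steiger_pval == s[3]
        for r in analysis.results:
            assert r.pval_adjusted == min(1.0, r.pval * 11)

    def test_zero_snps_refused(self):
        with pytest.raises(ValueError):
            run_all_methods([])
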