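import dataclasses
import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediation.harmonization import orient_positive_exposure
from mrmediation.uvmr import (InsufficientInstrumentsError, MrResult,
                              cochran_q, ivw, mode_estimator, mr_egger,
                              ratio_estimates, weighted_median)
from tests.conftest import make_instrument


def random_instruments(rng, j):
    bx = rng.uniform(0.05, 0.4, j) * rng.choice([-1, 1], j)
    sy = rng.uniform(0.005, 0.05, j)
    by = 0.3 * bx + rng.normal(0, sy)
    return [make_instrument(rsid=f"rs{i}", bx=bx[i], by=by[i], sy=sy[i])
            for i in range(j)]


class TestRatioEstimates:
    def test_arithmetic_and_sign(self, instrument_factory):
        ests, _ = ratio_estimates([
            instrument_factory(bx=0.1, sx=0.01, by=0.05, sy=0.02),
            instrument_factory(rsid="rs2", bx=-0.1, by=0.05, sy=0.02)])
        assert ests[0].beta_ratio == pytest.approx(0.5)
        assert ests[0].se_ratio == pytest.approx(0.2)
        assert ests[1].beta_ratio == pytest.approx(-0.5)
        assert ests[1].se_ratio == pytest.approx(0.2)

    def test_zero_exposure_effect_excluded(self, instrument_factory):
        ests, excluded = ratio_estimates([
            instrument_factory(bx=0.0), instrument_factory(rsid="rs2")])
        assert excluded == ["rs1"] and len(ests) == 1


class TestIvw:
    def test_identical_ratios_give_exact_estimate_and_zero_q(self):
        insts = [make_instrument(rsid=f"rs{i}", bx=0.2, by=0.08, sy=0.05)
                 for i in range(2)]
        res = ivw(insts)
        assert res.estimate == pytest.approx(0.4, abs=1e-14)
        q = cochran_q(insts)
        assert q.q_stat == pytest.approx(0.0, abs=1e-20)
        assert q.q_pval == pytest.approx(1.0)

    def test_matches_statsmodels_wls_through_origin(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            insts = random_instruments(rng, int(rng.integers(3, 21)))
            bx = np.array([h.beta_exposure for h in insts])
            by = np.array([h.beta_outcome for h in insts])
            sy = np.array([h.se_outcome for h in insts])
            fit = sm.WLS(by, bx, weights=sy ** -2).fit()
            res = ivw(insts, re_mode="fixed")
            assert math.isclose(res.estimate, fit.params[0], rel_tol=1e-10)

    def test_equals_weighted_mean_of_ratios(self, five_instruments):
        res = ivw(five_instruments, re_mode="fixed")
        ests, _ = ratio_estimates(five_instruments)
        w = np.array([e.weight for e in ests])
        r = np.array([e.beta_ratio for e in ests])
        assert math.isclose(res.estimate, float(np.sum(w * r) / w.sum()),
                            rel_tol=1e-10)

    def test_between_two_ratios(self):
        insts = [make_instrument(rsid="a", bx=0.2, by=0.02, sy=0.01),
                 make_instrument(rsid="b", bx=0.2, by=0.08, sy=0.01)]
        res = ivw(insts)
        assert 0.1 <= res.estimate <= 0.4

    def test_joint_negation_invariance(self, five_instruments):
        flipped = [dataclasses.replace(h, beta_exposure=-h.beta_exposure,
                                       beta_outcome=-h.beta_outcome)
                   if i == 2 else h for i, h in enumerate(five_instruments)]
        assert math.isclose(ivw(five_instruments).estimate,
                            ivw(flipped).estimate, rel_tol=1e-12)

    def test_random_effects_se_never_below_fixed(self, five_instruments):
        fixed = ivw(five_instruments, re_mode="fixed")
        mre = ivw(five_instruments, re_mode="multiplicative_random")
        assert mre.se >= fixed.se
        assert mre.estimate == fixed.estimate

    def test_insufficient_instruments(self, instrument_factory):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([instrument_factory()])

    def test_ci_and_or_scale_arithmetic(self):
        r = MrResult("ivw", -0.186, 0.05, 0.01, 10)
        assert r.ci_low == pytest.approx(-0.186 - 1.959964 * 0.05)
        orp, lo, hi = r.or_scale
        assert orp == pytest.approx(math.exp(-0.186))
        assert lo == pytest.approx(math.exp(r.ci_low))


class TestEgger:
    def test_exact_interpolation_of_collinear_points(self):
        insts = [make_instrument(rsid=f"rs{i}", bx=bx, by=0.01 + 0.3 * bx,
                                 sy=0.01)
                 for i, bx in enumerate([0.1, 0.2, 0.3])]
        res, sens = mr_egger(insts)
        assert res.estimate == pytest.approx(0.3, abs=1e-12)
        assert sens.egger_intercept == pytest.approx(0.01, abs=1e-12)
        assert sens.q_stat == pytest.approx(0.0, abs=1e-16)

    def test_matches_statsmodels_wls_with_intercept(self):
        rng = np.random.default_rng(7)
        insts = orient_positive_exposure(random_instruments(rng, 15))
        bx = np.array([h.beta_exposure for h in insts])
        by = np.array([h.beta_outcome for h in insts])
        sy = np.array([h.se_outcome for h in insts])
        fit = sm.WLS(by, sm.add_constant(bx), weights=sy ** -2).fit()
        res, sens = mr_egger(insts, re_mode="fixed")
        assert math.isclose(res.estimate, fit.params[1], rel_tol=1e-10)
        assert math.isclose(sens.egger_intercept, fit.params[0], rel_tol=1e-10)

    def test_requires_orientation(self):
        insts = [make_instrument(rsid=f"rs{i}", bx=bx, by=0.3 * bx, sy=0.01)
                 for i, bx in enumerate([-0.1, 0.2, 0.3])]
        with pytest.raises(ValueError, match="orient"):
            mr_egger(insts)
        res, _ = mr_egger(orient_positive_exposure(insts))
        assert math.isfinite(res.estimate)

    def test_balanced_pleiotropy_intercept_near_zero(self):
        rng = np.random.default_rng(3)
        j = 50
        bx = rng.uniform(0.1, 0.4, j)
        sy = np.full(j, 0.01)
        by = 0.3 * bx + rng.normal(0, 0.005, j) + rng.normal(0, sy)
        insts = [make_instrument(rsid=f"rs{i}", bx=bx[i], by=by[i], sy=sy[i])
                 for i in range(j)]
        _, sens = mr_egger(insts)
        assert abs(sens.egger_intercept) < 3 * sens.intercept_se

    def test_zero_exposure_variance_degenerate(self):
        insts = [make_instrument(rsid=f"rs{i}", bx=0.2, by=0.06, sy=0.01)
                 for i in range(3)]
        from mrmediation.uvmr import DegenerateDesignError
        with pytest.raises(DegenerateDesignError):
            mr_egger(insts)


class TestWeightedMedian:
    def test_middle_order_statistic_with_equal_weights(self):
        insts = [make_instrument(rsid=f"rs{i}", bx=1.0, by=r, sy=0.1)
                 for i, r in enumerate([0.1, 0.4, 0.9])]
        res = weighted_median(insts, seed=1)
        assert res.estimate == pytest.approx(0.4, abs=1e-9)

    def test_dominant_weight_limit(self):
        insts = [make_instrument(rsid="big", bx=1.0, by=0.7, sy=0.001)]
        insts += [make_instrument(rsid=f"rs{i}", bx=1.0, by=0.1, sy=10.0)
                  for i in range(4)]
        res = weighted_median(insts, seed=1)
        assert abs(res.estimate - 0.7) < 1e-3

    def test_matches_brute_force_weighted_quantile(self):
        # oracle: ECDF of point masses with half-mass correction, dense scan
        rng = np.random.default_rng(11)
        for _ in range(20):
            j = int(rng.integers(3, 12))
            ratios = np.sort(rng.normal(0.3, 0.5, j))
            ses = rng.uniform(0.05, 0.5, j)
            insts = [make_instrument(rsid=f"rs{i}", bx=1.0, by=ratios[i],
                                     sy=ses[i]) for i in range(j)]
            w = ses ** -2
            w = w / w.sum()
            cum = np.cumsum(w) - w / 2
            if cum[0] >= 0.5:
                expected = ratios[0]
            elif cum[-1] <= 0.5:
                expected = ratios[-1]
            else:
                expected = float(np.interp(0.5, cum, ratios))
            res = weighted_median(insts, seed=0, n_boot=100)
            assert res.estimate == pytest.approx(expected, rel=1e-9)

    def test_four_equal_weight_ratios_interpolate(self):
        ratios = [0.1, 0.2, 0.6, 0.9]
        insts = [make_instrument(rsid=f"rs{i}", bx=1.0, by=r, sy=0.1)
                 for i, r in enumerate(ratios)]
        res = weighted_median(insts, seed=1)
        # centred cumulative weights 0.125, 0.375, 0.625, 0.875
        expected = 0.2 + (0.5 - 0.375) / 0.25 * (0.6 - 0.2)
        assert res.estimate == pytest.approx(expected, abs=1e-9)

    def test_bootstrap_se_reproducible(self, five_instruments):
        a = weighted_median(five_instruments, seed=5)
        b = weighted_median(five_instruments, seed=5)
        assert a.se == b.se

    def test_too_few_instruments(self, instrument_factory):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median([instrument_factory(), instrument_factory(rsid="b")])


class TestModeEstimator:
    def test_degenerate_density_returns_common_ratio(self):
        insts = [make_instrument(rsid=f"rs{i}", bx=0.2, by=0.05, sy=0.01)
                 for i in range(5)]
        res = mode_estimator(insts, seed=1)
        assert res.estimate == pytest.approx(0.25)

    def test_majority_cluster_wins_and_matches_brute_force_kde(self):
        rng = np.random.default_rng(2)
        ratios = np.concatenate([0.2 + rng.normal(0, 0.01, 7),
                                 0.8 + rng.normal(0, 0.01, 3)])
        insts = [make_instrument(rsid=f"rs{i}", bx=1.0, by=r, sy=0.05)
                 for i, r in enumerate(ratios)]
        res = mode_estimator(insts, weighted=False, seed=1)
        assert 0.1 < res.estimate < 0.3
        # dense-grid oracle with the same bandwidth rule
        j = len(ratios)
        sd = ratios.std(ddof=1)
        mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
        h = 0.9 * min(sd, mad) * j ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200_001)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios) / h) ** 2).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        coarse_step = (ratios.max() - ratios.min() + 6 * h) / 511
        assert res.estimate == pytest.approx(oracle, abs=coarse_step)

    def test_weighted_variant_follows_weight(self):
        ratios = [0.2, 0.21, 0.19, 0.8, 0.81, 0.79]
        ses = [10.0] * 3 + [0.01] * 3
        insts = [make_instrument(rsid=f"rs{i}", bx=1.0, by=r, sy=s)
                 for i, (r, s) in enumerate(zip(ratios, ses))]
        res = mode_estimator(insts, weighted=True, seed=1)
        assert 0.7 < res.estimate < 0.9

    def test_too_few_instruments(self, instrument_factory):
        with pytest.raises(InsufficientInstrumentsError):
            mode_estimator([instrument_factory(), instrument_factory(rsid="b")])


class TestCochranQ:
    def test_hand_computed_two_snp_value(self):
        # ratios 0.3, 0.5 with equal ratio-se 0.1: b = 0.4,
        # Q = 100*(0.1)^2 + 100*(0.1)^2 = 2
        insts = [make_instrument(rsid="a", bx=1.0, by=0.3, sy=0.1),
                 make_instrument(rsid="b", bx=1.0, by=0.5, sy=0.1)]
        q = cochran_q(insts)
        assert q.q_stat == pytest.approx(2.0, abs=1e-12)
        assert q.q_df == 1

    def test_permutation_invariance(self, five_instruments):
        a = cochran_q(five_instruments)
        b = cochran_q(five_instruments[::-1])
        assert a.q_stat == pytest.approx(b.q_stat, rel=1e-12)
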