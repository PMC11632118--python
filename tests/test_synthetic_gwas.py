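import numpy as np
import pytest

from mrmediation.gwas_io import records_to_frame, wald_pvalue
from mrmediation.harmonization import harmonize, retained
from mrmediation.instrument_selection import select_instruments
from mrmediation.synthetic_gwas import (Pleiotropy, SimConfig, replace,
                                        scenario_library,
                                        simulate_summary_stats)
from mrmediation.uvmr import ivw


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(J=2), dict(n_x=0), dict(maf_range=(0.0, 0.4)),
        dict(maf_range=(0.3, 0.6)), dict(mean_f=-1.0)])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_unknown_scenario_errors(self):
        with pytest.raises(KeyError):
            scenario_library("nonexistent")

    def test_scenario_definitions(self):
        assert scenario_library("no-mediation").a == 0.0
        assert scenario_library("full-mediation").c_prime == 0.0
        pl = scenario_library("paper-like")
        assert 0.50 <= (pl.a * pl.b) / (pl.c_prime + pl.a * pl.b) <= 0.54

    def test_paper_like_total_matches_headline_magnitude(self):
        pl = scenario_library("paper-like")
        total = pl.c_prime + pl.a * pl.b
        assert total == pytest.approx(np.log(0.830), abs=0.005)


class TestGeneration:
    def test_same_seed_identical_output(self):
        cfg = SimConfig(J=20, J_m=10, seed=42)
        a = simulate_summary_stats(cfg)
        b = simulate_summary_stats(cfg)
        for studies_a, studies_b in zip(a[:3], b[:3]):
            assert studies_a == studies_b
        assert a[3] == b[3]

    def test_different_seeds_differ(self):
        a = simulate_summary_stats(SimConfig(J=20, J_m=10, seed=1))
        b = simulate_summary_stats(SimConfig(J=20, J_m=10, seed=2))
        assert a[0] != b[0]

    def test_truth_identity_proportion_times_total(self):
        _, _, _, truth = simulate_summary_stats(SimConfig(J=5, J_m=3, seed=0))
        assert truth.proportion_true * truth.total == pytest.approx(
            truth.a * truth.b, rel=1e-15)

    def test_generated_pvalues_consistent_with_betas(self):
        exposure, mediator, outcome, _ = simulate_summary_stats(
            SimConfig(J=50, J_m=50, seed=3))
        for records in (exposure, mediator, outcome):
            assert not any(r.pval_inconsistent for r in records)
            r = records[0]
            assert r.pval == pytest.approx(wald_pvalue(r.beta, r.se))

    def test_se_follows_sample_size_and_maf(self):
        exposure, _, _, _ = simulate_summary_stats(
            SimConfig(J=10, J_m=0, n_x=100_000, seed=4))
        for r in exposure:
            # eaf is observed with small noise; reconstructed se must agree
            # with the analytic form at the true maf to a few percent
            implied_maf_se = 1.0 / np.sqrt(2 * r.eaf * (1 - r.eaf) * r.n)
            assert r.se == pytest.approx(implied_maf_se, rel=0.1)

    def test_instruments_spaced_beyond_clump_window(self):
        exposure, _, _, _ = simulate_summary_stats(SimConfig(J=60, J_m=60, seed=5))
        df = records_to_frame(exposure)
        for _, grp in df.groupby("chrom"):
            pos = np.sort(grp["pos"].to_numpy())
            assert (np.diff(pos) >= 10_000_000).all()

    def test_empirical_beta_noise_matches_analytic_se(self):
        # same SNP panel re-noised across replicates: sd of observed betas
        # about the truth must match the analytic SE within 5%
        base = SimConfig(J=30, J_m=0, seed=0)
        zs = []
        for s in range(1000):
            exposure, _, _, truth = simulate_summary_stats(replace(base, seed=s))
            betas = np.array([r.beta for r in exposure])
            se = np.array([r.se for r in exposure])
            zs.append((betas - np.array(truth.gamma)) / se)
        z = np.concatenate(zs)  # MAFs and gammas vary by seed: standardized
        assert np.std(z) == pytest.approx(1.0, abs=0.05)


class TestNoiselessLimit:
    def test_ivw_recovers_total_effect_as_noise_vanishes(self):
        # scaling every n by 1e6 while holding the instrument effect sizes
        # fixed (mean_f scales with n) shrinks all sampling noise 1000-fold
        cfg = scenario_library("paper-like", seed=6, J=80, J_m=0,
                               n_x=360_000_000_000, n_m=170_000_000_000,
                               n_y=200_000_000_000, mean_f=300.0 * 1e6,
                               palindromic_fraction=0.0,
                               strand_flip_fraction=0.0, eaf_noise_sd=0.0)
        exposure, _, outcome, truth = simulate_summary_stats(cfg)
        out_by = {r.rsid: r for r in outcome}
        hx, _ = harmonize(exposure, [out_by[r.rsid] for r in exposure])
        res = ivw(hx)
        assert abs(res.estimate - truth.total) < 1e-3


class TestHarmonizationStress:
    def test_scrambled_strands_give_same_results_as_clean(self):
        base = scenario_library("paper-like", seed=7, J=80, J_m=0)
        clean_cfg = replace(base, palindromic_fraction=0.0,
                            strand_flip_fraction=0.0)
        noisy_cfg = replace(base, palindromic_fraction=0.0,
                            strand_flip_fraction=0.5)
        def total_estimate(cfg):
            exposure, _, outcome, _ = simulate_summary_stats(cfg)
            iv, _ = select_instruments(exposure)
            out_by = {r.rsid: r for r in outcome}
            hx, _ = harmonize(iv, [out_by[r.rsid] for r in iv])
            return {h.rsid: h.beta_outcome for h in retained(hx)}
        clean = total_estimate(clean_cfg)
        noisy = total_estimate(noisy_cfg)
        assert set(clean) == set(noisy)
        for rsid in clean:
            assert clean[rsid] == pytest.approx(noisy[rsid], abs=1e-12)

    def test_ambiguous_palindromes_dropped_not_misaligned(self):
        cfg = scenario_library("paper-like", seed=8, J=100, J_m=0,
                               palindromic_fraction=0.5,
                               maf_range=(0.40, 0.50))
        exposure, _, outcome, _ = simulate_summary_stats(cfg)
        out_by = {r.rsid: r for r in outcome}
        hx, report = harmonize(exposure, [out_by[r.rsid] for r in exposure])
        assert report.drop_reasons["palindromic-ambiguous"] > 0
        for h in retained(hx):
            assert h.beta_outcome is not None


class TestPleiotropy:
    def test_directional_shifts_outcome_betas(self):
        cfg = SimConfig(J=200, J_m=0, a=0.0, b=0.0, c_prime=0.0,
                        pleiotropy=Pleiotropy("directional", 0.05, 0.001),
                        seed=9)
        exposure, _, outcome, truth = simulate_summary_stats(cfg)
        assert np.mean(truth.delta) == pytest.approx(0.05, abs=0.001)
        # reported alleles are scrambled by design, and the pleiotropic
        # shift is defined on the exposure-raising allele: align, then
        # orient by the sign of the true instrument effect
        out_by = {r.rsid: r for r in outcome}
        hx, _ = harmonize(exposure, [out_by[r.rsid] for r in exposure])
        sign = {r.rsid: (1.0 if g >= 0 else -1.0)
                for r, g in zip(exposure, truth.gamma)}
        oriented = [h.beta_outcome * sign[h.rsid] for h in retained(hx)]
        assert np.mean(oriented) == pytest.approx(0.05, abs=0.01)

    def test_balanced_has_zero_mean_direct_effects(self):
        cfg = SimConfig(J=500, J_m=0,
                        pleiotropy=Pleiotropy("balanced", sd=0.05), seed=10)
        _, _, _, truth = simulate_summary_stats(cfg)
        assert abs(np.mean(truth.delta)) < 0.01
        assert np.std(truth.delta) == pytest.approx(0.05, rel=0.15)
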