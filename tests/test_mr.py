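"""Instrument selection, harmonization and the MR estimator battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitocausal.containers import ValidationError
from mitocausal.mr import (
    MRConfig,
    cochran_q,
    clump,
    egger,
    f_statistic,
    harmonize,
    ivw,
    mode_estimators,
    presso,
    run_mr,
    select_instruments,
    wald_ratios,
    weighted_median,
    adjust_exposures,
)
from mitocausal.synth import MRSimConfig, gen_two_sample_gwas

from conftest import make_harmonized, make_sumstats


def quick_ivw(seed, cfg_kwargs):
    """Generate a pair, select instruments, harmonize, IVW."""
    exp, out, _ = gen_two_sample_gwas(MRSimConfig(seed=seed, **cfg_kwargs))
    inst = select_instruments(exp)
    h = harmonize(inst.df, out)
    return ivw(h)


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.03, 0.01) == pytest.approx(9.0)
        assert f_statistic(0.0, 0.5) == 0.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            f_statistic(0.1, 0.0)


class TestClump:
    def test_correlated_neighbours_pruned_by_pvalue(self):
        df = make_sumstats([0.2, 0.2], [0.01, 0.01],
                           pvals=[1e-10, 1e-9], positions=[1000, 2000])
        ld = {("rs1", "rs2"): 0.5}
        out = clump(df, ld)
        assert list(out["SNP"]) == ["rs1"]

    def test_outside_window_both_kept(self):
        df = make_sumstats([0.2, 0.2], [0.01, 0.01],
                           pvals=[1e-10, 1e-9],
                           positions=[1000, 1000 + 15_000 * 1000])
        out = clump(df, {("rs1", "rs2"): 0.99})
        assert set(out["SNP"]) == {"rs1", "rs2"}

    def test_missing_ld_assumed_independent_and_logged(self):
        df = make_sumstats([0.2, 0.2], [0.01, 0.01],
                           pvals=[1e-10, 1e-9], positions=[1000, 2000])
        log = []
        out = clump(df, ld=None, log=log)
        assert set(out["SNP"]) == {"rs1", "rs2"}
        assert any("assumed independent" in entry[2] for entry in log)


class TestSelectInstruments:
    def test_hand_traced_toy_table(self):
        # p: 1e-10, 1e-9, 1e-7, 1e-12, 1e-8; rs4(1e-12) clumps rs1(1e-10)
        df = make_sumstats([0.2] * 5, [0.01] * 5,
                           pvals=[1e-10, 1e-9, 1e-7, 1e-12, 1e-8],
                           positions=[1000, 2000, 3000, 4000, 5000])
        ld = {("rs4", "rs1"): 0.9}
        inst = select_instruments(df, ld)
        assert set(inst.df["SNP"]) == {"rs4", "rs2"}
        stages = dict(zip(inst.log["SNP"], inst.log["stage"]))
        assert stages["rs3"] == "p_filter" and stages["rs5"] == "p_filter"

    def test_boundary_pvalue_excluded(self):
        df = make_sumstats([0.2, 0.2], [0.01, 0.01], pvals=[1e-7, 1e-9])
        inst = select_instruments(df)
        assert list(inst.df["SNP"]) == ["rs2"]

    def test_all_weak_instruments_is_error(self):
        df = make_sumstats([0.01, 0.01], [0.01, 0.01], pvals=[1e-10, 1e-10])
        with pytest.raises(ValidationError, match="no valid instruments"):
            select_instruments(df)


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = make_sumstats([0.1], [0.01], eas=["A"], oas=["G"])
        out = make_sumstats([-0.05], [0.01], eas=["G"], oas=["A"])
        h = harmonize(exp, out)
        assert h.df["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_palindromic_at_half_frequency_dropped(self):
        exp = make_sumstats([0.1], [0.01], eas=["A"], oas=["T"], eafs=[0.5])
        out = make_sumstats([0.1], [0.01], eas=["A"], oas=["T"], eafs=[0.5])
        h = harmonize(exp, out)
        assert h.n_snps == 0
        assert h.drop_log["reason"].iloc[0] == "palindromic ambiguous"

    def test_palindromic_corrected_by_frequency(self):
        exp = make_sumstats([0.1], [0.01], eas=["A"], oas=["T"], eafs=[0.2])
        # outcome reports the same variant from the other strand: eaf 0.8
        out = make_sumstats([0.3], [0.01], eas=["A"], oas=["T"], eafs=[0.8])
        h = harmonize(exp, out)
        assert h.df["beta_out"].iloc[0] == pytest.approx(-0.3)
        assert h.df["EAF_out"].iloc[0] == pytest.approx(0.2)

    def test_drop_all_policy_removes_palindromes(self):
        exp = make_sumstats([0.1], [0.01], eas=["C"], oas=["G"], eafs=[0.2])
        out = make_sumstats([0.1], [0.01], eas=["C"], oas=["G"], eafs=[0.2])
        h = harmonize(exp, out, palindromic_policy="drop_all")
        assert h.n_snps == 0

    def test_incompatible_alleles_dropped_with_reason(self):
        exp = make_sumstats([0.1], [0.01], eas=["A"], oas=["G"])
        out = make_sumstats([0.1], [0.01], eas=["A"], oas=["C"])
        h = harmonize(exp, out)
        assert h.n_snps == 0
        assert h.drop_log["reason"].iloc[0] == "allele mismatch"

    def test_strand_complement_aligned(self):
        exp = make_sumstats([0.1], [0.01], eas=["A"], oas=["G"])
        out = make_sumstats([0.07], [0.01], eas=["T"], oas=["C"])
        h = harmonize(exp, out)
        assert h.df["beta_out"].iloc[0] == pytest.approx(0.07)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_involution_under_outcome_reorientation(self, seed):
        """Flipping the outcome's alleles, beta sign and EAF leaves the
        harmonized pair unchanged."""
        exp, out, _ = gen_two_sample_gwas(MRSimConfig(n_snps=8, seed=seed))
        flipped = out.copy()
        flipped[["EA", "OA"]] = flipped[["OA", "EA"]].to_numpy()
        flipped["BETA"] = -flipped["BETA"]
        flipped["EAF"] = 1.0 - flipped["EAF"]
        a = harmonize(exp, out)
        b = harmonize(exp, flipped)
        pd.testing.assert_frame_equal(a.df, b.df)


class TestWaldRatios:
    def test_ratio_and_delta_se(self):
        h = make_harmonized([0.2], [0.01], [0.02], [0.01])
        r = wald_ratios(h)
        assert r["ratio"].iloc[0] == pytest.approx(0.1)
        assert r["se"].iloc[0] == pytest.approx(0.05)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        h = make_harmonized([0.2], [0.01], [0.0], [0.01])
        assert wald_ratios(h)["ratio"].iloc[0] == 0.0

    def test_zero_exposure_beta_excluded_and_logged(self):
        h = make_harmonized([0.0, 0.2], [0.01, 0.01], [0.1, 0.02], [0.01, 0.01])
        r = wald_ratios(h)
        assert len(r) == 1 and r.attrs["excluded"] == ["rs1"]


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.2], [0.01], [0.02], [0.01])
        e = ivw(h)
        assert e["method"] == "Wald ratio"
        assert e["beta"] == pytest.approx(0.1)

    def test_symmetric_two_snp_average(self):
        h = make_harmonized([0.2, 0.2], [0.01, 0.01], [0.02, 0.06], [0.01, 0.01])
        assert ivw(h)["beta"] == pytest.approx(0.2, abs=1e-12)

    def test_matches_weighted_regression_oracle(self, rng):
        import statsmodels.api as sm
        bx = rng.normal(0.1, 0.03, 20)
        by = 0.07 * bx + rng.normal(0, 0.01, 20)
        se = rng.uniform(0.005, 0.02, 20)
        h = make_harmonized(bx, np.full(20, 0.005), by, se)
        fit = sm.WLS(by, bx, weights=1 / se**2).fit()
        assert ivw(h)["beta"] == pytest.approx(fit.params[0], abs=1e-10)

    def test_recovers_theta_in_simulation(self):
        ests = [quick_ivw(s, dict(theta=0.05))["beta"] for s in range(200)]
        assert np.mean(ests) == pytest.approx(0.05, abs=0.005)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.5, 4.0), st.integers(0, 1000))
    def test_scale_equivariance(self, c, seed):
        r = np.random.default_rng(seed)
        bx = r.normal(0.1, 0.02, 10)
        by = r.normal(0.01, 0.005, 10)
        h1 = make_harmonized(bx, np.full(10, 0.005), by, np.full(10, 0.005))
        h2 = make_harmonized(c * bx, np.full(10, 0.005 * c), by, np.full(10, 0.005))
        assert ivw(h2)["beta"] == pytest.approx(ivw(h1)["beta"] / c, rel=1e-9)


class TestEgger:
    def test_intercept_calibrated_without_pleiotropy(self):
        rejections = 0
        reps = 100
        for s in range(reps):
            exp, out, _ = gen_two_sample_gwas(MRSimConfig(
                n_snps=50, theta=0.05, seed=s))
            h = harmonize(select_instruments(exp).df, out)
            _, intercept = egger(h)
            rejections += intercept["p"] < 0.05
        assert rejections / reps <= 0.12

    def test_directional_pleiotropy_estimated(self):
        ints, slopes = [], []
        for s in range(60):
            exp, out, _ = gen_two_sample_gwas(MRSimConfig(
                n_snps=50, theta=0.05, frac_invalid=1.0,
                pleiotropy_mean=0.05, pleiotropy_sd=0.0, seed=s))
            h = harmonize(select_instruments(exp).df, out)
            slope, intercept = egger(h)
            ints.append(intercept["beta"])
            slopes.append(slope["beta"])
        assert np.mean(ints) == pytest.approx(0.05, rel=0.2)
        assert np.mean(slopes) == pytest.approx(0.05, abs=0.02)

    def test_too_few_snps_rejected(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.01, 0.02], [0.01] * 2)
        with pytest.raises(ValidationError):
            egger(h)


class TestWeightedMedian:
    def test_identical_ratios(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                            [0.02, 0.04, 0.08], [0.01] * 3)
        assert weighted_median(h, n_boot=50)["beta"] == pytest.approx(0.2)

    def test_majority_weight_wins(self, rng):
        # ~60% of weight near ratio 0.2, 40% near 1.0
        bx = np.full(10, 0.2)
        by = np.concatenate([np.full(6, 0.04), np.full(4, 0.2)])
        by = by + rng.normal(0, 0.002, 10)
        h = make_harmonized(bx, np.full(10, 0.005), by, np.full(10, 0.01))
        est = weighted_median(h, n_boot=200, seed=1)
        assert est["beta"] == pytest.approx(0.2, abs=0.05)

    def test_equal_weights_is_plain_median(self):
        h = make_harmonized([0.1] * 3, [0.01] * 3,
                            [0.01, 0.02, 0.03], [0.01] * 3)
        assert weighted_median(h, n_boot=50)["beta"] == pytest.approx(0.2)


class TestModeEstimators:
    def test_identical_ratios_return_constant(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                            [0.03, 0.06, 0.12], [0.01] * 3)
        simple, weighted = mode_estimators(h, n_boot=50)
        assert simple["beta"] == pytest.approx(0.3)
        assert weighted["beta"] == pytest.approx(0.3)

    def test_plurality_cluster_wins(self, rng):
        bx = np.full(20, 0.2)
        by = np.concatenate([np.full(14, 0.02),
                             rng.uniform(0.1, 0.3, 6)])
        by = by + rng.normal(0, 0.001, 20)
        h = make_harmonized(bx, np.full(20, 0.005), by, np.full(20, 0.005))
        simple, _ = mode_estimators(h, n_boot=50, seed=2)
        assert simple["beta"] == pytest.approx(0.1, abs=0.03)

    def test_weighted_equals_simple_under_equal_weights(self):
        h = make_harmonized([0.1] * 5, [0.01] * 5,
                            [0.01, 0.015, 0.02, 0.025, 0.03], [0.01] * 5)
        simple, weighted = mode_estimators(h, n_boot=50)
        assert simple["beta"] == pytest.approx(weighted["beta"], abs=1e-9)


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01] * 2)
        q, df, p = cochran_q(h, 0.2)
        assert q == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_calibrated_under_valid_instruments(self):
        ratios = []
        for s in range(50):
            exp, out, _ = gen_two_sample_gwas(MRSimConfig(theta=0.05, seed=s))
            h = harmonize(select_instruments(exp).df, out)
            theta = ivw(h)["beta"]
            q, df, _ = cochran_q(h, theta)
            ratios.append(q / df)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_gross_outlier_detected(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            bx = np.full(20, 0.2)
            by = 0.1 * bx + r.normal(0, 0.002, 20)
            by[0] += 10 * 0.002 / 0.2 * 0.2  # +10 ratio-SD excursion
            h = make_harmonized(bx, np.full(20, 0.005), by, np.full(20, 0.002))
            theta = ivw(h)["beta"]
            _, _, p = cochran_q(h, theta)
            hits += p < 0.001
        assert hits >= 19


class TestPresso:
    def test_global_test_calibrated(self):
        rejections = 0
        reps = 30
        for s in range(reps):
            exp, out, _ = gen_two_sample_gwas(MRSimConfig(
                n_snps=20, theta=0.05, seed=s))
            h = harmonize(select_instruments(exp).df, out)
            res = presso(h, n_sim=300, seed=s)
            rejections += res["global_p"] <= 0.05
        assert rejections / reps <= 0.15

    def test_injected_outlier_flagged_and_corrected(self):
        flagged = 0
        improved = 0
        reps = 10
        for s in range(reps):
            exp, out, _ = gen_two_sample_gwas(MRSimConfig(
                n_snps=20, theta=0.05, seed=100 + s))
            out = out.copy()
            out.loc[0, "BETA"] += 0.15  # one grossly pleiotropic SNP
            h = harmonize(select_instruments(exp).df, out)
            res = presso(h, n_sim=500, seed=s)
            uncorrected = ivw(h)["beta"]
            flagged += "rs00001" in res["outliers"]
            if res["corrected_ivw"]:
                improved += (abs(res["corrected_ivw"]["beta"] - 0.05)
                             < abs(uncorrected - 0.05))
        assert flagged >= 9
        assert improved >= 8

    def test_too_few_snps_rejected(self):
        h = make_harmonized([0.1] * 3, [0.01] * 3, [0.01] * 3, [0.01] * 3)
        with pytest.raises(ValidationError):
            presso(h)


class TestRunMR:
    def test_odds_ratio_format(self):
        from mitocausal.mr import _or_ci
        orr, lo, hi = _or_ci(0.04, 0.02)
        assert round(orr, 3) == 1.041
        assert round(lo, 3) == 1.001
        assert round(hi, 3) == 1.082

    def test_full_battery_on_simulated_pair(self):
        exp, out, _ = gen_two_sample_gwas(MRSimConfig(theta=0.1, seed=42))
        res = run_mr(exp, out, config=MRConfig(n_boot=100, presso_sims=200))
        methods = set(res.estimates["method"])
        assert {"IVW", "Egger", "Egger intercept", "Weighted median",
                "Simple mode", "Weighted mode"} <= methods
        assert res.estimate("IVW")["beta"] == pytest.approx(0.1, abs=0.03)
        assert res.q_df == res.harmonized.n_snps - 1

    def test_estimators_agree_on_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, np.full(4, 0.01), 0.25 * bx, np.full(4, 0.01))
        assert ivw(h, random_effects=False)["beta"] == pytest.approx(0.25)
        slope, intercept = egger(h)
        assert slope["beta"] == pytest.approx(0.25, abs=1e-9)
        assert intercept["beta"] == pytest.approx(0.0, abs=1e-9)
        assert weighted_median(h, n_boot=50)["beta"] == pytest.approx(0.25)
        s, w = mode_estimators(h, n_boot=50)
        assert s["beta"] == pytest.approx(0.25)

    def test_bh_adjustment_across_exposures(self):
        p = pd.Series([0.001, 0.02, 0.8], index=["g1", "g2", "g3"])
        adj = adjust_exposures(p)
        assert adj.loc["g1", "significant"]
        assert not adj.loc["g3", "significant"]
        bonf = adjust_exposures(p, method="bonferroni")
        assert bonf.loc["g1", "p_adj"] == pytest.approx(0.003)
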