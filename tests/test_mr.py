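"""Harmonization, instrument strength, Steiger, and the MR estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aortapipe.mr import (
    HarmonizedInstrumentSet,
    MRResult,
    classify_significance,
    harmonize,
    instrument_strength,
    ivw_re,
    mr_egger,
    mr_report,
    rucker_select,
    steiger_filter,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from aortapipe.synth import MRSimConfig, generate_mr_summary_stats


def sumstat_row(snp, ea, oa, eaf, beta, se=0.01, n=30000):
    return {"SNP": snp, "CHR": 1, "BP": 1, "EA": ea, "OA": oa,
            "EAF": eaf, "BETA": beta, "SE": se, "P": 1e-9, "N": n}


def make_tables(rows_exp, rows_out):
    return pd.DataFrame(rows_exp), pd.DataFrame(rows_out)


def iset_from_arrays(bx, by, sy=None, sx=None, eaf=0.3):
    k = len(bx)
    table = pd.DataFrame(
        {
            "SNP": [f"v{i}" for i in range(k)],
            "beta_exposure": bx,
            "se_exposure": sx if sx is not None else np.full(k, 0.01),
            "beta_outcome": by,
            "se_outcome": sy if sy is not None else np.full(k, 0.01),
            "eaf": np.full(k, eaf),
            "n_exposure": 30_000,
            "n_outcome": 100_000,
            "palindromic_removed": False,
            "flipped": False,
        }
    )
    return HarmonizedInstrumentSet(table)


class TestHarmonize:
    def test_palindromic_high_maf_removed(self):
        exp, out = make_tables(
            [sumstat_row("rs1", "A", "T", 0.45, 0.1)],
            [sumstat_row("rs1", "A", "T", 0.45, 0.05)],
        )
        h = harmonize(exp, out)
        assert bool(h.table["palindromic_removed"].iloc[0])
        assert h.k == 0

    def test_palindromic_low_maf_aligned_by_frequency(self):
        exp, out = make_tables(
            [sumstat_row("rs1", "A", "T", 0.10, 0.1)],
            [sumstat_row("rs1", "A", "T", 0.11, 0.05)],
        )
        h = harmonize(exp, out)
        row = h.table.iloc[0]
        assert not row["palindromic_removed"] and not row["flipped"]
        assert row["beta_outcome"] == pytest.approx(0.05)

    def test_palindromic_discordant_frequency_flipped(self):
        exp, out = make_tables(
            [sumstat_row("rs1", "A", "T", 0.10, 0.1)],
            [sumstat_row("rs1", "A", "T", 0.90, 0.05)],
        )
        row = harmonize(exp, out).table.iloc[0]
        assert row["flipped"] and row["beta_outcome"] == pytest.approx(-0.05)

    def test_swapped_alleles_flip_outcome_beta(self):
        exp, out = make_tables(
            [sumstat_row("rs1", "A", "G", 0.3, 0.1)],
            [sumstat_row("rs1", "G", "A", 0.7, 0.05)],
        )
        row = harmonize(exp, out).table.iloc[0]
        assert row["flipped"] and row["beta_outcome"] == pytest.approx(-0.05)

    def test_strand_complement_recognised(self):
        exp, out = make_tables(
            [sumstat_row("rs1", "A", "G", 0.3, 0.1)],
            [sumstat_row("rs1", "T", "C", 0.3, 0.05)],  # same variant, other strand
        )
        row = harmonize(exp, out).table.iloc[0]
        assert not row["flipped"] and row["beta_outcome"] == pytest.approx(0.05)

    def test_simulated_flips_are_undone(self):
        cfg = MRSimConfig(theta=0.3, k_instruments=50, outcome_allele_flip_fraction=0.7,
                          palindromic_fraction=0.0, seed=4)
        exp, out = generate_mr_summary_stats(cfg)
        h = harmonize(exp, out)
        merged = h.table.set_index("SNP")
        # undoing the reporting flips must recover a positive ratio slope
        est = ivw_re(h).estimate
        assert est == pytest.approx(0.3, abs=0.05)
        assert merged["flipped"].sum() > 10


class TestInstrumentStrength:
    def test_f_statistic_formula(self):
        # R² = 0.5 at n = 4 -> F = 2; R² = 0.001 at n = 31908 -> F ≈ 31.94
        t = iset_from_arrays([1.0], [0.0], eaf=0.5)
        t.table["n_exposure"] = 4
        t.table["beta_exposure"] = 1.0  # R2 = 2*0.25*1 = 0.5
        s = instrument_strength(t)
        assert s.table["f_stat"].iloc[0] == pytest.approx(0.5 * 2 / 0.5)
        t2 = iset_from_arrays([np.sqrt(0.001 / 0.5)], [0.0], eaf=0.5)
        t2.table["n_exposure"] = 31_908
        s2 = instrument_strength(t2)
        assert s2.table["f_stat"].iloc[0] == pytest.approx(0.001 * 31_906 / 0.999, rel=1e-9)
        assert s2.table["f_stat"].iloc[0] == pytest.approx(31.94, abs=0.01)

    def test_zero_effect_gives_zero_f(self):
        s = instrument_strength(iset_from_arrays([0.0], [0.1]))
        assert s.table["f_stat"].iloc[0] == 0.0
        assert bool(s.table["weak"].iloc[0])

    def test_binary_outcome_r2_bounded(self):
        s = instrument_strength(iset_from_arrays([0.1, 0.2], [5.0, 50.0]), outcome_binary=True)
        assert (s.table["r2_outcome"] < 1).all()

    def test_small_sample_rejected(self):
        t = iset_from_arrays([0.1], [0.1])
        t.table["n_exposure"] = 2
        with pytest.raises(ValueError):
            instrument_strength(t)


class TestSteiger:
    def _strength(self, bx, by, n_out=100_000, binary=False):
        s = iset_from_arrays(bx, by)
        s.table["n_outcome"] = n_out
        return instrument_strength(s, outcome_binary=binary)

    def test_zero_outcome_r2_removes_nothing(self):
        s = steiger_filter(self._strength([0.1, 0.2], [0.0, 0.0]))
        assert not s.table["steiger_removed"].any()

    def test_outcome_dominant_variant_removed(self):
        s = steiger_filter(self._strength([0.05], [0.5]))
        assert bool(s.table["steiger_removed"].iloc[0])

    def test_small_samples_lack_power(self):
        s = iset_from_arrays([0.050], [0.055])
        s.table["n_exposure"] = 50
        s.table["n_outcome"] = 50
        s = steiger_filter(instrument_strength(s))
        assert not bool(s.table["steiger_removed"].iloc[0])

    def test_requires_strength_first(self):
        with pytest.raises(ValueError):
            steiger_filter(iset_from_arrays([0.1], [0.1]))


class TestWaldRatio:
    def test_point_estimate(self):
        est, se = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01)[0] == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


class TestIVW:
    def test_single_variant_equals_wald_ratio(self):
        s = iset_from_arrays([0.1], [0.05], sy=[0.02])
        res = ivw_re(s)
        est, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert res.estimate == pytest.approx(est)
        assert res.se == pytest.approx(se)

    def test_exact_weighted_least_squares(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = ivw_re(iset_from_arrays(bx, 0.5 * bx))
        assert res.estimate == pytest.approx(0.5, rel=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-20)

    def test_matches_manual_wls_oracle(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.2, 10)
        by = 0.4 * bx + rng.normal(0, 0.01, 10)
        sy = rng.uniform(0.005, 0.02, 10)
        res = ivw_re(iset_from_arrays(bx, by, sy=sy))
        w = 1 / sy**2
        beta = np.sum(w * bx * by) / np.sum(w * bx**2)
        q = np.sum(w * (by - beta * bx) ** 2)
        se = np.sqrt(1 / np.sum(w * bx**2)) * max(1.0, np.sqrt(q / 9))
        assert res.estimate == pytest.approx(beta, rel=1e-12)
        assert res.se == pytest.approx(se, rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.2, 12)
        by = 0.4 * bx + rng.normal(0, 0.02, 12)
        s = iset_from_arrays(bx, by)
        perm = rng.permutation(12)
        s2 = iset_from_arrays(bx[perm], by[perm])
        assert ivw_re(s).estimate == pytest.approx(ivw_re(s2).estimate, rel=1e-12)
        assert ivw_re(s).q == pytest.approx(ivw_re(s2).q, rel=1e-12)

    def test_i2_within_bounds_and_ci_contains_estimate(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = rng.integers(2, 15)
            bx = rng.uniform(0.05, 0.3, k)
            by = 0.2 * bx + rng.normal(0, 0.05, k)
            res = ivw_re(iset_from_arrays(bx, by))
            assert 0.0 <= res.i2 < 1.0
            assert res.ci_low <= res.estimate <= res.ci_high


class TestEgger:
    def test_exact_line_with_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.02 + 0.5 * bx
        res = mr_egger(iset_from_arrays(bx, by))
        assert res.estimate == pytest.approx(0.5, rel=1e-9)
        assert res.intercept == pytest.approx(0.02, rel=1e-9)
        assert res.q_prime == pytest.approx(0.0, abs=1e-18)

    def test_proportional_effects_give_zero_intercept(self):
        bx = np.array([0.1, 0.15, 0.3])
        res = mr_egger(iset_from_arrays(bx, 0.7 * bx))
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self):
        bx = np.array([0.1, -0.2, 0.3, -0.15])
        by = 0.01 + 0.5 * np.abs(bx)
        by = by * np.sign(bx)
        by = 0.5 * bx + 0.01 * np.sign(bx)
        res1 = mr_egger(iset_from_arrays(bx, by))
        res2 = mr_egger(iset_from_arrays(-bx, -by))
        assert res1.estimate == pytest.approx(res2.estimate, rel=1e-12)
        assert res1.intercept == pytest.approx(res2.intercept, rel=1e-12)

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            mr_egger(iset_from_arrays([0.1, 0.2], [0.05, 0.1]))

    def test_q_dominates_q_prime(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(3, 20))
            bx = rng.uniform(0.05, 0.3, k)
            by = 0.03 + 0.3 * bx + rng.normal(0, 0.03, k)
            s = iset_from_arrays(bx, by)
            assert ivw_re(s).q >= mr_egger(s).q_prime - 1e-12


class TestRucker:
    def _result(self, q=10.0, k=11, intercept_p=0.5):
        return (
            MRResult("IVW-RE", 0.2, 0.05, 0.1, 0.3, 0.01, k, q=q, q_df=k - 1),
            MRResult("MR-Egger", 0.1, 0.1, -0.1, 0.3, 0.3, k, q_prime=5.0,
                     intercept=0.02, intercept_p=intercept_p),
        )

    def test_defaults_to_ivw(self):
        ivw, egger = self._result(q=8.0, intercept_p=0.8)
        assert rucker_select(ivw, egger) == "IVW-RE"

    def test_switches_only_with_both_conditions(self):
        crit = stats.chi2.ppf(0.95, 1)
        ivw, egger = self._result(q=5.0 + crit + 1.0, intercept_p=0.01)
        assert rucker_select(ivw, egger) == "MR-Egger"
        ivw2, egger2 = self._result(q=5.0 + crit + 1.0, intercept_p=0.5)
        assert rucker_select(ivw2, egger2) == "IVW-RE"
        ivw3, egger3 = self._result(q=5.0 + crit - 0.5, intercept_p=0.01)
        assert rucker_select(ivw3, egger3) == "IVW-RE"


class TestWeightedMedian:
    def test_equal_weights_median(self):
        bx = np.full(3, 0.1)
        by = np.array([0.04, 0.05, 0.06])
        res = weighted_median(iset_from_arrays(bx, by))
        assert res.estimate == pytest.approx(0.5)

    def test_robust_to_single_outlier(self):
        bx = np.full(10, 0.1)
        by = 0.05 * np.ones(10)
        by[0] = 0.5  # wild ratio 5.0 among nine ratios of 0.5
        res = weighted_median(iset_from_arrays(bx, by))
        assert res.estimate == pytest.approx(0.5, abs=0.02)

    def test_weight_concentration_limit(self):
        bx = np.full(4, 0.1)
        by = np.array([0.03, 0.05, 0.07, 0.09])
        sy = np.array([1e-5, 1.0, 1.0, 1.0])
        res = weighted_median(iset_from_arrays(bx, by, sy=sy))
        assert res.estimate == pytest.approx(0.3, abs=0.01)

    def test_bootstrap_se_deterministic_by_seed(self):
        bx = np.linspace(0.1, 0.3, 6)
        by = 0.4 * bx + np.array([0.01, -0.01, 0.0, 0.02, -0.02, 0.0])
        a = weighted_median(iset_from_arrays(bx, by), seed=42)
        b = weighted_median(iset_from_arrays(bx, by), seed=42)
        assert a.se == b.se


class TestWeightedMode:
    def test_identical_ratios(self):
        bx = np.full(5, 0.1)
        res = weighted_mode(iset_from_arrays(bx, 0.06 * np.ones(5) * 0.1 / 0.1 * 1.0))
        assert res.estimate == pytest.approx(0.6, abs=0.01)

    def test_plurality_cluster_wins(self):
        bx = np.full(10, 0.1)
        by = np.where(np.arange(10) < 7, 0.05, 0.15)
        res = weighted_mode(iset_from_arrays(bx, by))
        assert res.estimate == pytest.approx(0.5, abs=0.1)

    def test_infinite_bandwidth_approaches_weighted_mean(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.1, 0.3, 8)
        by = 0.4 * bx + rng.normal(0, 0.02, 8)
        sy = np.full(8, 0.01)
        res = weighted_mode(iset_from_arrays(bx, by, sy=sy), bandwidth_factor=50.0)
        ratios = by / bx
        w = (bx / sy) ** 2
        assert res.estimate == pytest.approx(np.average(ratios, weights=w), abs=0.02)


class TestReporting:
    @pytest.mark.parametrize("p, tier", [(0.003, "significant"), (0.03, "suggestive"), (0.2, "null")])
    def test_bonferroni_tiers(self, p, tier):
        assert classify_significance(p, n_outcomes=10) == tier

    def test_threshold_is_five_millis(self):
        assert classify_significance(0.0049) == "significant"
        assert classify_significance(0.0051) == "suggestive"

    def test_report_table_shape_and_selection(self):
        bx = np.linspace(0.1, 0.4, 8)
        by = 0.5 * bx
        s = iset_from_arrays(bx, by)
        methods = {"IVW-RE": ivw_re(s), "MR-Egger": mr_egger(s),
                   "weighted-median": weighted_median(s)}
        table = mr_report({("aao_max", "aneurysm"): methods})
        assert len(table) == 3
        assert set(table["selected_model"]) == {"IVW-RE"}
        main = table[table["is_main"]]
        assert main["method"].iloc[0] == "IVW-RE"


class TestEndToEndRecovery:
    def test_ivw_recovers_causal_log_odds(self):
        theta = np.log(1.5)
        estimates = []
        for rep in range(30):
            cfg = MRSimConfig(theta=theta, k_instruments=60, pleiotropy_mode="none",
                              seed=900 + rep)
            exp, out = generate_mr_summary_stats(cfg)
            s = steiger_filter(instrument_strength(harmonize(exp, out)))
            estimates.append(ivw_re(s).estimate)
        assert np.mean(estimates) == pytest.approx(theta, abs=0.02)

    def test_steiger_keeps_forward_instruments(self):
        cfg = MRSimConfig(theta=0.2, k_instruments=50, seed=17)
        exp, out = generate_mr_summary_stats(cfg)
        s = steiger_filter(instrument_strength(harmonize(exp, out)))
        assert s.table["steiger_removed"].sum() == 0
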