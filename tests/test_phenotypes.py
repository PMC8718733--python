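"""Phenotype derivation, BSA, inverse normal transform, reference values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aortapipe.features import FrameFeatures
from aortapipe.phenotypes import (
    compute_bsa,
    derive_aao_phenotypes,
    inverse_normal_transform,
    reference_table,
    trait_correlations,
)


def feature(area, diameter=30.0, index=0):
    return FrameFeatures(frame_index=index, area_cm2=area, perimeter_mm=100.0,
                         diameter_mm=diameter, roundness=0.95)


class TestBSA:
    def test_dubois_reference_value(self):
        assert compute_bsa(170.0, 70.0) == pytest.approx(
            0.007184 * 70**0.425 * 170**0.725
        )
        assert compute_bsa(170.0, 70.0) == pytest.approx(1.810, abs=5e-3)

    def test_mosteller_reference_value(self):
        assert compute_bsa(170.0, 70.0, formula="mosteller") == pytest.approx(
            np.sqrt(170 * 70 / 3600), rel=1e-12
        )

    @pytest.mark.parametrize("h, w", [(0.0, 70.0), (170.0, 0.0), (np.nan, 70.0), (170.0, None)])
    def test_missing_inputs_signal_nan(self, h, w):
        assert np.isnan(compute_bsa(h, w))

    def test_unknown_formula_rejected(self):
        with pytest.raises(ValueError):
            compute_bsa(170, 70, formula="boyd")


class TestDerivePhenotypes:
    def test_cohort_mean_worked_example(self):
        # areas spanning 7.2–8.1 cm² at pulse pressure 54.6 mmHg give a
        # distensibility of 2.29, reported as 2.3 in 10⁻³ mmHg⁻¹
        fs = [feature(7.2), feature(7.9), feature(8.1)]
        p = derive_aao_phenotypes(fs, sbp=120.0 + 54.6, dbp=120.0, bsa=1.85)
        expected = (8.1 - 7.2) / (7.2 * 54.6) * 1e3
        assert p.distensibility == pytest.approx(expected)
        assert round(p.distensibility, 1) == 2.3
        assert p.aao_max_cm2 == 8.1 and p.aao_min_cm2 == 7.2

    def test_equal_extremes_give_zero(self):
        p = derive_aao_phenotypes([feature(8.0), feature(8.0)], 130.0, 80.0, 1.9)
        assert p.distensibility == 0.0

    def test_nonpositive_pulse_pressure_marks_missing(self):
        p = derive_aao_phenotypes([feature(7.0), feature(8.0)], 80.0, 80.0, 1.9)
        assert np.isnan(p.distensibility)
        assert "non_positive_pulse_pressure" in p.missing_reasons

    def test_missing_bsa_blocks_indexing_only(self):
        p = derive_aao_phenotypes([feature(7.0), feature(8.0)], 130.0, 80.0, float("nan"))
        assert np.isnan(p.aao_max_idx) and not np.isnan(p.distensibility)
        assert "missing_bsa" in p.missing_reasons

    def test_indexing_identity(self):
        p = derive_aao_phenotypes([feature(7.0), feature(8.0)], 130.0, 80.0, 1.9)
        assert p.aao_max_idx * p.bsa == pytest.approx(p.aao_max_cm2)
        assert p.aao_min_idx * p.bsa == pytest.approx(p.aao_min_cm2)

    def test_distensibility_invariant_to_area_units(self):
        fs_cm2 = [feature(7.0), feature(8.0)]
        fs_mm2 = [feature(700.0), feature(800.0)]
        a = derive_aao_phenotypes(fs_cm2, 130.0, 80.0, 1.9).distensibility
        b = derive_aao_phenotypes(fs_mm2, 130.0, 80.0, 1.9).distensibility
        assert a == pytest.approx(b)

    def test_no_frames_all_missing(self):
        p = derive_aao_phenotypes([], 130.0, 80.0, 1.9)
        assert np.isnan(p.aao_max_cm2)
        assert "no_retained_frames" in p.missing_reasons

    def test_recovery_against_generative_truth(self, clean_study):
        # artefact-free participant: contour-derived distensibility lands
        # within 2% of the analytic generative value
        from aortapipe.qc import analyze_study

        cfg, study, truth = clean_study
        feats = analyze_study(study.images, truth.masks, cfg.pixel_spacing,
                              compute_diameters=False)
        cov = study.covariates
        p = derive_aao_phenotypes(feats, cov["sbp"], cov["dbp"], 1.9)
        assert p.distensibility == pytest.approx(truth.true_distensibility, rel=0.02)


class TestInverseNormalTransform:
    def test_three_point_oracle(self):
        out = inverse_normal_transform([3.0, 1.0, 2.0])
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.5) / 3)
        np.testing.assert_allclose(out, expected)
        np.testing.assert_allclose(out, [0.9674, -0.9674, 0.0], atol=1e-4)

    def test_median_of_odd_input_is_zero(self):
        out = inverse_normal_transform([10.0, 40.0, 20.0, 50.0, 30.0])
        assert out[4] == pytest.approx(0.0)

    def test_large_sample_moments(self):
        rng = np.random.default_rng(1)
        out = inverse_normal_transform(rng.gamma(2.0, size=10_000))
        assert abs(out.mean()) < 1e-8
        assert out.std(ddof=1) == pytest.approx(1.0, abs=0.01)

    def test_ties_get_average_ranks(self):
        out = inverse_normal_transform([1.0, 2.0, 2.0, 3.0])
        assert out[1] == pytest.approx(out[2])

    def test_nan_passthrough(self):
        out = inverse_normal_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_blom_offset_option(self):
        vals = [3.0, 1.0, 2.0]
        out = inverse_normal_transform(vals, offset="blom")
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / (3 + 0.25))
        np.testing.assert_allclose(out, expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([5.0, 5.0, 5.0])


class TestReferenceTable:
    def _phenos(self, ages, values, sex=None):
        return pd.DataFrame({
            "aao_max_cm2": values,
            "age": ages,
            "sex": sex if sex is not None else np.zeros(len(ages), dtype=int),
        })

    def test_single_age_bin_populated(self):
        t = reference_table(self._phenos([60.0] * 8, np.arange(8.0)))
        t_all = t[(t["phenotype"] == "aao_max_cm2") & (t["sex"] == "All")]
        filled = t_all.set_index("age_bin")["n"]
        assert filled["55-65"] == 8
        assert filled[["<55", "65-75", ">75"]].sum() == 0

    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(40, 85, 200)
        t = reference_table(self._phenos(ages, rng.normal(8, 1, 200)))
        t_all = t[(t["phenotype"] == "aao_max_cm2") & (t["sex"] == "All")]
        assert t_all["n"].sum() == 200

    def test_configured_age_trend_is_monotone(self):
        # the generator's age slope on area should appear as monotone
        # increasing bin means of the generative truth
        from aortapipe.synth import CohortConfig, generate_cine_study, generate_covariates

        cfg = CohortConfig(n_participants=250, n_frames=2, image_size=(8, 8), seed=9)
        cov = generate_covariates(cfg)
        truth_min = [generate_cine_study(cfg, pid)[1].true_aao_min_cm2 for pid in cov.index]
        t = reference_table(pd.DataFrame({"aao_min_cm2": truth_min}),
                            age=cov["age"], sex=cov["sex"])
        means = t[(t["phenotype"] == "aao_min_cm2") & (t["sex"] == "All")].set_index("age_bin")["mean"]
        ordered = means[["<55", "55-65", "65-75", ">75"]].to_numpy()
        assert (np.diff(ordered) > 0).all()

    def test_sex_stratification(self):
        rng = np.random.default_rng(4)
        sex = rng.integers(0, 2, 100)
        t = reference_table(self._phenos(np.full(100, 60.0), rng.normal(8, 1, 100), sex=sex))
        men = t[(t["sex"] == "Men") & (t["age_bin"] == "55-65")]["n"].iloc[0]
        women = t[(t["sex"] == "Women") & (t["age_bin"] == "55-65")]["n"].iloc[0]
        assert men + women == 100


class TestTraitCorrelations:
    def test_self_and_anti_correlation(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        t = trait_correlations(df).set_index(["trait_a", "trait_b"])
        assert t.loc[("a", "b"), "r"] == pytest.approx(1.0)
        assert t.loc[("a", "c"), "r"] == pytest.approx(-1.0)

    def test_null_coverage_of_fisher_interval(self):
        rng = np.random.default_rng(8)
        covered = 0
        for _ in range(100):
            df = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
            row = trait_correlations(df).iloc[0]
            covered += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert covered >= 93

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        row = trait_correlations(df).iloc[0]
        assert not row["valid"] and np.isnan(row["r"])


class TestEndToEndRecovery:
    def test_estimated_vs_true_distensibility_slope(self):
        # baseline-segmented cohort: regressing estimated on true
        # distensibility must give a slope near unity (calibration)
        from aortapipe.qc import analyze_study, participant_qc
        from aortapipe.segment import segment_frame_baseline
        from aortapipe.synth import CohortConfig, generate_cine_study, generate_covariates

        cfg = CohortConfig(n_participants=40, n_frames=20, artefact_probability=0.0, seed=31)
        cov = generate_covariates(cfg)
        est, true = [], []
        for pid, c in cov.iterrows():
            study, truth = generate_cine_study(cfg, pid, covariates=c.to_dict())
            masks = np.stack([segment_frame_baseline(f) for f in study.images])
            feats = analyze_study(study.images, masks, cfg.pixel_spacing,
                                  compute_diameters=False)
            rep = participant_qc(feats, c.to_dict())
            retained = [f for f, s in zip(feats, rep.frame_statuses) if s == "pass"]
            p = derive_aao_phenotypes(retained, c["sbp"], c["dbp"], 1.9)
            est.append(p.distensibility)
            true.append(truth.true_distensibility)
        slope = np.polyfit(true, est, 1)[0]
        assert 0.95 <= slope <= 1.05
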