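"""Tests of the curve -> FV -> condition -> patient -> cohort aggregation."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from ecmech import (
    InsufficientDataError,
    ProbeCalibration,
    RampConfig,
    YoungModulusMap,
    compare_conditions,
    condition_summary,
    fit_volume,
    fv_median,
    mc_calibration_error,
    metadata_associations,
    PatientComparison,
)
from ecmech.cohort_stats import _holm, _welch
from ecmech.forcecurve_io import METADATA_COLUMNS
from ecmech.synthetic import CohortSpec, PatientSpec, synthesize_cohort


class TestFvMedian:
    def test_lognormal_median_recovery(self):
        rng = np.random.default_rng(0)
        vals = 5e3 * 10 ** (0.25 * rng.standard_normal(10_000))
        res = fv_median(vals)
        assert res.method == "gaussian_fit"
        assert not res.multimodal
        assert res.value == pytest.approx(5e3, rel=0.03)

    def test_degenerate_identical_values_exact(self):
        res = fv_median(np.full(50, 7e3))
        assert res.value == 7e3
        assert res.method == "sample_median"
        assert not res.multimodal

    def test_bimodal_distribution_flagged(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [
                2e3 * 10 ** (0.05 * rng.standard_normal(5000)),
                2e4 * 10 ** (0.05 * rng.standard_normal(5000)),
            ]
        )
        res = fv_median(vals)
        assert res.multimodal
        assert res.fit_r_squared < 0.9
        assert res.value == pytest.approx(np.median(vals), rel=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            fv_median(np.full(19, 1e3))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        vals = 1e4 * 10 ** (0.2 * rng.standard_normal(2000))
        a = 2.5
        assert fv_median(a * vals).value == pytest.approx(
            a * fv_median(vals).value, rel=1e-6
        )

    def test_nonfinite_and_nonpositive_values_ignored(self):
        rng = np.random.default_rng(3)
        vals = 1e4 * 10 ** (0.2 * rng.standard_normal(500))
        polluted = np.concatenate([vals, [np.nan, np.inf, -5.0, 0.0]])
        assert fv_median(polluted).value == fv_median(vals).value


def _const_map(value, n=25, patient="P", condition="normal", roi="roi0"):
    side = int(math.isqrt(n))
    E = np.full((side, side), float(value))
    return YoungModulusMap(patient=patient, condition=condition, roi=roi, E=E)


class TestConditionSummary:
    def test_mean_and_sem_hand_arithmetic(self):
        maps = [_const_map(v, roi=f"roi{i}") for i, v in enumerate((4e3, 5e3, 6e3))]
        summ = condition_summary(maps)
        assert summ.fv_medians == [4e3, 5e3, 6e3]
        assert summ.mean_median == pytest.approx(5e3)
        assert summ.sem == pytest.approx(1e3 / np.sqrt(3), rel=1e-12)  # 577 Pa
        assert summ.combined_error == pytest.approx(summ.sem)  # mc term absent

    def test_identical_fvs_sem_zero(self):
        maps = [_const_map(5e3, roi=f"roi{i}") for i in range(3)]
        summ = condition_summary(maps, mc_rel_error=0.03)
        assert summ.sem == 0.0
        assert summ.combined_error == pytest.approx(0.03 * 5e3)

    def test_quadrature_combination(self):
        maps = [_const_map(v, roi=f"roi{i}") for i, v in enumerate((4e3, 5e3, 6e3))]
        summ = condition_summary(maps, mc_rel_error=0.10)
        expected = np.hypot(1e3 / np.sqrt(3), 0.10 * 5e3)
        assert summ.combined_error == pytest.approx(expected, rel=1e-12)

    def test_single_fv_sem_missing_with_warning(self):
        with pytest.warns(UserWarning, match="SEM undefined"):
            summ = condition_summary([_const_map(5e3)], mc_rel_error=0.05)
        assert summ.sem is None
        assert summ.combined_error == pytest.approx(0.05 * 5e3)

    def test_pooled_count_conserved(self):
        maps = [_const_map(v, roi=f"roi{i}") for i, v in enumerate((4e3, 5e3, 6e3))]
        summ = condition_summary(maps)
        assert len(summ.pooled_E) == sum(m.n_fitted for m in maps)

    def test_violin_quartiles(self):
        maps = [_const_map(v, roi=f"roi{i}") for i, v in enumerate((4e3, 5e3, 6e3))]
        vio = condition_summary(maps).violin_summary()
        pooled = np.concatenate([m.values() for m in maps])
        assert vio["median"] == np.quantile(pooled, 0.5)
        assert vio["q1"] == np.quantile(pooled, 0.25)


class TestMonteCarloCalibrationError:
    @pytest.fixture(scope="class")
    def fitted_maps(self):
        spec = CohortSpec(
            patients=[PatientSpec(patient_id="P", relative_stiffening=0.0,
                                  n_rois_per_condition=2)],
            grid_shape=(5, 5),
            ramp=RampConfig(noise_sd_volts=0.0),
            seed=21,
        )
        cohort = synthesize_cohort(spec)
        maps = [fit_volume(fv) for fv in cohort.force_volumes if fv.condition == "normal"]
        return maps, spec.calibration

    def test_zero_uncertainty_returns_exact_zero(self, fitted_maps):
        maps, calib = fitted_maps
        calib0 = dataclasses.replace(calib, rel_unc_k=0.0, rel_unc_s=0.0)
        assert mc_calibration_error(maps, calib0, n_mc=100, seed=0) == 0.0

    def test_spring_constant_uncertainty_propagates_linearly(self, fitted_maps):
        """E is exactly proportional to k, so a 10% k-uncertainty must come
        back as ~0.10 relative error."""
        maps, calib = fitted_maps
        calib_k = dataclasses.replace(calib, rel_unc_k=0.10, rel_unc_s=0.0)
        val = mc_calibration_error(maps, calib_k, n_mc=400, seed=3)
        assert val == pytest.approx(0.10, abs=0.015)

    def test_sensitivity_uncertainty_matches_finite_difference(self, fitted_maps):
        """The MC spread under s-uncertainty alone agrees with a brute-force
        finite-difference propagation of s through rescale + fit."""
        from ecmech.hertz import fit_curve
        from ecmech.preprocessing import rescale

        maps, calib = fitted_maps
        calib_s = dataclasses.replace(calib, rel_unc_k=0.0, rel_unc_s=0.05)
        val = mc_calibration_error(maps, calib_s, n_mc=400, seed=4)
        # finite difference of the condition statistic with respect to s
        eps = 0.01

        def stat(c):
            meds = []
            for m in maps:
                es = [
                    fit_curve(rescale(m.force_volume.curves[rc], c, m.contact_points[rc]), c).E
                    for rc in sorted(m.fits)
                ]
                meds.append(np.median(es))
            return np.mean(meds)

        base = stat(calib_s)
        bumped = stat(calib_s.scaled(s_factor=1 + eps))
        rel_sens = abs(bumped - base) / base / eps  # d ln(stat) / d ln(s)
        predicted = rel_sens * 0.05
        assert val == pytest.approx(predicted, rel=0.2)
        assert val > 0


class TestCompareConditions:
    def test_identical_summaries_null_result(self):
        maps_a = [_const_map(5e3, roi=f"roi{i}") for i in range(3)]
        maps_b = [_const_map(5e3, condition="neoplastic", roi=f"roi{i}") for i in range(3)]
        comp = compare_conditions(condition_summary(maps_a), condition_summary(maps_b))
        assert comp.relative_stiffening == 0.0
        assert comp.p_value == 1.0
        assert comp.significant is False

    def test_relative_stiffening_formula(self):
        maps_a = [_const_map(1e3, roi=f"roi{i}") for i in range(2)]
        maps_b = [_const_map(13e3, condition="neoplastic", roi=f"roi{i}") for i in range(2)]
        comp = compare_conditions(condition_summary(maps_a), condition_summary(maps_b))
        # (13 - 1)/1 = 12, printed as 1200%
        assert comp.relative_stiffening == pytest.approx(12.0)

    def test_welch_p_value_against_textbook_formula(self):
        a = np.array([4e3, 5e3, 6e3])
        b = np.array([8e3, 10e3, 12e3])
        maps_a = [_const_map(v, roi=f"roi{i}") for i, v in enumerate(a)]
        maps_b = [_const_map(v, condition="neoplastic", roi=f"roi{i}") for i, v in enumerate(b)]
        comp = compare_conditions(condition_summary(maps_a), condition_summary(maps_b))
        # independent textbook computation of the Welch statistic and df
        from scipy import stats as st

        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_ref = 2 * st.t.sf(abs(t), df)
        assert comp.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_single_fv_side_reports_no_p_value(self):
        with pytest.warns(UserWarning):
            summ_a = condition_summary([_const_map(5e3)])
            maps_b = [_const_map(9e3, condition="neoplastic", roi=f"roi{i}") for i in range(3)]
            comp = compare_conditions(summ_a, condition_summary(maps_b))
        assert comp.p_value is None
        assert comp.significant is None
        assert comp.relative_stiffening == pytest.approx(0.8)


def _metadata_frame(rows):
    df = pd.DataFrame(rows)
    for col in METADATA_COLUMNS:
        if col not in df:
            df[col] = ""
    return df[METADATA_COLUMNS]


def _comparison(pid, stiffening, e_normal=1e4, p=0.01):
    return PatientComparison(
        patient_id=pid, E_normal=e_normal, E_normal_err=100.0,
        E_neoplastic=e_normal * (1 + stiffening), E_neoplastic_err=100.0,
        relative_stiffening=stiffening, p_value=p, significant=p < 0.05,
    )


class TestMetadataAssociations:
    def test_constant_stiffening_gives_null_contrasts(self):
        comps = [_comparison(f"P{i}", 0.5) for i in range(8)]
        meta = _metadata_frame(
            [
                {
                    "patient_id": f"P{i}",
                    "age_years": 60,
                    "sex": "F" if i % 2 else "M",
                    "diagnosis": "Adenocarcinoma",
                    "grade": "G2" if i < 4 else "G3",
                    "chemotherapy": "yes" if i % 2 else "no",
                    "kras_braf_status": "NONE" if i < 4 else "KRAS G12D",
                }
                for i in range(8)
            ]
        )
        table = metadata_associations(comps, meta)
        welch = table[table["kind"] == "welch_t"]
        assert (welch["p_value"] == 1.0).all()
        assert (welch["statistic"] == 0.0).all()
        pearson = table[table["kind"] == "pearson"]
        # age has zero variance: correlations undefined, reported missing
        assert pearson["p_value"].isna().all()

    def test_age_slope_recovered(self):
        """Stiffening generated as 0.5 + 0.02*(age - 50) + noise is recovered
        with the right slope and a significant correlation."""
        rng = np.random.default_rng(7)
        ages = rng.integers(35, 85, size=30)
        stiff = 0.5 + 0.02 * (ages - 50) + rng.normal(0, 0.05, 30)
        comps = [_comparison(f"P{i}", s) for i, s in enumerate(stiff)]
        meta = _metadata_frame(
            [
                {
                    "patient_id": f"P{i}",
                    "age_years": int(a),
                    "sex": "F",
                    "diagnosis": "Adenocarcinoma",
                    "grade": "G2",
                    "chemotherapy": "yes",
                    "kras_braf_status": "NONE",
                }
                for i, a in enumerate(ages)
            ]
        )
        table = metadata_associations(comps, meta).set_index("contrast")
        row = table.loc["stiffening_vs_age"]
        assert row["p_value"] < 0.05
        # recover the slope from r via the sample SDs: slope = r * s_y / s_x
        slope = row["statistic"] * np.std(stiff, ddof=1) / np.std(ages.astype(float), ddof=1)
        assert slope == pytest.approx(0.02, rel=0.25)

    def test_grade_contrast_detects_twofold_difference(self):
        rng = np.random.default_rng(8)
        stiff = np.concatenate([
            rng.normal(0.5, 0.05, 10),   # G2
            rng.normal(1.0, 0.05, 10),   # G3
        ])
        comps = [_comparison(f"P{i}", s) for i, s in enumerate(stiff)]
        meta = _metadata_frame(
            [
                {
                    "patient_id": f"P{i}",
                    "age_years": 50 + i,
                    "sex": "F",
                    "diagnosis": "Adenocarcinoma",
                    "grade": "G2" if i < 10 else "G3",
                    "chemotherapy": "yes",
                    "kras_braf_status": "NONE",
                }
                for i in range(20)
            ]
        )
        table = metadata_associations(comps, meta).set_index("contrast")
        assert table.loc["stiffening_vs_grade", "p_value"] < 0.05

    def test_excluded_patient_omitted(self):
        comps = [_comparison(f"P{i}", 0.3 + 0.1 * i) for i in range(6)]
        meta = _metadata_frame(
            [
                {
                    "patient_id": f"P{i}",
                    "age_years": 50 + i,
                    "sex": "F" if i % 2 else "M",
                    "diagnosis": "Adenocarcinoma" if i < 5 else "Neuroendocrine carcinoma",
                    "grade": "G2",
                    "chemotherapy": "yes",
                    "kras_braf_status": "NONE",
                }
                for i in range(6)
            ]
        )
        table = metadata_associations(comps, meta, exclude=("P5",))
        assert not any(table["contrast"].str.contains("Neuroendocrine"))
        assert (table[table["kind"] == "pearson"]["n"] == 5).all()

    def test_small_group_skipped_with_warning(self):
        comps = [_comparison(f"P{i}", 0.3 + 0.1 * i) for i in range(5)]
        meta = _metadata_frame(
            [
                {
                    "patient_id": f"P{i}",
                    "age_years": 50 + i,
                    "sex": "M" if i == 0 else "F",  # one-male group
                    "diagnosis": "Adenocarcinoma",
                    "grade": "G2",
                    "chemotherapy": "yes",
                    "kras_braf_status": "NONE",
                }
                for i in range(5)
            ]
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            table = metadata_associations(comps, meta).set_index("contrast")
        assert np.isnan(table.loc["stiffening_vs_sex", "p_value"])
        assert "skipped" in table.loc["stiffening_vs_sex", "note"]

    def test_mutation_status_nd_dropped_from_contrast_only(self):
        comps = [_comparison(f"P{i}", 0.3 + 0.05 * i) for i in range(6)]
        meta = _metadata_frame(
            [
                {
                    "patient_id": f"P{i}",
                    "age_years": 50 + i,
                    "sex": "F",
                    "diagnosis": "Adenocarcinoma",
                    "grade": "G2",
                    "chemotherapy": "yes",
                    "kras_braf_status": ["NONE", "NONE", "KRAS G12S", "BRAF V600E", "ND", "ND"][i],
                }
                for i in range(6)
            ]
        )
        table = metadata_associations(comps, meta).set_index("contrast")
        assert table.loc["stiffening_vs_kras_braf", "n"] == 4
        assert table.loc["stiffening_vs_age", "n"] == 6


class TestStatHelpers:
    def test_holm_adjustment(self):
        # textbook Holm: sorted p (0.01, 0.02, 0.04) with m=3 -> (0.03, 0.04, 0.04)
        adj = _holm([0.04, 0.01, None, 0.02])
        assert adj[1] == pytest.approx(0.03)
        assert adj[3] == pytest.approx(0.04)
        assert adj[0] == pytest.approx(0.04)
        assert adj[2] is None

    def test_welch_zero_variance_different_means(self):
        t, p = _welch([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and np.isinf(t)
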