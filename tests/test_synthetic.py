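"""Tests of the synthetic force-curve and cohort generator."""

import numpy as np
import pytest

from ecmech import (
    CohortSpec,
    GroundTruthField,
    ParameterError,
    PatientSpec,
    RampConfig,
    estimate_sensitivity,
    find_contact_point,
    fit_curve,
    generate_field,
    hertz_force,
    rescale,
    synthesize_cohort,
    synthesize_curve,
    synthesize_stiff_substrate_curve,
)


class TestGenerateField:
    def test_zero_variance_mode_is_exact(self):
        spec = GroundTruthField(modes=[(5000.0, 0.0, 1.0)], grid_shape=(7, 9))
        field = generate_field(spec)
        assert field.shape == (7, 9)
        np.testing.assert_array_equal(field, 5000.0)

    def test_single_mode_median_consistency(self):
        # oracle: the median of a log-normal is its median parameter
        spec = GroundTruthField(modes=[(5000.0, 0.3, 1.0)], grid_shape=(100, 100), seed=3)
        field = generate_field(spec)
        assert np.median(field) == pytest.approx(5000.0, rel=0.03)
        assert np.all(field > 0)

    def test_two_modes_give_bimodal_log_histogram(self):
        spec = GroundTruthField(
            modes=[(2000.0, 0.05, 0.5), (20000.0, 0.05, 0.5)],
            grid_shape=(100, 100),
            seed=7,
        )
        counts, edges = np.histogram(np.log10(generate_field(spec)), bins=30)
        centres = 0.5 * (edges[:-1] + edges[1:])
        # local maxima of the histogram sit near the two mode medians
        peaks = [
            centres[i]
            for i in range(1, len(counts) - 1)
            if counts[i] >= counts[i - 1] and counts[i] >= counts[i + 1] and counts[i] > 50
        ]
        assert any(abs(p - np.log10(2000)) < 0.15 for p in peaks)
        assert any(abs(p - np.log10(20000)) < 0.15 for p in peaks)

    def test_spatial_correlation_forms_patches(self):
        modes = [(2000.0, 0.0, 0.5), (20000.0, 0.0, 0.5)]
        smooth = generate_field(
            GroundTruthField(modes=modes, grid_shape=(40, 40), spatial_correlation_length=3.0, seed=1)
        )
        rough = generate_field(
            GroundTruthField(modes=modes, grid_shape=(40, 40), spatial_correlation_length=0.0, seed=1)
        )

        def n_transitions(f):
            lab = f > 5000.0
            return np.sum(lab[:, 1:] != lab[:, :-1]) + np.sum(lab[1:, :] != lab[:-1, :])

        assert n_transitions(smooth) < 0.5 * n_transitions(rough)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ParameterError):
            GroundTruthField(modes=[(5000.0, 0.1, 0.6), (2000.0, 0.1, 0.6)], grid_shape=(4, 4))

    def test_deterministic_given_seed(self):
        spec = GroundTruthField(modes=[(5000.0, 0.2, 1.0)], grid_shape=(20, 20), seed=11)
        np.testing.assert_array_equal(generate_field(spec), generate_field(spec))


class TestSynthesizeCurve:
    def test_precontact_voltage_is_exact_baseline(self, calib, quiet_ramp):
        curve = synthesize_curve(1e4, calib, quiet_ramp, contact_z=3000.0, baseline_volts=0.12)
        pre = curve.z < 3000.0
        np.testing.assert_allclose(curve.voltage[pre], 0.12, atol=1e-15)

    def test_force_balance_satisfied_along_curve(self, calib, quiet_ramp):
        """Every post-contact sample satisfies k*d = Hertz force at the implied
        indentation, to the generator's stated residual tolerance."""
        curve = synthesize_curve(1e4, calib, quiet_ramp, contact_z=3000.0)
        d = curve.voltage * calib.sensitivity
        delta = (curve.z - 3000.0) - d
        post = delta > 0
        force = calib.spring_constant * d[post]
        np.testing.assert_allclose(force, hertz_force(delta[post], 1e4, calib.tip_radius), atol=1e-6)

    def test_force_at_1000nm_indentation_matches_hand_value(self, calib, quiet_ramp):
        # independent hand evaluation: (4/3)*(1e4 Pa/0.75)*sqrt(1e4 nm)*1000^1.5 = 56.2 nN
        curve = synthesize_curve(1e4, calib, quiet_ramp, contact_z=3000.0)
        d = curve.voltage * calib.sensitivity
        delta = (curve.z - 3000.0) - d
        force = calib.spring_constant * d
        f_at_1000 = np.interp(1000.0, delta, force)
        assert f_at_1000 == pytest.approx(56.2, abs=0.1)

    def test_rigid_limit_slope_is_inverse_sensitivity(self, calib, quiet_ramp):
        curve = synthesize_stiff_substrate_curve(calib, quiet_ramp, contact_z=3000.0)
        post = curve.z > 3000.0
        slope = np.polyfit(curve.z[post], curve.voltage[post], 1)[0]
        assert slope == pytest.approx(1.0 / calib.sensitivity, rel=1e-12)

    def test_max_load_trigger_truncates_ramp(self, calib, quiet_ramp):
        curve = synthesize_curve(5e4, calib, quiet_ramp, contact_z=3000.0)
        force = calib.spring_constant * curve.voltage * calib.sensitivity
        assert len(curve) < quiet_ramp.n_points
        assert force.max() <= quiet_ramp.max_load + 1e-9

    def test_reproducible_from_seed(self, calib, noisy_ramp):
        c1 = synthesize_curve(1e4, calib, noisy_ramp, 3000.0, seed=5)
        c2 = synthesize_curve(1e4, calib, noisy_ramp, 3000.0, seed=5)
        np.testing.assert_array_equal(c1.voltage, c2.voltage)
        c3 = synthesize_curve(1e4, calib, noisy_ramp, 3000.0, seed=6)
        assert not np.array_equal(c1.voltage, c3.voltage)

    def test_contact_outside_ramp_rejected(self, calib, quiet_ramp):
        with pytest.raises(ParameterError):
            synthesize_curve(1e4, calib, quiet_ramp, contact_z=16000.0)

    def test_baseline_tilt_applied(self, calib, quiet_ramp):
        curve = synthesize_curve(1e4, calib, quiet_ramp, 3000.0, baseline_tilt_volts_per_nm=1e-5)
        pre = curve.z < 2900.0
        slope = np.polyfit(curve.z[pre], curve.voltage[pre], 1)[0]
        assert slope == pytest.approx(1e-5, rel=1e-9)


class TestRoundTripInvariants:
    def test_noise_free_roundtrip_recovers_modulus(self, calib, quiet_ramp):
        """Generator -> contact detection -> rescale -> fit recovers E_true to
        < 0.5% (bounds the discretization error of the 8192-point ramp)."""
        for E_true in (2e3, 1e4, 5e4):
            curve = synthesize_curve(E_true, calib, quiet_ramp, contact_z=3137.0)
            cp = find_contact_point(curve, calib)
            fit = fit_curve(rescale(curve, calib, cp), calib)
            assert fit.E == pytest.approx(E_true, rel=0.005)

    def test_rigid_substrate_curve_recovers_sensitivity(self, calib, quiet_ramp):
        curve = synthesize_stiff_substrate_curve(calib, quiet_ramp, contact_z=3000.0)
        n = len(curve)
        s_hat = estimate_sensitivity(curve, (n - 2000, n))
        assert s_hat == pytest.approx(calib.sensitivity, rel=1e-3)


class TestSynthesizeCohort:
    @pytest.fixture(scope="class")
    def small_cohort_spec(self):
        return CohortSpec(
            patients=[
                PatientSpec(patient_id="P1", relative_stiffening=1.0, n_rois_per_condition=2),
                PatientSpec(patient_id="P2", relative_stiffening=0.0, n_rois_per_condition=2),
            ],
            grid_shape=(4, 4),
            ramp=RampConfig(n_points=1024),
            seed=9,
        )

    def test_layout_and_ground_truth(self, small_cohort_spec):
        cohort = synthesize_cohort(small_cohort_spec)
        assert len(cohort.force_volumes) == 2 * 2 * 2
        gt = cohort.ground_truth
        assert len(gt) == 8 * 16
        assert set(gt.columns) == {
            "patient", "condition", "roi", "row", "col", "E_true_Pa", "contact_z_nm",
        }

    def test_zero_stiffening_equalizes_conditions(self):
        p = PatientSpec(patient_id="X", E_normal_median=5e3, relative_stiffening=0.0)
        assert p.median_for("normal") == p.median_for("neoplastic") == 5e3

    def test_stiffening_formula(self):
        p = PatientSpec(patient_id="X", E_normal_median=5e3, relative_stiffening=1.0)
        assert p.median_for("neoplastic") == pytest.approx(10e3)
        # 1200% relative stiffening means a 13x neoplastic/normal ratio
        p13 = PatientSpec(patient_id="Y", E_normal_median=1e3, relative_stiffening=12.0)
        assert p13.median_for("neoplastic") == pytest.approx(13e3)

    def test_dataset_roundtrips_through_io(self, small_cohort_spec, tmp_path):
        from ecmech import read_dataset

        cohort = synthesize_cohort(small_cohort_spec, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        assert len(back.force_volumes) == len(cohort.force_volumes)
        for fv_a, fv_b in zip(cohort.force_volumes, back.force_volumes):
            assert fv_a.key == fv_b.key
            for cell, curve in fv_a.iter_cells():
                np.testing.assert_array_equal(curve.voltage, fv_b.curves[cell].voltage)

    def test_byte_identical_regeneration(self, small_cohort_spec, tmp_path):
        import filecmp

        synthesize_cohort(small_cohort_spec, tmp_path / "a")
        synthesize_cohort(small_cohort_spec, tmp_path / "b")
        names = [p.name for p in sorted((tmp_path / "a").iterdir())]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors
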