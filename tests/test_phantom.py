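"""Tests of the synthetic beam phantom and acquisition simulator."""

import numpy as np
import pytest

from vfadose import (
    BeamModel,
    FlipAngleVolumeSet,
    PhantomSpec,
    R1Volume,
    ScanProtocol,
    apply_kspace_truncation,
    calibrate_noise_sigma,
    central_axis_delta_r1,
    delta_r1,
    depth_dose,
    dose_to_r1,
    dose_volume,
    extract_depth_profile,
    fit_linear_calibration,
    fit_r1_volume,
    generate_calibration_vials,
    image_quality,
    sensitivity_at_depth,
    simulate_acquisition,
    spgr_signal,
)
from vfadose.calibration import CalibrationPoint
from vfadose.relaxometry import _fit_e1_intercept


class TestDepthDose:
    def test_entrance_normalization_exact(self):
        beam = BeamModel(entrance_dose_gy=600.0)
        assert depth_dose(0.0, beam) == pytest.approx(600.0, rel=1e-12)

    def test_peak_location_and_height(self):
        beam = BeamModel(entrance_dose_gy=600.0)
        z = np.arange(0.0, 70.0, 0.1)
        dd = depth_dose(z, beam)
        assert abs(z[np.argmax(dd)] - beam.peak_depth_mm) <= 0.1
        assert dd.max() / 600.0 == pytest.approx(
            beam.peak_to_entrance_ratio, rel=0.002
        )

    def test_distal_asymptote(self):
        beam = BeamModel(entrance_dose_gy=600.0)
        far = beam.peak_depth_mm + 10.0 * beam.distal_falloff_mm
        assert depth_dose(far, beam) < 0.01 * 600.0

    def test_plateau_declines(self):
        beam = BeamModel(entrance_dose_gy=600.0)
        assert depth_dose(30.0, beam) < depth_dose(5.0, beam) < 600.0

    def test_penumbra_monotone_beyond_min_depth(self):
        beam = BeamModel()
        z = np.linspace(beam.penumbra_min_depth_mm, 90.0, 200)
        s = beam.penumbra_sigma_mm(z)
        assert np.all(np.diff(s) >= 0)


class TestDoseVolume:
    def test_central_axis_matches_curve(self):
        # odd lateral matrix puts a voxel center exactly on the beam axis
        spec = PhantomSpec(
            vial_diameter_mm=16.0, vial_length_mm=24.0, gel_start_mm=2.0,
            kspace_matrix=(32, 25), n_slices=25, oversample_factor=4,
            beam=BeamModel(
                entrance_dose_gy=300.0, peak_depth_mm=14.0,
                peak_width_mm=2.0, distal_falloff_mm=0.5,
                penumbra_min_depth_mm=10.0, field_side_mm=6.0,
            ),
        )
        dose, mask = dose_volume(spec)
        j, k = 12, 12  # voxel center at 12.5 mm = lateral center
        z = (np.arange(dose.shape[0]) + 0.5) - spec.gel_start_mm
        inside = (z >= 0) & (z <= spec.vial_length_mm)
        truth = central_axis_delta_r1(spec, z[inside])
        line = dose_to_r1(dose, spec)[inside, j, k] - spec.background_r1_per_s
        assert np.allclose(line, truth, rtol=1e-9, atol=1e-12)

    def test_lateral_flux_conservation(self, small_spec):
        dose, mask = dose_volume(small_spec)
        beam = small_spec.beam
        z = (np.arange(dose.shape[0]) + 0.5) - small_spec.gel_start_mm
        d_curve = depth_dose(np.clip(z, 0, None), beam)
        # mid-plateau slab, vial wide enough to catch the blurred field
        iz = int(np.argmin(np.abs(z - 6.0)))
        integral = dose[iz].sum() * small_spec.voxel_mm**2
        expected = d_curve[iz] * beam.field_side_mm**2
        assert integral == pytest.approx(expected, rel=0.005)

    def test_field_must_fit_in_vial(self, small_spec):
        from dataclasses import replace

        bad = replace(small_spec, beam=BeamModel(field_side_mm=20.0))
        with pytest.raises(ValueError, match="vial"):
            dose_volume(bad)

    def test_outside_vial_masked_zero(self, small_spec):
        dose, mask = dose_volume(small_spec)
        assert np.all(dose[~mask] == 0.0)


class TestDoseToR1:
    def test_zero_dose_gives_background(self, small_spec):
        r1 = dose_to_r1(np.zeros(small_spec.grid_shape), small_spec)
        assert np.allclose(r1, small_spec.background_r1_per_s)

    def test_entrance_sensitivity_arithmetic(self):
        spec = PhantomSpec()
        # 600 Gy at an entrance-plateau voxel: deltaR1 = 1.08 * 0.6
        dose = np.zeros(spec.grid_shape)
        iz = 10  # z = 10.5mm, depth 8.5mm: entrance sensitivity regime
        dose[iz] = 600.0
        r1 = dose_to_r1(dose, spec)
        delta = r1[iz] - spec.background_r1_per_s
        assert np.allclose(delta, 1.08 * 0.6, rtol=1e-12)

    def test_linearity_in_dose(self, small_spec):
        dose, _ = dose_volume(small_spec)
        d1 = dose_to_r1(dose, small_spec) - small_spec.background_r1_per_s
        d2 = dose_to_r1(2.0 * dose, small_spec) - small_spec.background_r1_per_s
        assert np.allclose(d2, 2.0 * d1)

    def test_sensitivity_ramp_endpoints(self):
        spec = PhantomSpec()
        zp, w = spec.beam.peak_depth_mm, spec.beam.peak_width_mm
        assert sensitivity_at_depth(5.0, spec) == spec.entrance_sensitivity
        assert sensitivity_at_depth(zp, spec) == spec.peak_sensitivity
        assert sensitivity_at_depth(zp + 10.0, spec) == spec.peak_sensitivity
        mid = sensitivity_at_depth(zp - 1.5 * w, spec)
        assert spec.entrance_sensitivity < mid < spec.peak_sensitivity


class TestKspaceTruncation:
    def test_constant_image_reconstructs_exactly(self):
        img = np.full(512, 3.3)
        rec = apply_kspace_truncation(img, 64)
        assert np.allclose(rec, 3.3, atol=1e-12)

    def test_gibbs_step_overshoot_about_nine_percent(self):
        n, ov = 256, 8
        x = np.zeros(n * ov)
        x[n * ov // 2:] = 1.0
        rec = apply_kspace_truncation(x, n, keep_grid=True)
        overshoot = rec.max() - 1.0
        assert 0.08 <= overshoot <= 0.10

    def test_registration_preserves_feature_position(self):
        n, ov = 96, 8
        x_hi = (np.arange(n * ov) + 0.5) / ov
        spike = np.exp(-0.5 * ((x_hi - 49.5) / 0.6) ** 2)  # at a cell center
        rec = apply_kspace_truncation(spike, n)
        assert np.argmax(rec) == 49
        # neighbors symmetric about the spike
        assert rec[48] == pytest.approx(rec[50], rel=1e-6)

    def test_parseval_energy_bound(self):
        rng = np.random.default_rng(5)
        img = rng.random((64, 64))
        e_src = np.sum(img**2) * 1.0  # unit cell area
        rec = apply_kspace_truncation(img, (32, 32))
        e_rec = np.sum(rec**2) * (64 / 32) ** 2  # coarser cells
        assert e_rec <= e_src + 1e-9
        same = apply_kspace_truncation(img, (64, 64))
        assert np.sum(same**2) == pytest.approx(e_src, rel=1e-12)

    def test_target_larger_than_source_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            apply_kspace_truncation(np.zeros(32), 64)


class TestNoiseCalibration:
    def test_deterministic(self, protocol):
        s1 = calibrate_noise_sigma(protocol, 0.8, 1000.0, 0.037)
        s2 = calibrate_noise_sigma(protocol, 0.8, 1000.0, 0.037)
        assert s1 == s2 and s1 > 0

    def test_zero_cv_gives_zero_sigma(self, protocol):
        assert calibrate_noise_sigma(protocol, 0.8, 1000.0, 0.0) == 0.0

    def test_achieves_target_cv(self, protocol):
        sigma = calibrate_noise_sigma(protocol, 0.8, 1000.0, 0.037)
        signals = np.array(
            [spgr_signal(1000.0, 1250.0, protocol, a) for a in protocol.flip_angles_deg]
        )
        rng = np.random.default_rng(99)
        meas = np.hypot(
            signals[:, None] + sigma * rng.normal(size=(2, 40_000)),
            sigma * rng.normal(size=(2, 40_000)),
        )
        e1, b = _fit_e1_intercept(meas, protocol.flip_angles_rad)
        ok = np.isfinite(e1) & (e1 > 0) & (e1 < 1) & (b > 0)
        r1 = -1000.0 * np.log(e1[ok]) / protocol.tr_ms
        assert r1.std(ddof=1) / r1.mean() == pytest.approx(0.037, rel=0.05)


class TestSimulateAcquisition:
    def test_noiseless_no_truncation_identity_chain(self):
        spec = PhantomSpec(
            vial_diameter_mm=16.0,
            vial_length_mm=24.0,
            kspace_matrix=(32, 24),
            n_slices=24,
            noise_cv=0.0,
            beam=BeamModel(
                entrance_dose_gy=300.0, peak_depth_mm=14.0,
                peak_width_mm=2.0, distal_falloff_mm=0.5,
                penumbra_min_depth_mm=10.0, field_side_mm=6.0,
            ),
        )
        dose, mask = dose_volume(spec)  # acquisition grid: truncation == id
        r1_ideal = np.where(mask, dose_to_r1(dose, spec), 0.0)
        m0_map = spec.m0_arb * mask
        protocol = ScanProtocol(matrix=spec.kspace_matrix, n_slices=spec.n_slices)
        vset = simulate_acquisition(r1_ideal, m0_map, protocol, spec, seed=0)
        fit = fit_r1_volume(vset, protocol)
        inner = mask & fit.valid_mask
        assert inner.sum() > 0.9 * mask.sum()
        assert np.allclose(fit.r1_per_s[inner], r1_ideal[inner], rtol=1e-8)

    def test_seeded_runs_bit_reproducible(self, small_acq):
        a = small_acq.realize(seed=7)
        b = small_acq.realize(seed=7)
        for va, vb in zip(a.irradiated.volumes + a.control.volumes,
                          b.irradiated.volumes + b.control.volumes):
            assert np.array_equal(va, vb)
        c = small_acq.realize(seed=8)
        assert not np.array_equal(a.irradiated.volumes[0], c.irradiated.volumes[0])

    def test_plateau_cv_matches_target_over_seeds(self, small_acq):
        """The calibrated noise yields an R1-map CV within 10% (relative)
        of the 3.7% target, averaged over 20 seeded realizations."""
        spec = small_acq.spec
        cvs = []
        for s in range(20):
            st = small_acq.realize(seed=1000 + s)
            ctrl = fit_r1_volume(st.control, st.protocol)
            _, cv = image_quality(
                ctrl,
                (8.0, spec.lateral_center_mm[0], spec.lateral_center_mm[1]),
                10.0,
                plane="z",
            )
            cvs.append(cv)
        assert np.mean(cvs) == pytest.approx(3.7, rel=0.10)

    def test_slab_averaging_shrinks_profile_noise(self, dose_series):
        """For i.i.d. voxel noise the fluctuation of the n x n averaged
        profile about the generator truth scales ~1/n (7x7 vs single
        line: expected factor 7)."""
        acq = dose_series[600.0]
        st = acq.realize(seed=11)
        irr = fit_r1_volume(st.irradiated, st.protocol)
        ctrl = fit_r1_volume(st.control, st.protocol)
        d = delta_r1(irr, ctrl)
        tv = R1Volume(
            st.delta_r1_true, np.zeros_like(st.delta_r1_true),
            st.vial_mask, (1.0, 1.0, 1.0),
        )
        center = st.spec.lateral_center_mm
        fluct = {}
        for n in (1, 7):
            pm = extract_depth_profile(d, 0, center, n)
            pt = extract_depth_profile(tv, 0, center, n)
            zm = pm.origin_mm + pm.depth_mm
            zt = pt.origin_mm + pt.depth_mm
            sel = (zm >= 10.0) & (zm <= 40.0)
            selt = (zt >= 10.0) & (zt <= 40.0)
            fluct[n] = np.std(pm.value[sel] - pt.value[selt])
        ratio = fluct[1] / fluct[7]
        assert 4.5 <= ratio <= 10.5  # expectation 7, ~30 plateau samples


class TestCalibrationVials:
    def test_zero_concentration_gives_background(self):
        sets, truth = generate_calibration_vials(
            [0.0], noise_cv=0.0, oversample_factor=4
        )
        assert truth.r1_true_per_s.iloc[0] == pytest.approx(0.8)
        protocol = ScanProtocol(matrix=(16, 24), n_slices=24, nex=1,
                                fov_mm=(16.0, 24.0))
        fit = fit_r1_volume(sets[0], protocol)
        # interior voxels (away from the wall ringing) recover background
        inner = fit.valid_mask.copy()
        inner[:, :8, :] = inner[:, -8:, :] = False
        inner[:, :, :8] = inner[:, :, -8:] = False
        assert np.nanmedian(fit.r1_per_s[inner]) == pytest.approx(0.8, rel=1e-3)

    def test_noiseless_series_recovers_relaxivity(self):
        concs = [0.0, 0.125, 0.25, 0.375, 0.5]
        sets, truth = generate_calibration_vials(
            concs, relaxivity=5.7, noise_cv=0.0, oversample_factor=4
        )
        protocol = ScanProtocol(matrix=(16, 24), n_slices=24, nex=1,
                                fov_mm=(16.0, 24.0))
        points = []
        for c, vset in zip(concs, sets):
            fit = fit_r1_volume(vset, protocol)
            from vfadose import roi_mean_r1

            mean, sd, n = roi_mean_r1(fit, (8.0, 12.0, 12.0), 10.0, plane="z")
            points.append(CalibrationPoint(c, mean, sd, n))
        curve = fit_linear_calibration(points)
        assert curve.slope == pytest.approx(5.7, rel=1e-3)
        assert curve.r_squared > 0.99999

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            generate_calibration_vials([-0.1])
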