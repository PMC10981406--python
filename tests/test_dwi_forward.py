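"""Forward model: b-value, flow attenuation (MC vs closed form), calibration,
phantom geometry and volume rendering."""

import dataclasses

import numpy as np
import pytest

from pvspulse import dwi_forward as fwd
from pvspulse import synth_cohort as sc


class TestBValue:
    def test_matches_closed_form_for_protocol_gradients(self, pgse):
        # (gamma*G*delta)^2 * (Delta - delta/3), evaluated independently
        q = pgse.gamma * 0.03 * 5e-3
        expected = q * q * (26e-3 - 5e-3 / 3.0) * 1e-6
        b = fwd.compute_b_value(pgse)
        assert b == pytest.approx(expected, rel=1e-12)
        assert b == pytest.approx(39.2, abs=0.05)
        # the protocol's printed nominal value differs from the closed form
        assert pgse.b_nominal == 43.0

    def test_zero_gradient_and_quadratic_scaling(self, pgse):
        assert fwd.compute_b_value(dataclasses.replace(
            pgse, gradient_amplitude=0.0)) == 0.0
        doubled = dataclasses.replace(pgse, gradient_amplitude=0.06)
        assert fwd.compute_b_value(doubled) == pytest.approx(
            4 * fwd.compute_b_value(pgse), rel=1e-12)

    def test_b0_axis_is_unweighted(self, pgse):
        b0 = dataclasses.replace(pgse, axis="none")
        assert fwd.compute_b_value(b0) == 0.0
        assert fwd.effective_b(b0) == 0.0


class TestAnalyticAttenuation:
    def test_zero_velocity_limit_is_one(self, pgse):
        assert fwd.analytic_attenuation_uniform(0.0, pgse) == 1.0

    def test_full_phase_wrap_null(self, pgse):
        v_null = 2.0 * np.pi / pgse.phase_per_velocity
        assert fwd.analytic_attenuation_uniform(v_null, pgse) \
            == pytest.approx(0.0, abs=1e-12)

    def test_non_increasing_before_null(self, pgse):
        v_null = 2.0 * np.pi / pgse.phase_per_velocity
        v = np.linspace(0.0, 0.999 * v_null, 400)
        a = np.array([fwd.analytic_attenuation_uniform(vi, pgse) for vi in v])
        assert np.all(np.diff(a) <= 1e-12)


class TestMcAttenuation:
    N_SPINS = 40000

    def test_matches_closed_form_within_three_mc_se(self, pgse, cycle):
        """Dual route: spin-phase Monte Carlo vs the sinc-type closed form
        over a grid of peak velocities in [0, 5] mm/s."""
        for i, v in enumerate([0.0, 0.5, 1.0, 1.89, 3.0, 4.0, 5.0]):
            flow = sc.FlowParams(v_peak=v, d_free=1e-9, perp_pulsatile_gain=0.0)
            mc = fwd.mc_attenuation(flow, pgse, cycle.arrival_delay, cycle,
                                    "parallel", n_spins=self.N_SPINS, seed=100 + i)
            analytic = fwd.analytic_attenuation_uniform(v, pgse)
            se = np.sqrt(1.0 / (2 * self.N_SPINS))  # bound on |mean e^{i phi}| SE
            assert abs(mc - analytic) < 3 * max(se, 1e-4)

    def test_no_motion_no_diffusion_gives_unity(self, pgse, cycle):
        flow = sc.FlowParams(v_peak=0.0, d_free=1e-15, perp_pulsatile_gain=0.0)
        att = fwd.mc_attenuation(flow, pgse, 25.0, cycle, "parallel", seed=0)
        assert att == pytest.approx(1.0, abs=1e-10)

    def test_perpendicular_without_gain_is_pure_diffusion(self, pgse, cycle):
        flow = sc.FlowParams(v_peak=2.0, d_free=0.002, perp_pulsatile_gain=0.0)
        att = fwd.mc_attenuation(flow, pgse, cycle.arrival_delay, cycle,
                                 "perpendicular", seed=0)
        assert att == pytest.approx(np.exp(-43.0 * 0.002), rel=1e-12)

    def test_plug_flow_is_coherent(self, pgse, cycle):
        """A single-velocity (plug) compartment only shifts phase: magnitude
        attenuation comes entirely from the isotropic term."""
        flow = sc.FlowParams(v_peak=2.0, profile="plug", d_free=0.002,
                             perp_pulsatile_gain=0.0)
        att = fwd.mc_attenuation(flow, pgse, cycle.arrival_delay, cycle,
                                 "parallel", seed=0)
        assert att == pytest.approx(np.exp(-43.0 * 0.002), rel=1e-9)

    def test_envelope_gates_the_effective_velocity(self, pgse, cycle):
        flow = sc.FlowParams(v_peak=2.0, d_free=0.002)
        diastole = fwd.mc_attenuation(flow, pgse, 120.0, cycle, "parallel", seed=0)
        assert diastole == pytest.approx(np.exp(-43.0 * 0.002), rel=1e-12)

    def test_too_few_spins_rejected(self, pgse, cycle):
        with pytest.raises(ValueError):
            fwd.mc_attenuation(sc.FlowParams(v_peak=1.0), pgse, 25.0, cycle,
                               "parallel", n_spins=10)


class TestCalibration:
    def test_zero_target_gives_zero_velocity(self, pgse):
        assert fwd.calibrate_v_peak(0.0, pgse) == 0.0

    def test_inverts_closed_form(self, pgse):
        """Independent oracle: dense grid search over the forward map."""
        grid = np.linspace(1e-4, 3.0, 300001)
        forward = np.array([-np.log(abs(np.sinc(
            pgse.phase_per_velocity * v / (2 * np.pi)))) / 43.0 for v in grid])
        for target in (0.003, 0.004, 0.005):
            v = fwd.calibrate_v_peak(target, pgse)
            v_grid = grid[np.argmin(np.abs(forward - target))]
            assert v == pytest.approx(v_grid, abs=2e-5)
            assert fwd.flow_dstar(v, pgse) == pytest.approx(target, abs=1e-5)

    def test_ang2_velocity_scale(self, pgse):
        ratio = fwd.calibrate_v_peak(0.003, pgse) / fwd.calibrate_v_peak(0.005, pgse)
        assert ratio == pytest.approx(0.78, abs=0.03)

    def test_unreachable_target_rejected(self, pgse):
        with pytest.raises(ValueError):
            fwd.calibrate_v_peak(1.0, pgse)

    def test_cohort_expectation_matches_simulation(self, pgse, rng):
        """Gauss-Hermite cohort expectation vs a plain Monte-Carlo average."""
        cv = 0.2
        v = fwd.calibrate_cohort_v_peak(0.004, pgse, cv=cv)
        sigma = np.sqrt(np.log1p(cv * cv))
        m = rng.lognormal(-sigma**2 / 2, sigma, 200_000)
        sim = np.mean([fwd.flow_dstar(x, pgse) for x in
                       np.minimum(v * m, 5.9)])
        assert sim == pytest.approx(0.004, rel=0.01)
        # convexity: the template animal sits below the cohort target
        assert fwd.flow_dstar(v, pgse) < 0.004


class TestPhantom:
    def test_all_regions_present_and_disjoint(self, phantom64):
        counts = {r: int(phantom64.mask(r).sum()) for r in fwd.REGION_LABELS}
        assert all(c > 0 for c in counts.values())
        assert sum(counts.values()) == phantom64.labels.size

    def test_tracts_orthogonal_and_long_enough(self, phantom64):
        for region, axis in (("right_PVS", 0), ("left_PVS", 1)):
            idx = np.argwhere(phantom64.mask(region)[:, :, 0])
            extent = idx.max(axis=0) - idx.min(axis=0) + 1
            assert extent[axis] > extent[1 - axis]
            assert idx.shape[0] >= 6

    def test_deterministic_and_slice_stable(self, acq64, phantom64):
        again = fwd.make_phantom(acq64)
        assert np.array_equal(again.labels, phantom64.labels)
        assert np.array_equal(phantom64.labels[:, :, 0], phantom64.labels[:, :, 1])

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            fwd.make_phantom(fwd.AcquisitionParams(matrix=(16, 16, 2)))

    def test_32_matrix_keeps_tracts(self):
        ph = fwd.make_phantom(fwd.AcquisitionParams(matrix=(32, 32, 2)))
        assert int(ph.mask("right_PVS").sum()) >= 6 * 2
        assert int(ph.mask("left_PVS").sum()) >= 6 * 2


class TestRenderVolume:
    def test_b0_roi_mean_near_s0(self, phantom64, baseline_animal, acq64):
        vol = fwd.render_volume(phantom64, baseline_animal,
                                fwd.PGSEParams(axis="none"), acq64, seed=7)
        roi = vol.data[phantom64.mask("right_PVS")]
        se = (1.0 / acq64.snr) / np.sqrt(roi.size)
        assert roi.mean() == pytest.approx(1.0, abs=5 * se + 1e-3)
        assert vol.meta["b_value_s_per_mm2"] == 0.0
        assert vol.meta["mpg_axis"] == "none"

    def test_infinite_snr_reproduces_model_exactly(self, phantom64,
                                                   baseline_animal):
        acq = fwd.AcquisitionParams(ecg_delay=25.0, snr=np.inf)
        pgse = fwd.PGSEParams(axis="FE")
        vol = fwd.render_volume(phantom64, baseline_animal, pgse, acq, seed=3)
        expected = fwd.region_signals(phantom64, baseline_animal, pgse, acq, seed=3)
        for region in ("right_PVS", "left_PVS", "SAS", "tissue"):
            roi = vol.data[phantom64.mask(region)]
            assert np.allclose(roi, expected[region])

    def test_parallel_tract_attenuates_more_during_systole(self, phantom64,
                                                           baseline_animal):
        acq = fwd.AcquisitionParams(ecg_delay=25.0, snr=np.inf)
        vol = fwd.render_volume(phantom64, baseline_animal,
                                fwd.PGSEParams(axis="FE"), acq, seed=3)
        right = vol.data[phantom64.mask("right_PVS")].mean()
        left = vol.data[phantom64.mask("left_PVS")].mean()
        assert right < left

    def test_rician_noise_nonnegative_and_small_bias(self, phantom64,
                                                     baseline_animal, acq64):
        pgse = fwd.PGSEParams(axis="FE")
        noise_free = fwd.region_signals(phantom64, baseline_animal, pgse,
                                        acq64, seed=0)["right_PVS"]
        deviations = []
        for rep in range(20):
            seed = [0, rep]
            vol = fwd.render_volume(phantom64, baseline_animal, pgse, acq64,
                                    seed=seed)
            assert np.all(vol.data >= 0)
            ref = fwd.region_signals(phantom64, baseline_animal, pgse, acq64,
                                     seed=seed)["right_PVS"]
            deviations.append(vol.data[phantom64.mask("right_PVS")].mean() - ref)
        assert abs(np.mean(deviations)) / noise_free < 0.01

    def test_volume_io_round_trip(self, phantom64, baseline_animal, acq64,
                                  tmp_path):
        vol = fwd.render_volume(phantom64, baseline_animal,
                                fwd.PGSEParams(axis="PE"), acq64, seed=5)
        path = tmp_path / "vol.nii.gz"
        fwd.save_volume(vol, path, affine=acq64.affine)
        back = fwd.load_volume(path)
        np.testing.assert_allclose(back.data, vol.data, rtol=1e-6)
        assert back.meta == vol.meta
        ph_path = tmp_path / "phantom.nii.gz"
        fwd.save_phantom(phantom64, ph_path)
        ph = fwd.load_phantom(ph_path)
        assert np.array_equal(ph.labels, phantom64.labels)
        assert ph.label_names == phantom64.label_names
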