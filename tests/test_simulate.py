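"""Generator checks: trajectory statistics, rendering, FRAP and pulse-chase
kinetics, against closed forms and conservation laws."""

import numpy as np
import pytest

from incluflux.simulate import (
    AcquisitionConfig,
    FrapMode,
    InclusionSpec,
    MotionKind,
    MotionModel,
    PulseChaseModel,
    render_cell_zstack,
    render_timelapse,
    simulate_ensemble,
    simulate_frap,
    simulate_pulse_chase,
    simulate_trajectory,
)


class TestTrajectory:
    def test_stationary_positions_identical(self):
        m = MotionModel(kind="stationary", diffusion_um2_s=0.0)
        tr = simulate_trajectory(m, 10, 0.1, seed=0)
        assert np.all(tr.x_um == tr.x_um[0])
        assert np.all(tr.y_um == tr.y_um[0])

    def test_ballistic_displacement_is_vt(self):
        v = 0.8
        m = MotionModel(kind="ballistic", diffusion_um2_s=0.0, drift_speed_um_s=v)
        dt = 0.05
        tr = simulate_trajectory(m, 20, dt, seed=3)
        disp = np.hypot(tr.x_um - tr.x_um[0], tr.y_um - tr.y_um[0])
        assert np.allclose(disp, v * tr.t_s, atol=1e-12)

    def test_brownian_step_variance_matches_2Ddt(self):
        # independent oracle: accumulate squared per-axis steps directly
        D, dt = 0.05, 1 / 32
        tr = simulate_trajectory(MotionModel(diffusion_um2_s=D), 10_001, dt, seed=11)
        steps = np.diff(np.column_stack([tr.x_um, tr.y_um]), axis=0)
        var = (steps**2).sum() / steps.size  # per-axis sample variance
        assert var == pytest.approx(2 * D * dt, rel=0.05)

    def test_invalid_arguments(self):
        m = MotionModel()
        with pytest.raises(ValueError):
            simulate_trajectory(m, 1, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_trajectory(m, 10, 0.0, seed=0)
        with pytest.raises(ValueError):
            MotionModel(kind="brownian", drift_speed_um_s=1.0)
        with pytest.raises(ValueError):
            MotionModel(kind="stationary", diffusion_um2_s=0.1)

    def test_seed_determinism_and_independence(self):
        m = MotionModel()
        a = simulate_trajectory(m, 50, 0.1, seed=7)
        b = simulate_trajectory(m, 50, 0.1, seed=7)
        c = simulate_trajectory(m, 50, 0.1, seed=8)
        assert np.array_equal(a.x_um, b.x_um) and np.array_equal(a.y_um, b.y_um)
        assert not np.array_equal(a.x_um, c.x_um)

    def test_reflective_bounds_contain_walk(self):
        m = MotionModel(diffusion_um2_s=5.0)
        tr = simulate_trajectory(m, 500, 0.1, seed=1, start_um=(1.0, 1.0),
                                 bounds_um=(2.0, 2.0))
        assert tr.x_um.min() >= 0 and tr.x_um.max() <= 2.0
        assert tr.y_um.min() >= 0 and tr.y_um.max() <= 2.0

    def test_ensemble_msd_matches_4Ddt(self):
        # Brownian ensemble: mean squared displacement over many tracks
        # within 5% of 4·D·Δt at lags 1..16
        D, dt = 0.059, 1 / 32
        tracks = simulate_ensemble(MotionModel(diffusion_um2_s=D), 1000, 33, dt, seed=5)
        pos = np.stack([t.positions_um for t in tracks])  # (n, T, 2)
        for k in (1, 4, 16):
            d = pos[:, k:] - pos[:, :-k]
            msd = (d**2).sum(axis=2).mean()
            assert msd / (4 * D * k * dt) == pytest.approx(1.0, abs=0.05)


class TestRenderTimelapse:
    def test_no_particles_background_only(self, quiet_config):
        stack, _ = render_timelapse([], quiet_config, seed=0)
        assert np.all(stack.data == quiet_config.background_level)

    def test_centroid_of_stationary_spot(self, quiet_config):
        m = MotionModel(kind="stationary", diffusion_um2_s=0.0)
        tr = simulate_trajectory(m, 3, 0.1, seed=0, start_um=(3.17, 2.93))
        stack, _ = render_timelapse([tr], quiet_config, seed=0, amplitude=100)
        frame = stack.frame(0) - quiet_config.background_level
        yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
        cx = (xx * frame).sum() / frame.sum()
        cy = (yy * frame).sum() / frame.sum()
        assert abs(cx - 31.7) < 0.05 and abs(cy - 29.3) < 0.05

    def test_bleach_geometric_decay(self, quiet_config):
        cfg = AcquisitionConfig(shot_noise=False, read_noise_sd=0.0,
                                background_level=0.0,
                                bleach_retention_per_exposure={"ch0": 0.9})
        m = MotionModel(kind="stationary", diffusion_um2_s=0.0)
        tr = simulate_trajectory(m, 4, 0.1, seed=0, start_um=(3.2, 3.2))
        stack, _ = render_timelapse([tr], cfg, seed=0, amplitude=100)
        peak0 = stack.frame(0).max()
        peak3 = stack.frame(3).max()
        assert peak3 / peak0 == pytest.approx(0.9**3, rel=1e-9)

    def test_photon_conservation(self, quiet_config):
        # summed spot intensity above background = amplitude · 2π·σ_px²
        cfg = AcquisitionConfig(shot_noise=False, read_noise_sd=0.0,
                                background_level=5.0)
        m = MotionModel(kind="stationary", diffusion_um2_s=0.0)
        tr = simulate_trajectory(m, 2, 0.1, seed=0, start_um=(3.2, 3.2))
        stack, _ = render_timelapse([tr], cfg, seed=0, amplitude=80)
        total = (stack.frame(0) - 5.0).sum()
        expected = 80 * 2 * np.pi * cfg.psf_sigma_px**2
        assert total == pytest.approx(expected, rel=0.01)

    def test_out_of_field_error_mode(self, quiet_config):
        m = MotionModel(kind="stationary", diffusion_um2_s=0.0)
        tr = simulate_trajectory(m, 2, 0.1, seed=0, start_um=(50.0, 3.0))
        with pytest.raises(ValueError):
            render_timelapse([tr], quiet_config, seed=0, out_of_field="error")

    def test_render_seed_determinism(self):
        cfg = AcquisitionConfig()  # noise on
        m = MotionModel(diffusion_um2_s=0.059)
        tr = simulate_trajectory(m, 10, 1 / 32, seed=2, start_um=(3.2, 3.2))
        a, _ = render_timelapse([tr], cfg, seed=9)
        b, _ = render_timelapse([tr], cfg, seed=9)
        assert np.array_equal(a.data, b.data)


class TestRenderZstack:
    def test_no_inclusions_uniform(self):
        cfg = AcquisitionConfig(shot_noise=False, read_noise_sd=0.0)
        stack, gt = render_cell_zstack([], cfg, seed=0, cytoplasm_mean=100.0)
        assert np.allclose(stack.data, 100.0)
        assert gt.true_masks.max() == 0

    def test_ground_truth_classes_by_area(self):
        cfg = AcquisitionConfig(shot_noise=False, read_noise_sd=0.0)
        small = InclusionSpec(center_um=(1.5, 1.5, 0), radii_um=(0.05, 0.05, 0.05))
        big = InclusionSpec(center_um=(4.5, 4.5, 0), radii_um=(0.25, 0.25, 0.25))
        _, gt = render_cell_zstack([small, big], cfg, seed=0)
        assert gt.true_parameters["classes"] == ["small_particle", "IB"]

    def test_overlapping_specs_error(self):
        cfg = AcquisitionConfig(shot_noise=False, read_noise_sd=0.0)
        a = InclusionSpec(center_um=(3.2, 3.2, 0), radii_um=(0.5, 0.5, 0.5))
        b = InclusionSpec(center_um=(3.4, 3.2, 0), radii_um=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            render_cell_zstack([a, b], cfg, seed=0)
        render_cell_zstack([a, b], cfg, seed=0, allow_merge=True)  # no raise


class TestFrap:
    def make(self, mode, bleach_depth=1.0, retention=1.0, seed=0):
        cfg = AcquisitionConfig(shot_noise=False, read_noise_sd=0.0,
                                background_level=0.0)
        return simulate_frap(0.5, mode, exchange_rate_per_min=0.5,
                             bleach_depth=bleach_depth, config=cfg,
                             duration_min=10, seed=seed,
                             imaging_retention=retention)

    def test_no_exchange_full_bleach_stays_dark(self):
        stack, gt = self.make(FrapMode.NO_EXCHANGE, bleach_depth=1.0)
        post = stack.data[gt.true_parameters["bleach_frame"]:, 0, 0]
        assert np.all(post == 0)

    def test_interior_mixing_is_uniform(self):
        stack, gt = self.make(FrapMode.INTERIOR_MIXING, bleach_depth=0.9)
        p = gt.true_parameters
        disk = gt.true_masks[0]
        for t in range(p["bleach_frame"] + 1, stack.n_frames):
            vals = stack.data[t, 0, 0][disk]
            assert vals.std() < 1e-9  # uniform by construction

    def test_surface_accretion_concentrates_in_shell(self):
        from incluflux.flux import shell_core_ratio

        stack, gt = self.make(FrapMode.SURFACE_ACCRETION, bleach_depth=0.9)
        p = gt.true_parameters
        r_px = p["radius_um"] / 0.1
        ratio = shell_core_ratio(stack.data[p["bleach_frame"] + 1, 0, 0],
                                 p["center_px"], r_px, shell_fraction=0.2)
        assert ratio > 2.0

    def test_invalid_rates(self):
        cfg = AcquisitionConfig(shot_noise=False, read_noise_sd=0.0)
        with pytest.raises(ValueError):
            simulate_frap(0.5, "interior_mixing", -1.0, 0.5, cfg, 5, seed=0)
        with pytest.raises(ValueError):
            simulate_frap(0.5, "interior_mixing", 0.5, 1.5, cfg, 5, seed=0)


def _quiet_two_channel(retention=(1.0, 1.0)):
    return AcquisitionConfig(
        shot_noise=False, read_noise_sd=0.0,
        channels=("green", "red"),
        bleach_retention_per_exposure={"green": retention[0], "red": retention[1]},
    )


class TestPulseChase:
    def test_red_conservation_without_degradation(self):
        model = PulseChaseModel(k_deg_per_min=0.0, division_times_min=())
        s = simulate_pulse_chase(model, _quiet_two_channel(), 120, 10, seed=0)
        red = s.channel("red")
        total = (red["ib_integrated"]
                 + red["cyto_mean"] * s.meta["cyto_volume_au"]).to_numpy()
        assert np.allclose(total, total[0], rtol=1e-9)

    def test_one_way_transfer_monotone_to_asymptote(self):
        model = PulseChaseModel(k_out_per_min=0.0, k_deg_per_min=0.0,
                                division_times_min=())
        s = simulate_pulse_chase(model, _quiet_two_channel(), 400, 10, seed=0)
        ib = s.channel("red")["ib_integrated"].to_numpy()
        assert np.all(np.diff(ib) >= -1e-12)
        # approaches the full-cohort asymptote
        asymptote = s.meta["model"].conversion_fraction * (
            s.meta["model"].cyto0_au + s.meta["model"].ib0_au)
        assert ib[-1] == pytest.approx(asymptote, rel=0.02)

    def test_turnover_shape_rise_then_fall(self):
        model = PulseChaseModel()  # k_out, k_deg > 0
        s = simulate_pulse_chase(model, _quiet_two_channel(), 270, 10, seed=0)
        ib = s.channel("red")["ib_integrated"].to_numpy()
        i_max = int(np.argmax(ib))
        assert 0 < i_max < len(ib) - 1
        assert ib[-1] < ib[i_max]

    def test_mass_balance_across_divisions(self):
        model = PulseChaseModel(k_deg_per_min=0.0, synthesis_rate_au_min=0.0,
                                division_times_min=(40.0, 90.0, 140.0))
        s = simulate_pulse_chase(model, _quiet_two_channel(), 180, 10, seed=0)
        fp = s.meta["final_pools"]
        for color, c_key, i_key in (("red", "red_cyto", "red_ib"),
                                    ("green", "green_cyto", "green_ib")):
            total = fp[c_key] + fp[i_key] + s.meta["daughter_au"][color]
            frac = {"red": model.conversion_fraction,
                    "green": 1 - model.conversion_fraction}[color]
            assert total == pytest.approx(
                frac * (model.cyto0_au + model.ib0_au), rel=1e-9)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            simulate_pulse_chase(PulseChaseModel(), _quiet_two_channel(), 5, 10, seed=0)

    def test_noise_seed_determinism(self):
        model = PulseChaseModel()
        a = simulate_pulse_chase(model, _quiet_two_channel(), 60, 10, seed=4,
                                 noise_sd_frac=0.05)
        b = simulate_pulse_chase(model, _quiet_two_channel(), 60, 10, seed=4,
                                 noise_sd_frac=0.05)
        assert a.data.equals(b.data)
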