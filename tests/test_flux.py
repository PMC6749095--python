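"""FRAP/pulse-chase quantitation: bleach calibration and correction,
mask-based intensity bookkeeping, dilution prediction, regressions,
turnover summaries and kinetic parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from incluflux.flux import (
    DilutionModel,
    correct_bleaching,
    fit_bleach_decay,
    fit_pulse_chase_rates,
    frap_quantify,
    normalize_pulse_chase,
    predict_dilution,
    pulse_chase_quantify,
    recovery_regression,
    shell_core_ratio,
    turnover_summary,
)
from incluflux.simulate import (
    AcquisitionConfig,
    PulseChaseModel,
    simulate_frap,
    simulate_pulse_chase,
)
from incluflux.types import BleachDecayModel, CellMeasurement, FluxSeries, ImageStack


def quiet_cfg(**kw):
    base = dict(shot_noise=False, read_noise_sd=0.0, background_level=0.0)
    base.update(kw)
    return AcquisitionConfig(**base)


def two_channel_cfg(retention=(1.0, 1.0)):
    return AcquisitionConfig(
        shot_noise=False, read_noise_sd=0.0, channels=("green", "red"),
        bleach_retention_per_exposure={"green": retention[0], "red": retention[1]})


def make_series(times, values, channel="red", cyto=None):
    rows = []
    for i, (t, v) in enumerate(zip(times, values)):
        rows.append({"time_min": t, "channel": channel, "ib_area_um2": 1.0,
                     "ib_mean": v, "ib_integrated": v,
                     "cyto_mean": cyto[i] if cyto is not None else 1.0,
                     "corrected": False})
    return FluxSeries(data=pd.DataFrame(rows))


class TestBleachDecay:
    def test_exact_geometric_series(self):
        m = fit_bleach_decay([1, 0.9, 0.81, 0.729])
        assert m.retention_per_cycle == pytest.approx(0.900, abs=1e-9)
        assert m.fit_r_squared == pytest.approx(1.0, abs=1e-9)
        assert m.decay_rate == pytest.approx(-np.log(0.9), rel=1e-9)

    def test_constant_series_retention_one(self):
        m = fit_bleach_decay([1.0, 1.0, 1.0, 1.0])
        assert m.retention_per_cycle == 1.0

    def test_recovers_generator_retention_with_noise(self):
        rng = np.random.default_rng(2)
        series = 0.95 ** np.arange(10) * (1 + rng.normal(0, 0.01, 10))
        m = fit_bleach_decay(series)
        assert 0.94 <= m.retention_per_cycle <= 0.96

    def test_needs_three_cycles(self):
        with pytest.raises(ValueError):
            fit_bleach_decay([1.0, 0.9])


class TestCorrectBleaching:
    def test_inverse_of_geometric_decay(self):
        s = make_series([0, 10, 20, 30], [1.0, 0.9, 0.81, 0.729])
        m = BleachDecayModel(retention_per_cycle=0.9, fit_r_squared=1.0, channel="red")
        corr = correct_bleaching(s, m)
        vals = corr.channel("red")["ib_integrated"].to_numpy()
        assert np.allclose(vals, 1.0, rtol=1e-12)
        assert corr.channel("red")["corrected"].all()

    def test_retention_one_is_identity(self):
        s = make_series([0, 10, 20], [1.0, 0.8, 0.7])
        m = BleachDecayModel(1.0, 1.0, channel="red")
        corr = correct_bleaching(s, m)
        assert np.allclose(corr.channel("red")["ib_integrated"], [1.0, 0.8, 0.7])

    def test_simulator_round_trip(self):
        # correcting a bleached simulation reproduces the unbleached one
        model = PulseChaseModel(division_times_min=())
        bleached = simulate_pulse_chase(model, two_channel_cfg((0.97, 0.96)),
                                        270, 10, seed=1)
        clean = simulate_pulse_chase(model, two_channel_cfg((1.0, 1.0)),
                                     270, 10, seed=1)
        corr = correct_bleaching(bleached, BleachDecayModel(0.96, 1.0, "red"))
        for col in ("ib_integrated", "cyto_mean"):
            a = corr.channel("red")[col].to_numpy()
            b = clean.channel("red")[col].to_numpy()
            assert np.max(np.abs(a / b - 1)) < 1e-6

    def test_explicit_cycle_counts(self):
        s = make_series([0, 10], [1.0, 0.81])
        m = BleachDecayModel(0.9, 1.0, channel="red")
        corr = correct_bleaching(s, m, cycles_elapsed=[0, 2])  # z-plane counting
        assert corr.channel("red")["ib_integrated"].iloc[1] == pytest.approx(1.0)


class TestFrapQuantify:
    def run_frap(self, mode, **kw):
        cfg = quiet_cfg(background_level=5.0)
        stack, gt = simulate_frap(0.5, mode, exchange_rate_per_min=0.5,
                                  bleach_depth=0.9, config=cfg,
                                  duration_min=10, seed=0, **kw)
        return stack, gt, cfg

    def test_integrated_is_area_times_mean(self):
        stack, gt, cfg = self.run_frap("interior_mixing")
        cell = CellMeasurement(cytoplasm_mean=5.2, background=5.0)
        fs = frap_quantify(stack, cell, k_threshold=1.4)
        df = fs.data
        assert np.allclose(df["ib_integrated"], df["ib_area_um2"] * df["ib_mean"])

    def test_axis_ratio_arithmetic(self):
        assert 900 / 1100 == pytest.approx(0.818, abs=5e-4)

    def test_interior_mixing_diameter_recovers_uniformly(self):
        stack, gt, cfg = self.run_frap("interior_mixing")
        p = gt.true_parameters
        cell = CellMeasurement(cytoplasm_mean=5.2, background=5.0)
        fs = frap_quantify(stack, cell, k_threshold=1.4,
                           pre_bleach_index=0,
                           times_min=p["times_min"])
        ratios = fs.data["diameter_ratio"].to_numpy()
        post = ratios[p["bleach_frame"]:]
        assert np.all(np.diff(post) >= -1e-9)  # non-decreasing recovery
        # spatial uniformity during recovery
        r_px = p["radius_um"] / cfg.pixel_size_um
        for t in range(p["bleach_frame"] + 2, stack.n_frames):
            sc = shell_core_ratio(stack.data[t, 0, 0], p["center_px"], r_px,
                                  shell_fraction=0.2, background=5.0)
            assert sc < 1.1

    def test_missing_ib_records_zero_not_error(self):
        stack, gt, cfg = self.run_frap("no_exchange")
        cell = CellMeasurement(cytoplasm_mean=5.2, background=5.0)
        fs = frap_quantify(stack, cell, k_threshold=1.4)
        post = fs.data.iloc[gt.true_parameters["bleach_frame"]:]
        assert (post["ib_area_um2"] == 0).any()
        assert (post["diameter_ratio"] == 0).any()


class TestPulseChaseQuantify:
    def make_stack(self):
        # two-channel toy stack: green disk left, red disk right
        t_frames = []
        for t in range(3):
            green = np.full((32, 32), 10.0)
            red = np.full((32, 32), 8.0)
            yy, xx = np.mgrid[0:32, 0:32]
            gmask = (xx - 12) ** 2 + (yy - 16) ** 2 <= 16
            rmask = (xx - 18) ** 2 + (yy - 16) ** 2 <= 16
            green[gmask] = 40.0
            red[rmask] = 30.0
            t_frames.append(np.stack([green[None], red[None]], axis=1))
        data = np.stack(t_frames)  # (T, Z=1, C=2, Y, X)
        return ImageStack(data=data, pixel_size_um=0.1), gmask, rmask

    def test_union_mask_superset_of_each(self):
        stack, gmask, rmask = self.make_stack()
        cells = {"green": CellMeasurement(cytoplasm_mean=10.0),
                 "red": CellMeasurement(cytoplasm_mean=8.0)}
        fs = pulse_chase_quantify(stack, cells, k_threshold=1.5)
        union_area = fs.data["ib_area_um2"].iloc[0]
        assert union_area >= gmask.sum() * 0.01 - 1e-9
        assert union_area >= rmask.sum() * 0.01 - 1e-9
        assert union_area == pytest.approx((gmask | rmask).sum() * 0.01, rel=1e-9)

    def test_lower_threshold_never_shrinks_mask(self):
        stack, _, _ = self.make_stack()
        cells = {"green": CellMeasurement(cytoplasm_mean=10.0),
                 "red": CellMeasurement(cytoplasm_mean=8.0)}
        a = pulse_chase_quantify(stack, cells, k_threshold=1.5).data["ib_area_um2"].iloc[0]
        b = pulse_chase_quantify(stack, cells, k_threshold=1.2).data["ib_area_um2"].iloc[0]
        assert b >= a

    def test_missing_channel_rejected(self):
        stack, _, _ = self.make_stack()
        with pytest.raises(ValueError):
            pulse_chase_quantify(stack, {"green": CellMeasurement(cytoplasm_mean=10.0)})

    def test_red_conserved_simulation_non_decreasing(self):
        model = PulseChaseModel(k_out_per_min=0.0, k_deg_per_min=0.0)
        s = simulate_pulse_chase(model, two_channel_cfg(), 300, 10, seed=0)
        ib = s.channel("red")["ib_integrated"].to_numpy()
        assert np.all(np.diff(ib) >= -1e-12)

    def test_corrected_red_rises_then_falls_and_uncorrected_falls_faster(self):
        model = PulseChaseModel()  # k_out, k_deg > 0
        s = simulate_pulse_chase(model, two_channel_cfg((0.98, 0.97)), 270, 10, seed=0)
        corr = correct_bleaching(s, BleachDecayModel(0.97, 1.0, "red"))
        raw = s.channel("red")["ib_integrated"].to_numpy()
        fix = corr.channel("red")["ib_integrated"].to_numpy()
        i_max = int(np.argmax(fix))
        assert 0 < i_max < len(fix) - 1 and fix[-1] < fix[i_max]
        assert raw[-1] < fix[-1]  # uncorrected declines faster

    def test_normalization_ranges(self):
        model = PulseChaseModel()
        s = simulate_pulse_chase(model, two_channel_cfg(), 270, 10, seed=0)
        norm = normalize_pulse_chase(s)
        red = norm.channel("red")["ib_integrated"].to_numpy()
        green = norm.channel("green")["ib_integrated"].to_numpy()
        assert red.min() >= 0 and red.max() <= 1 + 1e-12
        assert green[0] == pytest.approx(1.0)


class TestDilution:
    def test_factor_3_7_gives_27_percent(self):
        out = predict_dilution(3.7)
        assert out["predicted_percent"] == pytest.approx(27.0, abs=0.05)

    @pytest.mark.parametrize("factor,frac", [(1.0, 1.0), (2.0, 0.5)])
    def test_simple_factors(self, factor, frac):
        assert predict_dilution(factor)["predicted_fraction"] == pytest.approx(frac)

    def test_alternative_compounded_derivation_reported(self):
        out = predict_dilution(DilutionModel(3.7, n_cycles=2.2, daughter_fraction=0.7))
        assert out["alternative_compounded_factor"] == pytest.approx(1.7**2.2, rel=1e-9)
        assert "alternative" in out["alternative_note"]

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            predict_dilution(0.5)


class TestRecoveryRegression:
    def test_exact_line(self):
        x = np.arange(3, 10, dtype=float)
        out = recovery_regression(2 * x + 1, x, np.arange(7) + 0.5)
        assert out["cytoplasm"]["slope"] == pytest.approx(2.0)
        assert out["cytoplasm"]["intercept"] == pytest.approx(1.0)
        assert out["cytoplasm"]["r_squared"] == pytest.approx(1.0)

    def test_independent_predictor_r2_zero(self):
        rng = np.random.default_rng(0)
        y = np.full(10, 5.0)
        x = rng.uniform(0, 1, 10)
        out = recovery_regression(y, x, rng.uniform(0, 1, 10))
        assert out["cytoplasm"]["r_squared"] == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_cohort_dependence_structure(self):
        # recovery generated ∝ cytoplasm with 20% noise, independent of
        # pre-bleach totals
        rng = np.random.default_rng(0)
        cyto = rng.uniform(20, 200, 12)
        pre = rng.uniform(200, 600, 12)
        recovered = 2.0 * cyto * (1 + rng.normal(0, 0.2, 12))
        out = recovery_regression(recovered, cyto, pre)
        assert out["cytoplasm"]["r_squared"] > 0.7
        assert out["pre_bleach"]["r_squared"] < 0.2


class TestTurnover:
    def test_arithmetic_example(self):
        s = make_series([0, 10, 20], [1.0, 2.0, 1.3])
        t_max, drop = turnover_summary(s, "red")
        assert t_max == 10 and drop == pytest.approx(35.0)

    def test_monotone_rise_zero_drop(self):
        s = make_series([0, 10, 20], [1.0, 1.5, 2.0])
        t_max, drop = turnover_summary(s, "red")
        assert t_max == 20 and drop == 0.0

    def test_drop_matches_closed_form_two_pool_solution(self):
        # closed-form linear-ODE oracle (matrix exponential) vs simulation
        from scipy.linalg import expm

        model = PulseChaseModel(division_times_min=())
        s = simulate_pulse_chase(model, two_channel_cfg(), 270, 10, seed=0)
        t_max, drop = turnover_summary(s, "red")
        A = np.array([[-(model.k_in_per_min + model.k_deg_per_min),
                       model.k_out_per_min],
                      [model.k_in_per_min, -model.k_out_per_min]])
        x0 = np.array([model.cyto0_au, model.ib0_au]) * model.conversion_fraction
        ts = np.arange(0, 271, 10)
        ib = np.array([(expm(A * t) @ x0)[1] for t in ts])
        drop_oracle = 100 * (ib.max() - ib[-1]) / ib.max()
        assert abs(drop - drop_oracle) < 5.0


class TestParameterRecovery:
    def test_rates_recovered_within_15pct(self):
        model = PulseChaseModel(division_times_min=())
        errs = []
        for seed in range(5):
            s = simulate_pulse_chase(model, two_channel_cfg(), 270, 10,
                                     seed=seed, noise_sd_frac=0.02)
            red = s.channel("red")
            fit = fit_pulse_chase_rates(
                red["time_min"].to_numpy(),
                red["cyto_mean"].to_numpy() * s.meta["cyto_volume_au"],
                red["ib_integrated"].to_numpy())
            errs.append([
                abs(fit["k_in_per_min"] / model.k_in_per_min - 1),
                abs(fit["k_out_per_min"] / model.k_out_per_min - 1),
                abs(fit["k_deg_per_min"] / model.k_deg_per_min - 1)])
        assert np.array(errs).mean(axis=0).max() < 0.15
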