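"""Absorbance conversion, chromophore regression and StO2 inversion."""

import numpy as np
import pytest

from neuroreflect.inversion import (
    ConditioningError,
    HemoglobinInverter,
    Spectrum,
    absorbance,
    estimates_to_frame,
    forward_reflectance_spectrum,
    oxygen_saturation,
    regress_chromophores,
)
from neuroreflect.tissue_optics import ChromophoreTable, extinction

WL = np.arange(500.0, 621.0, 5.0)


class TestAbsorbance:
    @pytest.mark.parametrize("refl, expected", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_decade_definition(self, refl, expected):
        spec = Spectrum(WL, np.full(WL.size, refl))
        assert np.allclose(absorbance(spec), expected)

    def test_round_trip_to_machine_precision(self, rng):
        r = rng.uniform(0.05, 1.0, WL.size)
        spec = Spectrum(WL, r)
        assert np.allclose(10.0 ** (-absorbance(spec)), r, rtol=1e-14)

    def test_non_positive_reflectance_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(WL, np.zeros(WL.size))


class TestRegression:
    def test_exact_linear_model_recovered(self, table):
        eo = extinction(table, WL, "HbO")
        er = extinction(table, WL, "HbR")
        A = 0.7 * eo + 0.2 * er + 0.05
        c = regress_chromophores(WL, A, table)
        assert np.allclose(c.as_array(), [0.7, 0.2, 0.05], atol=1e-12)

    def test_pure_component(self, table):
        A = extinction(table, WL, "HbO")
        c = regress_chromophores(WL, A, table)
        assert np.allclose(c.as_array(), [1.0, 0.0, 0.0], atol=1e-12)

    def test_matches_normal_equations_oracle(self, table, rng):
        eo = extinction(table, WL, "HbO")
        er = extinction(table, WL, "HbR")
        A = 0.4 * eo + 0.3 * er + 0.1 + rng.normal(0, 0.01, WL.size)
        c = regress_chromophores(WL, A, table)
        X = np.column_stack([eo, er, np.ones_like(WL)])
        oracle = np.linalg.solve(X.T @ X, X.T @ A)
        assert np.allclose(c.as_array(), oracle, atol=1e-10)

    def test_narrow_window_rejected(self, table):
        with pytest.raises(ValueError, match="10"):
            regress_chromophores(WL, np.ones(WL.size), table, window=(500.0, 520.0))

    def test_collinear_design_raises_conditioning_error(self):
        wl = np.linspace(500, 620, 25)
        eps = np.linspace(1.0, 2.0, 25)
        degenerate = ChromophoreTable(wl, eps, eps)  # HbO == HbR
        with pytest.raises(ConditioningError):
            regress_chromophores(wl, np.ones(25), degenerate)


class TestOxygenSaturation:
    @pytest.mark.parametrize("co, cr, expected", [
        (1.0, 1.0, 0.5), (2.5, 0.0, 1.0), (0.03, 0.02, 0.6)])
    def test_defining_formula(self, co, cr, expected):
        assert oxygen_saturation(co, cr) == pytest.approx(expected)

    def test_undefined_for_zero_total(self):
        with pytest.raises(ValueError):
            oxygen_saturation(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            oxygen_saturation(-0.1, 0.2)


class TestConversionModel:
    def test_quality_floor_on_concentration_targets(self, diffusion_inverter):
        assert np.all(diffusion_inverter.conversion_model_.r2[:2] >= 0.95)

    def test_in_sample_interior_grid_point(self, diffusion_inverter):
        """The map reproduces an interior grid point's own truth within 5%."""
        m = diffusion_inverter.conversion_model_
        interior = np.flatnonzero(
            np.isclose(m.targets[:, 0], 0.0466667) &
            np.isclose(m.targets[:, 1], 0.0833333) &
            np.isclose(m.targets[:, 2], 2.0))[0]
        from neuroreflect.inversion import RegressionCoefficients

        mapped, _ = m.evaluate(RegressionCoefficients(*m.alphas[interior]))
        rel = np.abs(mapped[:2] - m.targets[interior, :2]) / m.targets[interior, :2]
        assert np.all(rel < 0.05)

    def test_degenerate_single_a_level(self):
        inv = HemoglobinInverter(forward="diffusion", grid_a=(2.0,)).fit()
        spec = forward_reflectance_spectrum(0.06, 0.04, 2.0, forward="diffusion")
        est = inv.invert(spec)
        assert est.a == pytest.approx(2.0)
        assert est.StO2 == pytest.approx(0.6, abs=0.03)

    def test_too_few_grid_levels_rejected(self):
        with pytest.raises(ValueError):
            HemoglobinInverter(forward="diffusion", grid_C_HbO=(0.01, 0.1)).fit()


class TestRoundTrip:
    def test_interior_point_concentration_recovery(self, diffusion_inverter):
        spec = forward_reflectance_spectrum(0.06, 0.04, 2.0, forward="diffusion")
        est = diffusion_inverter.invert(spec)
        assert abs(est.C_HbO - 0.06) / 0.06 < 0.10
        assert abs(est.C_HbR - 0.04) / 0.04 < 0.10
        assert abs(est.StO2 - 0.6) < 0.05

    def test_recovery_battery_20_interior_points(self, diffusion_inverter):
        """Median |StO2 error| <= 3 points, max <= 8, over random interior truths."""
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(20):
            co = rng.uniform(0.025, 0.105)
            cr = rng.uniform(0.025, 0.105)
            a = rng.uniform(1.3, 2.7)
            est = diffusion_inverter.invert(
                forward_reflectance_spectrum(co, cr, a, forward="diffusion"))
            errs.append(abs(est.StO2 - co / (co + cr)) * 100.0)
        assert np.median(errs) <= 3.0
        assert max(errs) <= 8.0

    def test_scale_consistency_sto2_unbiased_under_scattering_changes(
            self, diffusion_inverter):
        """Changing the tissue's scattering amplitude alone must not bias
        StO2 by more than 3 points (the amplitude itself is only weakly
        identified at a single fiber separation)."""
        for a in (1.2, 1.8, 2.7):
            est = diffusion_inverter.invert(
                forward_reflectance_spectrum(0.06, 0.04, a, forward="diffusion"))
            assert abs(est.StO2 - 0.6) * 100.0 <= 3.0

    def test_zero_deoxy_truth_gives_high_saturation(self, diffusion_inverter):
        est = diffusion_inverter.invert(
            forward_reflectance_spectrum(0.06, 0.0, 2.0, forward="diffusion"))
        assert est.StO2 >= 0.9

    def test_sto2_clipped_to_unit_interval(self, diffusion_inverter):
        est = diffusion_inverter.invert(
            forward_reflectance_spectrum(0.1, 0.001, 2.0, forward="diffusion"))
        assert 0.0 <= est.StO2 <= 1.0

    def test_extrapolation_flagged(self, diffusion_inverter):
        spec = forward_reflectance_spectrum(0.4, 0.3, 2.0, forward="diffusion")
        est = diffusion_inverter.invert(spec)
        assert est.extrapolated

    def test_three_phase_trajectory_recovered(self, diffusion_inverter):
        """Baseline -> transient rise -> sustained fall, within 1 point
        noiseless with the analytic forward on both sides."""
        from neuroreflect.synthetic import fig8_like_trajectory, gen_forward_spectrum_series

        traj = fig8_like_trajectory()
        ser = gen_forward_spectrum_series(traj, forward="diffusion", noise_sd=0.0)
        est = np.array([
            diffusion_inverter.invert(Spectrum(ser.wavelengths, ser.reflectance[:, k])).StO2
            for k in range(ser.time_s.size)])
        truth = traj[:, 0] / (traj[:, 0] + traj[:, 1])
        assert np.max(np.abs(est - truth)) * 100.0 <= 1.0
        # three-phase shape: baseline < transient, hypoxemic < baseline
        assert est[:8].mean() < est[8:16].mean()
        assert est[-10:].mean() < est[:8].mean() - 0.15


class TestApi:
    def test_predict_and_frame(self, diffusion_inverter):
        specs = [forward_reflectance_spectrum(0.06, 0.04, 2.0, forward="diffusion"),
                 forward_reflectance_spectrum(0.035, 0.065, 2.0, forward="diffusion")]
        sto2 = diffusion_inverter.predict(specs)
        assert sto2.shape == (2,)
        df = estimates_to_frame([0.0, 10.0],
                                diffusion_inverter.predict_estimates(specs))
        assert list(df.columns[:3]) == ["time_s", "C_HbO_mM", "C_HbR_mM"]
        assert np.allclose(df["C_THb_mM"], df["C_HbO_mM"] + df["C_HbR_mM"])

    def test_get_params_round_trip(self):
        inv = HemoglobinInverter(forward="diffusion")
        params = inv.get_params(deep=False)
        assert params["forward"] == "diffusion"
        inv2 = HemoglobinInverter(**params)
        assert inv2.get_params(deep=False) == params
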