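"""Band-signal construction and SD event detectors against generator truth."""

import numpy as np
import pytest

from neuroreflect.ratiometrics import (
    SpectrumTimeSeries,
    Trace,
    band_ratio,
    baseline_normalize,
    classify_recording,
    detect_dc_shift,
    detect_eeg_suppression,
    detect_heme_reduction,
    detect_long_hypoxemia,
    detect_scattering_event,
    detect_turning_point,
)
from neuroreflect.synthetic import SdEventProfile, gen_trace_bundle


def _norm(tr):
    return baseline_normalize(tr)


class TestBaselineNormalize:
    def test_constant_trace_maps_to_one(self):
        t = np.arange(-100.0, 100.0)
        tr = baseline_normalize(Trace(t, np.full(t.size, 7.3)))
        assert np.allclose(tr.value, 1.0)

    def test_scale_invariance(self, bundle):
        tr = bundle["r569"]
        scaled = Trace(tr.time_s, 13.7 * tr.value)
        assert np.allclose(baseline_normalize(tr).value,
                           baseline_normalize(scaled).value, rtol=1e-12)

    def test_generator_baseline_within_tolerance(self, bundle):
        tr = baseline_normalize(bundle["r569"])
        pre = tr.value[(tr.time_s >= -60) & (tr.time_s <= 0)]
        assert pre.mean() == pytest.approx(1.0, abs=1e-3)

    def test_post_stimulus_window_rejected(self):
        t = np.arange(-100.0, 100.0)
        with pytest.raises(ValueError):
            baseline_normalize(Trace(t, np.ones(t.size)), (10.0, 60.0))


class TestBandRatio:
    @pytest.fixture()
    def series(self):
        wl = np.array([569.0, 578.0, 605.0, 620.0, 805.0])
        t = np.arange(-30.0, 60.0)
        refl = np.tile(np.array([0.4, 0.35, 0.5, 0.55, 0.6])[:, None], (1, t.size))
        refl[1, t >= 20.0] *= 1.1  # oxygenation step at t = 20 s
        return SpectrumTimeSeries(wl, t, refl)

    def test_self_ratio_is_one(self, series):
        tr = band_ratio(series, 569.0, 569.0)
        assert np.allclose(tr.value, 1.0)

    def test_common_mode_rejection(self, series):
        doubled = SpectrumTimeSeries(series.wavelengths, series.time_s,
                                     2.0 * series.reflectance)
        assert np.allclose(band_ratio(series, 578.0, 569.0).value,
                           band_ratio(doubled, 578.0, 569.0).value)

    def test_step_time_reproduced(self, series):
        tr = band_ratio(series, 578.0, 569.0)
        step_idx = int(np.argmax(np.abs(np.diff(tr.value))))
        assert abs(tr.time_s[step_idx + 1] - 20.0) <= 1.0

    def test_single_band_and_tolerance(self, series):
        tr = band_ratio(series, 806.0)  # within the 2 nm nearest-node tolerance
        assert np.allclose(tr.value, 0.6)
        with pytest.raises(ValueError):
            band_ratio(series, 700.0)


class TestTurningPoint:
    def test_programmed_crossing_recovered(self):
        t = np.arange(-60.0, 400.0)
        v = np.interp(t, [-60, 0, 100, 250, 400], [1.0, 1.0, 1.05, 1.0, 0.95])
        tp = detect_turning_point(Trace(t, v))
        assert tp == pytest.approx(250.0, abs=1.0)

    def test_monotone_trace_returns_none(self):
        t = np.arange(-60.0, 400.0)
        assert detect_turning_point(Trace(t, 1.0 + 0.001 * np.clip(t, 0, None))) is None

    def test_multichannel_first_channel_near_three_minutes(self):
        from neuroreflect.synthetic import gen_multichannel

        ch1 = _norm(gen_multichannel(seed=5)[0])
        tp = detect_turning_point(ch1)
        assert tp == pytest.approx(180.0, abs=15.0)


class TestScatteringDetector:
    def test_programmed_duration_recovered(self, bundle):
        ev = detect_scattering_event(_norm(bundle["r805"]))
        assert ev.detected
        assert ev.duration_s == pytest.approx(240.0, abs=15.0)

    def test_flat_noise_not_detected(self):
        rng = np.random.default_rng(0)
        t = np.arange(-60.0, 600.0)
        tr = Trace(t, 1.0 + rng.normal(0, 0.002, t.size))
        assert not detect_scattering_event(tr).detected

    def test_polarity_invariance(self):
        a = gen_trace_bundle(SdEventProfile(seed=7), scattering_polarity=1.0)["r805"]
        b = gen_trace_bundle(SdEventProfile(seed=7), scattering_polarity=-1.0)["r805"]
        ev_a = detect_scattering_event(_norm(a))
        ev_b = detect_scattering_event(_norm(b))
        assert ev_a.detected == ev_b.detected
        assert ev_a.duration_s == pytest.approx(ev_b.duration_s, abs=10.0)


class TestEegDetector:
    def test_programmed_suppression_recovered(self, bundle):
        ev = detect_eeg_suppression(bundle["eeg"], fs_hz=100.0)
        assert ev.detected
        assert ev.duration_s == pytest.approx(420.0, abs=30.0)

    def test_stationary_noise_not_detected(self):
        rng = np.random.default_rng(1)
        t = np.arange(-60.0, 600.0, 0.01)
        tr = Trace(t, 0.05 * rng.normal(0, 1, t.size))
        assert not detect_eeg_suppression(tr, fs_hz=100.0).detected

    @pytest.mark.parametrize("residual", [0.1, 0.25, 0.4])
    def test_duration_across_suppression_depths(self, residual):
        prof = SdEventProfile(seed=11)
        prof.eeg_suppression["depth_frac"] = 1.0 - residual
        ev = detect_eeg_suppression(gen_trace_bundle(prof)["eeg"], fs_hz=100.0)
        assert ev.detected
        assert ev.duration_s == pytest.approx(420.0, abs=10.0 + 5.0)

    def test_short_trace_rejected(self):
        t = np.arange(-1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            detect_eeg_suppression(Trace(t, np.ones(t.size)), fs_hz=2.0)


class TestDcDetector:
    def test_programmed_shift_recovered(self, bundle):
        m = detect_dc_shift(bundle["dc"])
        assert m.max_negative_shift_mV == pytest.approx(7.2, abs=0.3)
        assert m.time_to_min_s is not None

    def test_onset_within_ten_seconds_over_seeds(self):
        for seed in range(5):
            dc = gen_trace_bundle(SdEventProfile(seed=seed))["dc"]
            m = detect_dc_shift(dc)
            assert m.onset_s == pytest.approx(120.0, abs=10.0)

    def test_flat_trace_no_shift_no_onset(self):
        t = np.arange(-120.0, 300.0, 0.1)
        m = detect_dc_shift(Trace(t, np.zeros(t.size)))
        assert abs(m.max_negative_shift_mV) < 0.05
        assert m.onset_s is None


class TestHypoxemiaDetector:
    def test_programmed_long_hypoxemia(self, bundle):
        ev = detect_long_hypoxemia(_norm(bundle["oxy"]))
        assert ev.detected
        assert ev.duration_s == pytest.approx(5400.0, abs=60.0)

    def test_brief_dip_not_detected(self):
        prof = SdEventProfile(seed=2)
        prof.hypoxemia_phase["duration_s"] = 120.0
        ev = detect_long_hypoxemia(_norm(gen_trace_bundle(prof)["oxy"]))
        assert not ev.detected

    @pytest.mark.parametrize("programmed, expect", [(1620.0, False), (1980.0, True)])
    def test_detection_boundary_flips(self, programmed, expect):
        prof = SdEventProfile(seed=4)
        prof.hypoxemia_phase["duration_s"] = programmed
        ev = detect_long_hypoxemia(_norm(gen_trace_bundle(prof)["oxy"]))
        assert ev.detected is expect


class TestHemeDetector:
    def test_programmed_dip_recovered(self, bundle):
        ev = detect_heme_reduction(_norm(bundle["heme"]))
        assert ev.detected
        assert ev.onset_s == pytest.approx(90.0, abs=10.0)
        assert ev.duration_s == pytest.approx(180.0, abs=20.0)

    def test_no_dip_not_detected(self):
        rng = np.random.default_rng(5)
        t = np.arange(-60.0, 900.0)
        tr = Trace(t, 1.0 + rng.normal(0, 0.002, t.size))
        assert not detect_heme_reduction(tr).detected

    @pytest.mark.parametrize("seed", range(5))
    def test_recovery_under_noise_sweep(self, seed):
        """Noise SD up to 20% of the dip depth."""
        prof = SdEventProfile(seed=seed)
        prof.noise_sd["optical"] = 0.2 * prof.heme_dip["depth_frac"]
        ev = detect_heme_reduction(_norm(gen_trace_bundle(prof)["heme"]))
        assert ev.detected
        assert ev.onset_s == pytest.approx(90.0, abs=10.0)
        assert ev.duration_s == pytest.approx(180.0, abs=20.0)


class TestThresholdMonotonicity:
    """Raising a detector threshold never turns False into True."""

    def test_scattering(self, bundle):
        tr = _norm(bundle["r805"])
        det = [detect_scattering_event(tr, threshold_frac=f).detected
               for f in (0.01, 0.05, 0.1, 0.2, 0.5)]
        assert det == sorted(det, reverse=True)

    def test_hypoxemia_depth(self, bundle):
        tr = _norm(bundle["oxy"])
        det = [detect_long_hypoxemia(tr, depth_frac=d).detected
               for d in (0.01, 0.03, 0.06, 0.2)]
        assert det == sorted(det, reverse=True)

    def test_heme_threshold(self, bundle):
        tr = _norm(bundle["heme"])
        det = [detect_heme_reduction(tr, threshold_frac=f).detected
               for f in (0.005, 0.02, 0.05, 0.2)]
        assert det == sorted(det, reverse=True)

    def test_eeg_drop_frac(self, bundle):
        # lower drop_frac is the stricter threshold here
        det = [detect_eeg_suppression(bundle["eeg"], 100.0, drop_frac=f).detected
               for f in (0.9, 0.5, 0.1, 0.02)]
        assert det == sorted(det, reverse=True)


class TestClassification:
    def test_full_responder_all_true(self, bundle):
        traces = {k: (_norm(v) if k in ("r805", "oxy", "heme") else v)
                  for k, v in bundle.items() if k != "r569" and k != "dc"}
        row = classify_recording(traces, rat_id="r1", fluence_J_cm2=1.0)
        assert (row.scattering_change, row.eeg_suppression,
                row.long_hypoxemia, row.heme_reduction) == (True, True, True, True)

    def test_non_responder_all_false(self):
        flat = gen_trace_bundle(SdEventProfile.flat(seed=9))
        traces = {k: (_norm(v) if k in ("r805", "oxy", "heme") else v)
                  for k, v in flat.items() if k in ("r805", "eeg", "oxy", "heme")}
        row = classify_recording(traces)
        assert (row.scattering_change, row.eeg_suppression,
                row.long_hypoxemia, row.heme_reduction) == (False, False, False, False)

    def test_scattering_and_eeg_only_profile(self):
        """Mimics a cohort animal with SD but neither downstream event."""
        prof = SdEventProfile(seed=6)
        prof.hypoxemia_phase["depth_frac"] = 0.0
        prof.hyperemia_phase["depth_frac"] = 0.0
        prof.heme_dip["depth_frac"] = 0.0
        b = gen_trace_bundle(prof)
        traces = {k: (_norm(v) if k in ("r805", "oxy", "heme") else v)
                  for k, v in b.items() if k in ("r805", "eeg", "oxy", "heme")}
        row = classify_recording(traces)
        assert (row.scattering_change, row.eeg_suppression,
                row.long_hypoxemia, row.heme_reduction) == (True, True, False, False)

    def test_missing_modality_marked_none(self, bundle):
        row = classify_recording({"eeg": bundle["eeg"]})
        assert row.scattering_change is None
        assert row.eeg_suppression is True
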