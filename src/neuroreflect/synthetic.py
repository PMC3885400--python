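"""Synthetic-data generators for every input modality of the pipeline.

Each generator emulates the statistical structure the analysis assumes
for a cortical spreading-depolarization (SD) episode triggered by a
topical shock wave:

* a vigorous biphasic light-scattering transient (~4 min) with EEG
  suppression (~7 min);
* hyperemia/hyperoxemia turning into long-lasting (~1.5 h)
  oligemia/hypoxemia, with the oxygenation ratio crossing baseline at a
  programmed turning point (~4 min);
* a transient heme-aa3 reduction dip (onset ~1.5 min, ~3 min long);
* a negative DC-potential shift (~7.2 mV, ~30 s fall at ~2 min) with
  partial recovery;
* a radially expanding bright/dark scattering wave at millimeters per
  minute on NIR image stacks;
* distance-ordered oxygenation onsets across a multichannel fiber array.

Trace templates are piecewise cubic-smoothed step segments (default
smoothing constant 10 s) so that turning-point interpolation is
genuinely exercised; noise is additive Gaussian for traces,
multiplicative Gaussian for spectra and Poisson-approximate Gaussian for
images. Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratiometrics import SpectrumTimeSeries, Trace
from .wave_kinetics import ImageStack

__all__ = [
    "SdEventProfile",
    "gen_trace_bundle",
    "gen_forward_spectrum_series",
    "fig8_like_trajectory",
    "gen_wave_stack",
    "gen_multichannel",
    "gen_cohort",
    "REFERENCE_EVENT_RATES",
]

#: default smoothing time constant for trace templates, seconds
SMOOTHING_S = 10.0


def _smoothstep(t, t0, width):
    """Cubic ramp 0 -> 1 centered on t0 over ``width`` seconds."""
    x = np.clip((t - (t0 - width / 2.0)) / max(width, 1e-9), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _box(t, t_on, t_off, width):
    return _smoothstep(t, t_on, width) - _smoothstep(t, t_off, width)


@dataclass(frozen=True)
class SdEventProfile:
    """Programmed event parameters of one synthetic SD episode.

    Defaults transcribe the reference episode: 4-min scattering change,
    7-min EEG suppression, hyperoxemia turning to hypoxemia at 4 min,
    1.5-h hypoxemia, heme dip from 1.5 min lasting 3 min, and a 7.2-mV
    DC shift starting at 2 min with a 30-s fall.
    """

    scattering_event: dict = field(default_factory=lambda: dict(
        onset_s=5.0, duration_s=240.0, amplitude_frac=0.15))
    hyperemia_phase: dict = field(default_factory=lambda: dict(
        duration_s=230.0, depth_frac=0.03))
    hypoxemia_phase: dict = field(default_factory=lambda: dict(
        turning_point_s=240.0, duration_s=5400.0, depth_frac=0.05))
    heme_dip: dict = field(default_factory=lambda: dict(
        onset_s=90.0, duration_s=180.0, depth_frac=0.04))
    eeg_suppression: dict = field(default_factory=lambda: dict(
        onset_s=10.0, duration_s=420.0, depth_frac=0.8))
    dc_shift: dict = field(default_factory=lambda: dict(
        onset_s=120.0, fall_s=30.0, amplitude_mV=7.2, partial_recovery_frac=0.5))
    noise_sd: dict = field(default_factory=lambda: dict(
        optical=0.002, eeg_baseline_mV=0.05, dc_mV=0.05))
    smoothing_s: float = SMOOTHING_S
    seed: int = 0

    @staticmethod
    def flat(seed: int = 0) -> "SdEventProfile":
        """Zero-amplitude profile: all modalities stay at baseline."""
        return SdEventProfile(
            scattering_event=dict(onset_s=5.0, duration_s=240.0, amplitude_frac=0.0),
            hyperemia_phase=dict(duration_s=230.0, depth_frac=0.0),
            hypoxemia_phase=dict(turning_point_s=240.0, duration_s=5400.0, depth_frac=0.0),
            heme_dip=dict(onset_s=90.0, duration_s=180.0, depth_frac=0.0),
            eeg_suppression=dict(onset_s=10.0, duration_s=420.0, depth_frac=0.0),
            dc_shift=dict(onset_s=120.0, fall_s=30.0, amplitude_mV=0.0,
                          partial_recovery_frac=0.5),
            seed=seed,
        )


def _oxygenation_template(t, turning_point_s, rise_duration_s, rise_depth,
                          fall_duration_s, fall_depth, width):
    """Rise above baseline then sustained fall below it, crossing 1 at the
    programmed turning point (when rise and fall depths are equal; the
    crossing shifts by a small fraction of the smoothing width otherwise)."""
    rise = _box(t, turning_point_s - rise_duration_s, turning_point_s, width)
    fall = _box(t, turning_point_s, turning_point_s + fall_duration_s, width)
    return 1.0 + rise_depth * rise - fall_depth * fall


def gen_trace_bundle(profile: SdEventProfile | None = None,
                     fs_hz: dict | None = None,
                     t_start_s: float = -300.0,
                     t_end_s: float | None = None,
                     scattering_polarity: float = 1.0) -> dict:
    """Generate the six-channel trace set of one synthetic episode.

    Returns a dict with keys ``r805``, ``r569``, ``oxy`` (R_578/R_569),
    ``heme`` (R_605/R_620), ``eeg`` and ``dc``; optical traces are on a
    normalized scale (baseline 1), EEG and DC in mV.
    """
    p = profile or SdEventProfile()
    fs = {"optical": 1.0, "eeg": 100.0, "dc": 10.0}
    if fs_hz:
        fs.update(fs_hz)
    rng = np.random.default_rng(p.seed)
    hyp = p.hypoxemia_phase
    if t_end_s is None:
        t_end_s = hyp["turning_point_s"] + hyp["duration_s"] + 600.0
    w = p.smoothing_s

    def tgrid(f):
        return np.arange(t_start_s, t_end_s, 1.0 / f)

    out = {}

    # scattering R_805: oscillatory burst inside a smooth envelope
    t = tgrid(fs["optical"])
    sc = p.scattering_event
    env = _box(t, sc["onset_s"], sc["onset_s"] + sc["duration_s"], w)
    carrier = np.sin(2.0 * np.pi * (t - sc["onset_s"]) / 20.0)
    v = 1.0 + scattering_polarity * sc["amplitude_frac"] * env * carrier
    out["r805"] = Trace(t, v + rng.normal(0, p.noise_sd["optical"], t.size))

    # rCBV R_569: mirror of the oxygenation morphology (dips during hyperemia)
    hyper = p.hyperemia_phase
    v = 2.0 - _oxygenation_template(t, hyp["turning_point_s"], hyper["duration_s"],
                                    hyper["depth_frac"], hyp["duration_s"],
                                    hyp["depth_frac"], w)
    out["r569"] = Trace(t, v + rng.normal(0, p.noise_sd["optical"], t.size))

    # oxygenation R_578/R_569
    v = _oxygenation_template(t, hyp["turning_point_s"], hyper["duration_s"],
                              hyper["depth_frac"], hyp["duration_s"],
                              hyp["depth_frac"], w)
    out["oxy"] = Trace(t, v + rng.normal(0, p.noise_sd["optical"], t.size))

    # heme-aa3 ratio R_605/R_620: transient dip
    heme = p.heme_dip
    v = 1.0 - heme["depth_frac"] * _box(t, heme["onset_s"],
                                        heme["onset_s"] + heme["duration_s"], w)
    out["heme"] = Trace(t, v + rng.normal(0, p.noise_sd["optical"], t.size))

    # EEG: stationary noise with an amplitude-suppression epoch
    t = tgrid(fs["eeg"])
    ee = p.eeg_suppression
    amp = 1.0 - ee["depth_frac"] * _box(t, ee["onset_s"],
                                        ee["onset_s"] + ee["duration_s"], w)
    out["eeg"] = Trace(t, p.noise_sd["eeg_baseline_mV"] * amp * rng.normal(0, 1, t.size))

    # DC potential: steep negative shift, partial recovery, second decline
    t = tgrid(fs["dc"])
    dcp = p.dc_shift
    A = dcp["amplitude_mV"]
    rec = dcp["partial_recovery_frac"]
    t_fall_end = dcp["onset_s"] + dcp["fall_s"]
    v = (-A * _smoothstep(t, dcp["onset_s"] + dcp["fall_s"] / 2.0, dcp["fall_s"])
         + A * rec * _smoothstep(t, t_fall_end + 90.0, 120.0)
         - A * rec * _smoothstep(t, t_fall_end + 270.0, 120.0))
    v += 2.0 * np.exp(-0.5 * (t / 1.0) ** 2)  # brief stimulus artifact at t = 0
    out["dc"] = Trace(t, v + rng.normal(0, p.noise_sd["dc_mV"], t.size))

    return out


# -- spectra ---------------------------------------------------------------

def fig8_like_trajectory(n_times: int = 40,
                         baseline=(0.06, 0.04, 2.0),
                         transient=(0.07, 0.03, 2.2),
                         hypoxemic=(0.035, 0.065, 2.0),
                         n_baseline: int = 8, n_transient: int = 8) -> np.ndarray:
    """(C_HbO, C_HbR, a) trajectory: baseline (StO2 ~60%) -> transient
    hyperoxemia (~70%) -> sustained hypoxemia (~35%)."""
    segs = ([baseline] * n_baseline + [transient] * n_transient
            + [hypoxemic] * (n_times - n_baseline - n_transient))
    return np.array(segs, dtype=float)


def gen_forward_spectrum_series(trajectory: np.ndarray,
                                wavelengths=None,
                                forward: str = "diffusion",
                                noise_sd: float = 0.0,
                                seed: int = 0,
                                dt_s: float = 10.0,
                                stimulus_index: int = 8,
                                n_photons: int = 100_000,
                                box=((0.01, 0.12), (0.01, 0.12), (1.0, 3.0)),
                                ) -> SpectrumTimeSeries:
    """Forward-simulate a reflectance spectrum time series from a
    (C_HbO, C_HbR, a) truth trajectory.

    Uses the same forward family as the conversion model ('mc' or
    'diffusion'); noise is multiplicative Gaussian. The trajectory must
    stay inside the conversion-model box.
    """
    from .inversion import DEFAULT_WAVELENGTHS, forward_reflectance_spectrum

    traj = np.asarray(trajectory, dtype=float)
    for j, (lo, hi) in enumerate(box):
        if np.any(traj[:, j] < lo) or np.any(traj[:, j] > hi):
            raise ValueError("trajectory leaves the conversion-model box "
                             f"on axis {j} (allowed [{lo}, {hi}])")
    wl = np.asarray(DEFAULT_WAVELENGTHS if wavelengths is None else wavelengths,
                    dtype=float)
    rng = np.random.default_rng(seed)
    cache: dict[tuple, np.ndarray] = {}
    rows = []
    for k, (co, cr, a) in enumerate(traj):
        key = (round(co, 9), round(cr, 9), round(a, 9))
        if key not in cache:
            spec = forward_reflectance_spectrum(
                co, cr, a, wavelengths=wl, forward=forward,
                n_photons=n_photons, seed=seed + 37 * len(cache) + 11)
            cache[key] = spec.reflectance
        rows.append(cache[key] * (1.0 + rng.normal(0.0, noise_sd, wl.size))
                    if noise_sd > 0 else cache[key].copy())
    refl = np.clip(np.array(rows).T, 1e-12, 1.0)
    times = (np.arange(traj.shape[0]) - stimulus_index) * dt_s
    return SpectrumTimeSeries(wl, times, refl, stimulus_time_s=0.0)


# -- image stacks ----------------------------------------------------------

def gen_wave_stack(speed_mm_per_min: float = 2.4,
                   origin_px: tuple[int, int] = (170, 170),
                   pixel_pitch_mm: float = 0.05,
                   frame_interval_s: float = 5.0,
                   n_frames: int = 40,
                   shape: tuple[int, int] = (340, 340),
                   bright_amp: float = 30.0,
                   dark_amp: float = 15.0,
                   ring_width_mm: float = 0.8,
                   trail_gap_mm: float = 1.2,
                   background: float = 120.0,
                   wave_onset_s: float = 15.0,
                   noise_sd: float = 2.0,
                   seed: int = 0) -> ImageStack:
    """Radially expanding bright annulus trailed by a dark annulus on an
    8-bit NIR image stack (Poisson-approximate Gaussian noise)."""
    if speed_mm_per_min <= 0:
        raise ValueError("wave speed must be positive")
    rng = np.random.default_rng(seed)
    rows, cols = np.indices(shape)
    dist_mm = np.hypot(rows - origin_px[0], cols - origin_px[1]) * pixel_pitch_mm
    times = np.arange(n_frames) * frame_interval_s
    sigma = ring_width_mm / 2.3548  # FWHM -> Gaussian sigma
    frames = np.empty((n_frames,) + shape, dtype=np.uint8)
    for i, t in enumerate(times):
        img = np.full(shape, background, dtype=float)
        if t > wave_onset_s:
            r = speed_mm_per_min / 60.0 * (t - wave_onset_s)
            img += bright_amp * np.exp(-0.5 * ((dist_mm - r) / sigma) ** 2)
            r_dark = r - trail_gap_mm
            if r_dark > 0:
                img -= dark_amp * np.exp(-0.5 * ((dist_mm - r_dark) / sigma) ** 2)
        img += rng.normal(0.0, noise_sd, shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageStack(frames=frames, frame_times_s=times,
                      pixel_pitch_mm=pixel_pitch_mm, origin_px=origin_px)


# -- multichannel traces ---------------------------------------------------

def gen_multichannel(speed_mm_per_min: float = 2.6,
                     distances_mm=(2.0, 4.5, 7.0),
                     base_turning_point_s: float = 134.0,
                     rise_duration_s: float = 120.0,
                     rise_depth: float = 0.04,
                     fall_duration_s: float = 3600.0,
                     fall_depth: float = 0.04,
                     noise_sd: float = 0.002,
                     fs_hz: float = 1.0,
                     seed: int = 0,
                     smoothing_s: float = SMOOTHING_S) -> list[Trace]:
    """Oxygenation-ratio traces whose turning points are delayed by
    distance/speed across the fiber channels (hypoxemia expansion)."""
    dists = np.asarray(distances_mm, dtype=float)
    if np.any(dists <= 0) or np.any(np.diff(dists) <= 0):
        raise ValueError("channel distances must be positive and increasing")
    rng = np.random.default_rng(seed)
    delays = (dists / speed_mm_per_min * 60.0 if np.isfinite(speed_mm_per_min)
              else np.zeros_like(dists))
    t_end = base_turning_point_s + delays.max() + fall_duration_s / 2.0
    t = np.arange(-300.0, t_end, 1.0 / fs_hz)
    traces = []
    for d, delay in zip(dists, delays):
        tp = base_turning_point_s + delay
        v = _oxygenation_template(t, tp, rise_duration_s, rise_depth,
                                  fall_duration_s, fall_depth, smoothing_s)
        traces.append(Trace(t, v + rng.normal(0, noise_sd, t.size)))
    return traces


# -- cohort tables ---------------------------------------------------------

#: empirical per-fluence event rates of the reference cohort
REFERENCE_EVENT_RATES = {
    0.75: dict(n=5, p_sd=2 / 5, p_hyp_given_sd=1.0, p_heme_given_sd=1.0),
    1.0: dict(n=12, p_sd=9 / 12, p_hyp_given_sd=8 / 9, p_heme_given_sd=6 / 9),
    1.25: dict(n=5, p_sd=1.0, p_hyp_given_sd=4 / 5, p_heme_given_sd=1.0),
    1.5: dict(n=2, p_sd=1.0, p_hyp_given_sd=1 / 2, p_heme_given_sd=1 / 2),
}


def gen_cohort(n_scale: float = 1.0, rates: dict | None = None,
               seed: int = 0) -> pd.DataFrame:
    """Bernoulli cohort honoring the conditional structure: hypoxemia and
    heme-reduction events occur only among SD-positive animals.

    ``n_scale`` multiplies each fluence group's animal count (the default
    cohort mix is 5/12/5/2 across 0.75-1.5 J/cm^2).
    """
    rates = rates or REFERENCE_EVENT_RATES
    rng = np.random.default_rng(seed)
    rows = []
    for fluence, r in sorted(rates.items()):
        n = int(round(r["n"] * n_scale))
        for i in range(n):
            sd = rng.random() < r["p_sd"]
            hyp = sd and rng.random() < r["p_hyp_given_sd"]
            heme = sd and rng.random() < r["p_heme_given_sd"]
            rows.append(dict(rat_id=i + 1, fluence_J_cm2=fluence,
                             scattering_change=int(sd), eeg_suppression=int(sd),
                             long_hypoxemia=int(hyp), heme_reduction=int(heme)))
    columns = ["rat_id", "fluence_J_cm2", "scattering_change", "eeg_suppression",
               "long_hypoxemia", "heme_reduction"]
    return pd.DataFrame(rows, columns=columns)
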