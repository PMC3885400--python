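"""Band/ratio signals and spreading-depolarization event detectors.

Works on fiber-photometry style traces referenced to a stimulus at
t = 0 s (the shock-wave application). The four diffuse-reflectance
signals follow the field's conventions:

* ``R_805`` — near-infrared scattering signal (morphology);
* ``R_569`` — isosbestic reflectance, inverse proxy of regional
  cerebral blood volume (a *decrease* encodes hyperemia);
* ``R_578/R_569`` — hemoglobin oxygenation ratio (an *increase*
  encodes hyperoxemia);
* ``R_605/R_620`` — heme-aa3 redox ratio (a *decrease* encodes
  reduction of heme aa3, i.e. mitochondrial energy impairment).

All detectors operate on baseline-normalized traces (baseline mean
mapped to 1) and are therefore invariant to positive rescaling of the
raw signal; each detection boolean is monotone in its threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Trace",
    "SpectrumTimeSeries",
    "EventRow",
    "ScatteringEvent",
    "EegSuppression",
    "DcShift",
    "HypoxemiaEvent",
    "HemeReduction",
    "baseline_normalize",
    "band_ratio",
    "detect_turning_point",
    "detect_scattering_event",
    "detect_eeg_suppression",
    "detect_dc_shift",
    "detect_long_hypoxemia",
    "detect_heme_reduction",
    "classify_recording",
    "DEFAULT_DETECTOR_CONFIG",
]

#: default detector thresholds; all config-overridable
DEFAULT_DETECTOR_CONFIG = {
    "scattering_threshold_frac": 0.05,
    "scattering_window_s": 300.0,
    "eeg_rms_window_s": 10.0,
    "eeg_drop_frac": 0.5,
    "eeg_min_duration_s": 60.0,
    "hypoxemia_depth_frac": 0.03,
    "hypoxemia_min_duration_s": 1800.0,
    "heme_threshold_frac": 0.02,
    "heme_window_s": 600.0,
}


@dataclass(frozen=True)
class Trace:
    """A single-channel time series with the stimulus at ``stimulus_time_s``."""

    time_s: np.ndarray
    value: np.ndarray
    stimulus_time_s: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (t[0] <= self.stimulus_time_s <= t[-1]):
            raise ValueError("stimulus time must lie within the trace")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "value", v)

    def post_stimulus(self) -> "Trace":
        m = self.time_s >= self.stimulus_time_s
        return Trace(self.time_s[m], self.value[m], self.stimulus_time_s)


@dataclass(frozen=True)
class SpectrumTimeSeries:
    """Wavelength x time reflectance matrix."""

    wavelengths: np.ndarray  # nm, strictly increasing
    time_s: np.ndarray
    reflectance: np.ndarray  # (n_wavelengths, n_times)
    stimulus_time_s: float = 0.0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.time_s, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (wl.size, t.size):
            raise ValueError("reflectance must be (n_wavelengths, n_times)")
        if np.any(np.diff(wl) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("wavelength and time grids must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class EventRow:
    """One animal's event classification (``None`` marks a missing modality)."""

    rat_id: str
    fluence_J_cm2: float
    scattering_change: bool | None
    eeg_suppression: bool | None
    long_hypoxemia: bool | None
    heme_reduction: bool | None


# -- trace preprocessing ---------------------------------------------------

def baseline_normalize(trace: Trace, baseline_window_s: tuple[float, float] = (-60.0, 0.0)) -> Trace:
    """Divide by the pre-stimulus window mean (baseline maps to 1)."""
    lo, hi = baseline_window_s
    if hi > trace.stimulus_time_s:
        raise ValueError("baseline window must be wholly pre-stimulus")
    m = (trace.time_s >= lo) & (trace.time_s <= hi)
    if m.sum() < 5:
        raise ValueError("baseline window must contain >= 5 samples")
    base = trace.value[m].mean()
    if base == 0:
        raise ValueError("baseline mean is zero; cannot normalize")
    return replace(trace, value=trace.value / base)


def band_ratio(series: SpectrumTimeSeries, numerator_nm: float,
               denominator_nm: float | None = None, tol_nm: float = 2.0) -> Trace:
    """Pointwise band ratio trace (nearest-node lookup within ``tol_nm``).

    ``denominator_nm=None`` yields the single-band trace (R_805- or
    R_569-type signals).
    """

    def _row(nm):
        idx = int(np.argmin(np.abs(series.wavelengths - nm)))
        if abs(series.wavelengths[idx] - nm) > tol_nm:
            raise ValueError(f"no wavelength within {tol_nm} nm of {nm} nm")
        return series.reflectance[idx]

    num = _row(numerator_nm)
    val = num if denominator_nm is None else num / _row(denominator_nm)
    return Trace(series.time_s, val, series.stimulus_time_s)


def _baseline_noise_sd(trace: Trace) -> float:
    pre = trace.value[trace.time_s < trace.stimulus_time_s]
    return float(pre.std()) if pre.size >= 2 else 0.0


def _moving_average(v: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return v
    kernel = np.ones(n) / n
    pad = n // 2
    vp = np.pad(v, pad, mode="edge")
    return np.convolve(vp, kernel, mode="same")[pad:pad + v.size]


def _contiguous_runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is inclusive."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2] - 1))


# -- detectors -------------------------------------------------------------

def detect_turning_point(trace: Trace, smoothing_s: float = 5.0) -> float | None:
    """Time of the first post-stimulus baseline crossing after the
    post-stimulus extremum of a normalized trace.

    The trace is lightly smoothed; the initial deflection is the earlier
    of the global positive/negative extrema that exceed max(3 smoothed
    baseline-noise SDs, 10% of the maximum deviation). The crossing back
    through 1.0 after that extremum is linearly interpolated between
    samples. Returns ``None`` when no deflection or no return crossing
    exists.
    """
    post = trace.post_stimulus()
    if post.value.size < 2:
        return None
    dt = float(np.median(np.diff(post.time_s)))
    n_sm = max(int(round(smoothing_s / dt)), 1)
    sm_all = _moving_average(trace.value, n_sm)
    pre = sm_all[trace.time_s < trace.stimulus_time_s]
    noise = float(pre.std()) if pre.size >= 2 else 0.0
    d = _moving_average(post.value, n_sm) - 1.0
    thr = max(3.0 * noise, 0.1 * np.max(np.abs(d)), 1e-12)
    candidates = [i for i in (int(np.argmax(d)), int(np.argmin(d)))
                  if abs(d[i]) > thr]
    if not candidates:
        return None
    i0 = min(candidates)  # the extremum of the *initial* deflection
    sign = np.sign(d[i0])
    cross = np.flatnonzero(sign * d[i0:] <= 0.0)
    if cross.size == 0:
        return None
    j = i0 + int(cross[0])
    t0, t1 = post.time_s[j - 1], post.time_s[j]
    v0, v1 = sign * d[j - 1], sign * d[j]
    if v0 == v1:
        return float(t0)  # ties break toward the earlier time
    return float(t0 + (t1 - t0) * v0 / (v0 - v1))


@dataclass(frozen=True)
class ScatteringEvent:
    detected: bool
    duration_s: float


def detect_scattering_event(r805: Trace, threshold_frac: float = 0.05,
                            min_duration_s: float = 0.0,
                            window_s: float = 300.0) -> ScatteringEvent:
    """Drastic light-scattering change within ``window_s`` post-stimulus.

    Detected when |value - 1| exceeds ``threshold_frac`` inside the
    window; the duration spans the first to the last exceedance of the
    whole post-stimulus trace (sign-convention invariant).
    """
    post = r805.post_stimulus()
    dev = np.abs(post.value - 1.0) > threshold_frac
    in_window = dev & (post.time_s <= post.stimulus_time_s + window_s)
    if not in_window.any():
        return ScatteringEvent(False, 0.0)
    t_exceed = post.time_s[dev]
    duration = float(t_exceed[-1] - t_exceed[0])
    return ScatteringEvent(duration >= min_duration_s, duration)


@dataclass(frozen=True)
class EegSuppression:
    detected: bool
    onset_s: float | None
    duration_s: float


def detect_eeg_suppression(eeg: Trace, fs_hz: float, rms_window_s: float = 10.0,
                           drop_frac: float = 0.5,
                           min_duration_s: float = 60.0) -> EegSuppression:
    """Longest epoch where the sliding-RMS envelope drops below
    ``drop_frac`` times the pre-stimulus RMS for at least ``min_duration_s``."""
    n_win = max(int(round(rms_window_s * fs_hz)), 1)
    if eeg.value.size < n_win:
        raise ValueError("trace shorter than the RMS window")
    env = np.sqrt(_moving_average(eeg.value**2, n_win))
    pre = eeg.time_s < eeg.stimulus_time_s
    if not pre.any():
        raise ValueError("no pre-stimulus samples for the baseline RMS")
    base = float(np.sqrt(np.mean(eeg.value[pre] ** 2)))
    post = eeg.time_s >= eeg.stimulus_time_s
    low = (env < drop_frac * base) & post
    best = None
    for start, stop in _contiguous_runs(low):
        dur = eeg.time_s[stop] - eeg.time_s[start]
        if best is None or dur > best[0]:
            best = (dur, start)
    if best is None or best[0] < min_duration_s:
        return EegSuppression(False, None, 0.0 if best is None else float(best[0]))
    return EegSuppression(True, float(eeg.time_s[best[1]]), float(best[0]))


@dataclass(frozen=True)
class DcShift:
    max_negative_shift_mV: float
    onset_s: float | None
    time_to_min_s: float | None


def detect_dc_shift(dc: Trace, smoothing_s: float = 5.0,
                    artifact_halfwidth_s: float = 5.0) -> DcShift:
    """Negative DC-potential shift metrics.

    The shift is the pre-stimulus mean minus the post-stimulus minimum of
    the smoothed trace; the onset is the first time the smoothed trace
    falls 3 baseline-noise SDs below the baseline. The stimulus-artifact
    region (+-5 s around t = 0) is excluded.
    """
    dt = float(np.median(np.diff(dc.time_s)))
    sm = _moving_average(dc.value, max(int(round(smoothing_s / dt)), 1))
    pre = dc.time_s < dc.stimulus_time_s - artifact_halfwidth_s
    post = dc.time_s > dc.stimulus_time_s + artifact_halfwidth_s
    if not pre.any() or not post.any():
        raise ValueError("trace must extend beyond the artifact exclusion zone")
    base = float(sm[pre].mean())
    noise = float(dc.value[pre].std())
    i_min = np.flatnonzero(post)[int(np.argmin(sm[post]))]
    shift = base - float(sm[i_min])
    below = post & (sm < base - 3.0 * max(noise, 1e-12))
    onset = float(dc.time_s[int(np.argmax(below))]) if below.any() else None
    t_min = float(dc.time_s[i_min]) if onset is not None else None
    return DcShift(shift, onset, t_min)


@dataclass(frozen=True)
class HypoxemiaEvent:
    detected: bool
    duration_s: float


def detect_long_hypoxemia(oxy: Trace, min_duration_s: float = 1800.0,
                          depth_frac: float = 0.03) -> HypoxemiaEvent:
    """Long-lasting hypoxemia: the normalized oxygenation ratio stays below
    (1 - depth_frac) continuously for >= ``min_duration_s`` after its
    hyperoxemia-to-hypoxemia turning point."""
    tp = detect_turning_point(oxy)
    start = oxy.stimulus_time_s if tp is None else tp
    m = oxy.time_s >= start
    low = (oxy.value < 1.0 - depth_frac) & m
    longest = 0.0
    for s, e in _contiguous_runs(low):
        longest = max(longest, float(oxy.time_s[e] - oxy.time_s[s]))
    return HypoxemiaEvent(longest >= min_duration_s, longest)


@dataclass(frozen=True)
class HemeReduction:
    detected: bool
    onset_s: float | None
    duration_s: float


def detect_heme_reduction(ratio: Trace, threshold_frac: float = 0.02,
                          window_s: float = 600.0,
                          smoothing_s: float = 5.0) -> HemeReduction:
    """Transient dip of the heme-aa3 ratio below (1 - threshold_frac).

    Looks for the longest contiguous sub-threshold epoch starting within
    ``window_s`` of the stimulus; the trace is lightly smoothed first so
    that epoch edges are noise-stable.
    """
    post = ratio.post_stimulus()
    dt = float(np.median(np.diff(post.time_s)))
    sm = _moving_average(post.value, max(int(round(smoothing_s / dt)), 1))
    low = sm < 1.0 - threshold_frac
    best = None
    for s, e in _contiguous_runs(low):
        if post.time_s[s] > post.stimulus_time_s + window_s:
            continue
        dur = float(post.time_s[e] - post.time_s[s])
        if best is None or dur > best[0]:
            best = (dur, s)
    if best is None or best[0] <= 0.0:
        return HemeReduction(False, None, 0.0)
    return HemeReduction(True, float(post.time_s[best[1]]), best[0])


# -- classification --------------------------------------------------------

def classify_recording(traces: dict, rat_id: str = "0", fluence_J_cm2: float = 1.0,
                       config: dict | None = None) -> EventRow:
    """Run the four detectors on one animal's trace set.

    ``traces`` maps modality names to normalized :class:`Trace` objects:
    ``r805`` (scattering), ``eeg``, ``oxy`` (R_578/R_569) and ``heme``
    (R_605/R_620). A missing modality yields ``None`` in the row rather
    than a silent False.
    """
    cfg = dict(DEFAULT_DETECTOR_CONFIG)
    if config:
        cfg.update(config)

    scattering = eeg = hypox = heme = None
    if "r805" in traces:
        scattering = detect_scattering_event(
            traces["r805"], cfg["scattering_threshold_frac"],
            window_s=cfg["scattering_window_s"]).detected
    if "eeg" in traces:
        tr = traces["eeg"]
        fs = 1.0 / float(np.median(np.diff(tr.time_s)))
        eeg = detect_eeg_suppression(
            tr, fs, cfg["eeg_rms_window_s"], cfg["eeg_drop_frac"],
            cfg["eeg_min_duration_s"]).detected
    if "oxy" in traces:
        hypox = detect_long_hypoxemia(
            traces["oxy"], cfg["hypoxemia_min_duration_s"],
            cfg["hypoxemia_depth_frac"]).detected
    if "heme" in traces:
        heme = detect_heme_reduction(
            traces["heme"], cfg["heme_threshold_frac"], cfg["heme_window_s"]).detected
    return EventRow(rat_id, fluence_J_cm2, scattering, eeg, hypox, heme)
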