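"""Scattering-wave tracking and propagation-speed estimation.

Difference imaging of NIR reflectance stacks exposes the expanding
bright/dark annulus of a cortical spreading-depolarization wave; the
front radius is measured per frame as the 95th percentile of
super-threshold pixel distances from the application site, and the
propagation speed is the least-squares slope of radius versus time.
A companion estimator regresses multichannel fiber onset times on their
probe distances to give the hypoxemia expansion speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label

__all__ = [
    "ImageStack",
    "FrontTrack",
    "difference_stack",
    "track_front",
    "fit_front_speed",
    "onset_regression",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class ImageStack:
    """Frames x height x width intensity stack with acquisition metadata.

    ``origin_px`` is the (row, col) of the shock-wave application site.
    """

    frames: np.ndarray
    frame_times_s: np.ndarray
    pixel_pitch_mm: float
    origin_px: tuple[int, int]

    def __post_init__(self):
        f = np.asarray(self.frames)
        t = np.asarray(self.frame_times_s, dtype=float)
        if f.ndim != 3 or f.shape[0] != t.size:
            raise ValueError("frames must be (time, H, W) matching frame_times_s")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        r, c = self.origin_px
        if not (0 <= r < f.shape[1] and 0 <= c < f.shape[2]):
            raise ValueError("origin must lie within the frame")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "frame_times_s", t)
        object.__setattr__(self, "origin_px", (int(r), int(c)))


@dataclass(frozen=True)
class FrontTrack:
    """Per-frame front radii and the fitted radius-vs-time line."""

    times_s: np.ndarray
    radii_mm: np.ndarray
    skipped_frames: tuple = ()
    fit_speed_mm_per_min: float | None = None
    fit_intercept_mm: float | None = None
    fit_r2: float | None = None

    @property
    def n_samples(self) -> int:
        return int(self.times_s.size)


def difference_stack(stack: ImageStack, reference_index: int = 0) -> ImageStack:
    """Subtract the reference frame from every frame (signed float result)."""
    if not (0 <= reference_index < stack.frames.shape[0]):
        raise ValueError("reference index out of range")
    ref = stack.frames[reference_index].astype(float)
    return ImageStack(frames=stack.frames.astype(float) - ref,
                      frame_times_s=stack.frame_times_s,
                      pixel_pitch_mm=stack.pixel_pitch_mm,
                      origin_px=stack.origin_px)


def track_front(diff: ImageStack, threshold: float | None = None,
                min_blob_px: int = 20, radius_percentile: float = 95.0,
                n_noise_frames: int = 3) -> FrontTrack:
    """Track the bright-front radius across a difference stack.

    Per frame, positive-difference pixels above ``threshold`` are kept if
    they belong to a connected component of at least ``min_blob_px``
    pixels; the front radius is the ``radius_percentile`` percentile of
    their distances from the origin, in mm. Frames without qualifying
    pixels are skipped and recorded. The default threshold is 3x the
    per-pixel SD of the first ``n_noise_frames`` difference frames.
    """
    frames = diff.frames
    if threshold is None:
        noise = float(frames[:n_noise_frames].std())
        threshold = 3.0 * max(noise, 1e-9)
    rows, cols = np.indices(frames.shape[1:])
    dist_mm = np.hypot(rows - diff.origin_px[0], cols - diff.origin_px[1]) \
        * diff.pixel_pitch_mm
    times, radii, skipped = [], [], []
    for i, frame in enumerate(frames):
        mask = frame > threshold
        if mask.any():
            lab = label(mask, connectivity=2)
            counts = np.bincount(lab.ravel())
            counts[0] = 0
            keep = np.isin(lab, np.flatnonzero(counts >= min_blob_px))
        else:
            keep = mask
        if not keep.any():
            skipped.append(i)
            continue
        times.append(diff.frame_times_s[i])
        radii.append(float(np.percentile(dist_mm[keep], radius_percentile)))
    return FrontTrack(times_s=np.array(times), radii_mm=np.array(radii),
                      skipped_frames=tuple(skipped))


def _ols_line(x: np.ndarray, y: np.ndarray):
    X = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = slope * x + intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - pred) ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_front_speed(track: FrontTrack) -> FrontTrack:
    """Complete a track with the OLS radius-vs-time fit (speed in mm/min)."""
    if track.n_samples < 3:
        raise ValueError("front-speed fit requires >= 3 radius samples")
    slope, intercept, r2 = _ols_line(track.times_s, track.radii_mm)
    return FrontTrack(times_s=track.times_s, radii_mm=track.radii_mm,
                      skipped_frames=track.skipped_frames,
                      fit_speed_mm_per_min=slope * 60.0,
                      fit_intercept_mm=intercept, fit_r2=r2)


def onset_regression(channel_distances_mm, onset_times_s) -> float:
    """Expansion speed (mm/min) from distance-vs-onset least squares.

    Channels whose onset is ``None`` (no detected turning point) are
    dropped; at least two detected onsets are required.
    """
    pairs = [(d, t) for d, t in zip(channel_distances_mm, onset_times_s)
             if t is not None]
    if len(pairs) < 2:
        raise ValueError("onset regression requires >= 2 channels with onsets")
    d = np.array([p[0] for p in pairs], dtype=float)
    t = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(t, t[0]):
        raise ValueError("onset times are all equal; speed is unbounded")
    slope, _, _ = _ols_line(t, d)
    return slope * 60.0


# -- TIFF + sidecar-JSON IO ------------------------------------------------

def write_stack(stack: ImageStack, tif_path, meta_path) -> None:
    """Persist a stack as multi-page TIFF plus sidecar JSON metadata."""
    import tifffile

    tifffile.imwrite(tif_path, stack.frames)
    meta = {"frame_times_s": list(map(float, stack.frame_times_s)),
            "pixel_pitch_mm": stack.pixel_pitch_mm,
            "origin_px": list(stack.origin_px)}
    with open(meta_path, "w") as fh:
        json.dump(meta, fh)


def read_stack(tif_path, meta_path) -> ImageStack:
    import tifffile

    with open(meta_path) as fh:
        meta = json.load(fh)
    return ImageStack(frames=tifffile.imread(tif_path),
                      frame_times_s=np.asarray(meta["frame_times_s"], dtype=float),
                      pixel_pitch_mm=float(meta["pixel_pitch_mm"]),
                      origin_px=tuple(meta["origin_px"]))
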