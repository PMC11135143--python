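"""Event-centered windows and the two image encodings fed to the classifiers.

Each detected event is summarized by a window of ±285 ms around its center,
rendered as a 128x128 time-frequency (Gabor scalogram, 10-290 Hz) image and
a 128x128 amplitude-coding image.  The geometry is configurable from 32x32
(10-80 Hz, ±72 ms) up to 224x224 (10-500 Hz, ±500 ms) at constant per-pixel
resolution (~2.19 Hz and ~4.45 ms per pixel at the default).

Training-time augmentation shifts the window center uniformly within
±50 ms — re-extracting from the recording so new samples enter the window —
and flips the segment in time with probability 1/2.  Evaluation paths never
augment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .events import HfoEvent
from .io import Recording
from .wavelets import gabor_transform


@dataclass(frozen=True)
class ImageGeometry:
    """Window and image geometry; defaults give 2.1875 Hz/px and 4.4531 ms/px."""

    n_pixels: int = 128
    freq_low: float = 10.0
    freq_high: float = 290.0
    half_width_ms: float = 285.0

    @property
    def hz_per_pixel(self) -> float:
        return (self.freq_high - self.freq_low) / self.n_pixels

    @property
    def ms_per_pixel(self) -> float:
        return 2.0 * self.half_width_ms / self.n_pixels


#: presets matching the input-size sweep geometry (constant resolution)
GEOMETRIES = {
    32: ImageGeometry(32, 10.0, 80.0, 72.0),
    64: ImageGeometry(64, 10.0, 150.0, 144.0),
    128: ImageGeometry(128, 10.0, 290.0, 285.0),
    224: ImageGeometry(224, 10.0, 500.0, 500.0),
}


@dataclass
class EventWindow:
    """Raw samples around an event center, zero-padded at recording bounds."""

    samples: np.ndarray
    center_sample: int
    sample_rate: float
    half_width_ms: float = 285.0
    pad_left: int = 0
    pad_right: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.pad_left < 0 or self.pad_right < 0:
            raise ValueError("pads must be non-negative")

    def flipped(self) -> "EventWindow":
        """Time-reversed copy (the augmentation flip; an involution)."""
        return EventWindow(self.samples[::-1].copy(), self.center_sample,
                           self.sample_rate, self.half_width_ms,
                           pad_left=self.pad_right, pad_right=self.pad_left)


@dataclass(frozen=True)
class FeatureImage:
    """Normalized n x n image; ``grid`` rows run top-down (low freq at bottom)."""

    grid: np.ndarray
    kind: str  # "time_frequency" | "amplitude_coding"
    geometry: ImageGeometry


def extract_window(rec: Recording, event: HfoEvent, half_width_ms: float = 285.0,
                   shift_ms: float = 0.0) -> EventWindow:
    """Extract samples around the (possibly shifted) event midpoint.

    The segment has even length ``2 * round(half_width_ms * fs / 1000)``;
    parts outside the recording are zero-filled and recorded as pads.
    """
    if abs(shift_ms) > half_width_ms:
        raise ValueError("|shift_ms| may not exceed half_width_ms")
    fs = rec.sample_rate
    half = int(round(half_width_ms * fs / 1000.0))
    center = int(round(event.center() + shift_ms * fs / 1000.0))
    lo, hi = center - half, center + half
    sig = rec.channel(event.channel)
    pad_left = max(0, -lo)
    pad_right = max(0, hi - sig.size)
    seg = np.zeros(2 * half, dtype=np.float64)
    seg[pad_left: 2 * half - pad_right] = sig[max(0, lo): min(sig.size, hi)]
    return EventWindow(seg, center, fs, half_width_ms,
                       pad_left=pad_left, pad_right=pad_right)


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _resample_columns(arr: np.ndarray, n_cols: int) -> np.ndarray:
    """Linear resampling of the last axis to ``n_cols`` points."""
    if arr.shape[-1] == n_cols:
        return arr
    zoom = [1.0] * (arr.ndim - 1) + [n_cols / arr.shape[-1]]
    return ndimage.zoom(arr, zoom, order=1, grid_mode=True, mode="nearest")


def time_frequency_image(window: EventWindow, sample_rate: float | None = None,
                         geometry: ImageGeometry = GEOMETRIES[128],
                         cycles: float = 6.0) -> FeatureImage:
    """Gabor scalogram over the geometry's band, min-max normalized to [0, 1].

    Frequencies are sampled directly at ``n_pixels`` linear steps (no image
    resize on the frequency axis); the time axis is linearly resampled to
    ``n_pixels`` columns.  Low frequencies occupy the bottom rows.
    """
    fs = sample_rate if sample_rate is not None else window.sample_rate
    freqs = np.linspace(geometry.freq_low, geometry.freq_high, geometry.n_pixels)
    w = gabor_transform(window.samples, freqs, fs, cycles=cycles)
    mag = np.abs(w)
    mag = _resample_columns(mag, geometry.n_pixels)
    grid = _minmax(mag[::-1])  # row 0 = highest frequency
    return FeatureImage(grid=grid, kind="time_frequency", geometry=geometry)


def amplitude_coding_image(window: EventWindow,
                           geometry: ImageGeometry = GEOMETRIES[128]) -> FeatureImage:
    """Signed bar-code rendering of instantaneous amplitude.

    The segment is resampled to ``n_pixels`` columns and scaled by its peak
    absolute amplitude (scale-invariant).  Column t is filled outward from
    the middle row over a row count proportional to |amplitude|, above the
    midline for positive polarity and below for negative; the midline itself
    is always on.
    """
    n = geometry.n_pixels
    x = _resample_columns(window.samples, n)
    peak = float(np.max(np.abs(x)))
    a = x / peak if peak > 0 else np.zeros_like(x)
    mid = n // 2
    extent = np.round(np.abs(a) * (mid - 1)).astype(int)
    rows = np.arange(n)[:, None]
    above = (mid - rows >= 0) & (mid - rows <= extent[None, :]) & (a[None, :] >= 0)
    below = (rows - mid >= 0) & (rows - mid <= extent[None, :]) & (a[None, :] < 0)
    grid = (above | below).astype(np.float64)
    grid[mid, :] = 1.0
    return FeatureImage(grid=grid, kind="amplitude_coding", geometry=geometry)


def event_images(rec: Recording, event: HfoEvent,
                 geometry: ImageGeometry = GEOMETRIES[128],
                 shift_ms: float = 0.0, flip: bool = False,
                 cycles: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (time-frequency, amplitude-coding) grids for one event."""
    win = extract_window(rec, event, half_width_ms=geometry.half_width_ms,
                         shift_ms=shift_ms)
    if flip:
        win = win.flipped()
    tf = time_frequency_image(win, geometry=geometry, cycles=cycles)
    ac = amplitude_coding_image(win, geometry=geometry)
    return tf.grid, ac.grid


def augment(rec: Recording, event: HfoEvent, rng: np.random.Generator,
            geometry: ImageGeometry = GEOMETRIES[128],
            max_shift_ms: float = 50.0, flip_prob: float = 0.5) -> EventWindow:
    """Training-time augmentation: uniform ±max_shift_ms center shift, then
    re-extraction (new samples enter the window), then a probability-1/2
    time flip.  Order: shift -> extract -> flip."""
    if rng is None:
        raise ValueError("augmentation requires an explicit random generator")
    shift = float(rng.uniform(-max_shift_ms, max_shift_ms))
    win = extract_window(rec, event, half_width_ms=geometry.half_width_ms,
                         shift_ms=shift)
    if rng.random() < flip_prob:
        win = win.flipped()
    return win
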