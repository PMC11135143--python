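"""Ground-truth-labelled synthetic intracranial EEG.

Generates 1/f ("pink") background noise per channel with three kinds of
injected transients, each recorded in a ground-truth event set:

* **HFO**: a Gaussian-windowed sinusoid drawn from the ripple band
  (80-250 Hz, 30-100 ms); the truth interval is the ±3-sigma support of the
  envelope.  Amplitude is expressed as a multiple of the broadband
  background RMS.
* **spkHFO**: an HFO with a superimposed biphasic spike transient
  (first-derivative-of-Gaussian waveform).
* **artifact**: a broadband high-amplitude noise burst under the same
  Gaussian envelope.

Everything derives from one seed; per-channel noise streams and event draws
are sub-seeded so the output is reproducible bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventSet, HfoEvent
from .features import GEOMETRIES, ImageGeometry, event_images
from .io import Recording


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator (defaults: 4 x 60 s at 2 kHz)."""

    duration_s: float = 60.0
    sample_rate: float = 2000.0
    n_channels: int = 4
    noise_rms: float = 10.0          # microvolts, broadband
    noise_exponent: float = 1.0      # 1/f^alpha power spectrum
    n_hfo: int = 20
    hfo_freq: tuple[float, float] = (80.0, 250.0)
    hfo_duration_ms: tuple[float, float] = (30.0, 100.0)
    hfo_amplitude: float = 6.0       # RMS SNR: burst RMS / broadband background RMS
    hfo_cycles: float = 8.0          # oscillation cycles per event (0 = independent draws)
    spike_prob: float = 0.0          # chance an HFO carries a spike (-> spkHFO)
    spike_width_ms: float = 40.0
    spike_amplitude: float = 4.0     # x background RMS
    n_artifacts: int = 0
    artifact_amplitude: float = 8.0  # x background RMS
    artifact_duration_ms: tuple[float, float] = (20.0, 60.0)
    edge_margin_s: float = 1.0       # events stay clear of the recording edges
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate <= 0 or self.n_channels < 1:
            raise ValueError("invalid recording geometry")
        if min(self.n_hfo, self.n_artifacts) < 0:
            raise ValueError("event counts must be non-negative")
        if not 0 <= self.spike_prob <= 1:
            raise ValueError("spike_prob is a probability")


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a 1/f^exponent power spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite; it is filtered out downstream anyway
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _place_intervals(rng: np.random.Generator, durations: np.ndarray,
                     n_samples: int, margin: int, min_spacing: int,
                     existing: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping intervals inside the margins."""
    placed = list(existing)
    out = []
    for dur in durations:
        ok = False
        for _ in range(2000):
            start = int(rng.integers(margin, n_samples - margin - dur))
            cand = (start, start + int(dur))
            if all(cand[1] + min_spacing <= s or e + min_spacing <= cand[0]
                   for s, e in placed):
                placed.append(cand)
                out.append(cand)
                ok = True
                break
        if not ok:
            raise ValueError("cannot pack events: too many for the duration")
    return out


def simulate_recording(config: SimConfig) -> tuple[Recording, EventSet]:
    """Synthesize the recording and its ground-truth event set."""
    fs = config.sample_rate
    n = int(round(config.duration_s * fs))
    margin = int(round(config.edge_margin_s * fs))
    if 2 * margin >= n:
        raise ValueError("recording shorter than twice the edge margin")
    root = np.random.default_rng(config.seed)
    noise_seeds = root.integers(0, 2**31, size=config.n_channels)
    event_rng = np.random.default_rng(root.integers(0, 2**31))

    signals = np.stack([
        config.noise_rms * pink_noise(n, config.noise_exponent,
                                      np.random.default_rng(s))
        for s in noise_seeds
    ])
    names = [f"CH{i + 1}" for i in range(config.n_channels)]

    # round-robin assignment of events to channels
    specs: list[tuple[str, int]] = []  # (kind, channel)
    for k in range(config.n_hfo):
        kind = "spkHFO" if event_rng.random() < config.spike_prob else "non-spkHFO"
        specs.append((kind, k % config.n_channels))
    for k in range(config.n_artifacts):
        specs.append(("artifact", k % config.n_channels))

    events: list[HfoEvent] = []
    placed_by_ch: dict[int, list[tuple[int, int]]] = {c: [] for c in range(config.n_channels)}
    min_spacing = int(round(0.2 * fs))  # keep injections resolvable
    for kind, ch in specs:
        if kind == "artifact":
            dur_ms = event_rng.uniform(*config.artifact_duration_ms)
            freq = float("nan")
        else:
            # a bona fide HFO holds several consecutive oscillation cycles, so
            # frequency and duration are coupled: lower-frequency ripples last
            # longer.  Duration is drawn from the configured range and the
            # frequency follows from the cycle count, clipped into the band
            # (re-deriving the duration if the clip binds).
            dur_ms = event_rng.uniform(*config.hfo_duration_ms)
            if config.hfo_cycles > 0:
                freq = config.hfo_cycles / (dur_ms / 1000.0)
                lo, hi = config.hfo_freq
                if not lo <= freq <= hi:
                    freq = min(max(freq, lo), hi)
                    dur_ms = 1000.0 * config.hfo_cycles / freq
            else:
                freq = event_rng.uniform(*config.hfo_freq)
        dur = max(8, int(round(dur_ms * fs / 1000.0)))
        (start, end), = _place_intervals(event_rng, np.array([dur]), n, margin,
                                         min_spacing, placed_by_ch[ch])
        placed_by_ch[ch].append((start, end))
        t = (np.arange(start, end) - (start + end - 1) / 2.0) / fs
        sigma = (end - start) / (6.0 * fs)  # truth interval = ±3 sigma support
        envelope = np.exp(-t**2 / (2.0 * sigma**2))
        if kind == "artifact":
            burst = envelope * event_rng.standard_normal(end - start)
            signals[ch, start:end] += config.artifact_amplitude * config.noise_rms * burst
        else:
            phase = event_rng.uniform(0, 2 * np.pi)
            osc = envelope * np.sin(2 * np.pi * freq * t + phase)
            # amplitude is an RMS signal-to-noise ratio: at the envelope peak
            # the oscillation's RMS (peak / sqrt(2)) is `hfo_amplitude` times
            # the broadband background RMS
            peak = config.hfo_amplitude * np.sqrt(2.0) * config.noise_rms
            signals[ch, start:end] += peak * osc
            if kind == "spkHFO":
                sw = config.spike_width_ms / 1000.0 / 4.0  # sigma of the lobe
                spike = -t / sw * np.exp(0.5 - t**2 / (2.0 * sw**2))
                signals[ch, start:end] += (config.spike_amplitude
                                           * config.noise_rms * spike)
        events.append(HfoEvent(channel=names[ch], start=start, end=end,
                               detector="truth", label=kind))

    truth = EventSet(events, sample_rate=fs,
                     meta={"generator": "synthetic", "seed": config.seed}).sorted()
    return Recording(names, fs, signals), truth


def simulate_labelled_features(config: SimConfig,
                               geometry: ImageGeometry = GEOMETRIES[128]
                               ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature images at the ground-truth intervals.

    Returns (time-frequency images (N, n, n), amplitude-coding images
    (N, n, n), class labels); ordering follows the sorted truth set.
    """
    rec, truth = simulate_recording(config)
    tf, ac, labels = [], [], []
    for ev in truth:
        t, a = event_images(rec, ev, geometry=geometry)
        tf.append(t)
        ac.append(a)
        labels.append(ev.label)
    n = geometry.n_pixels
    if not tf:
        return (np.empty((0, n, n)), np.empty((0, n, n)), [])
    return np.stack(tf), np.stack(ac), labels
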