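# Methods

This note documents the models and procedures implemented in `hfokit`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Signal model and calibration

A recording is a channels × samples matrix in the physical units declared by
the EDF header (conventionally µV), with one sampling rate for all channels
(files mixing per-channel rates are rejected rather than resampled, since
every downstream stage assumes a single rate). Digital-to-physical
conversion is the affine map `V = R·D + O` with
`R = (V_max − V_min)/(D_max − D_min)` and `O = V_min − R·D_min`; it is exact
at both digital endpoints and keeps the DC offset that gain-only conversion
drops. Sample coordinates are 0-based and half-open `[start, end)`; time in
seconds is `sample / sample_rate`. EDF+ annotations and discontinuities are
ignored; only continuous signals are read.

## Ripple-band filter

Chebyshev type II, specified by passband edges (default 80–500 Hz),
passband ripple (0.5 dB) and stopband attenuation (93 dB). The stopband
edges are not independently meaningful in this workflow and default to
`0.9 × pass_low` and `min(1.1 × pass_high, 0.95 × Nyquist)`; all four edges
are configurable. The filter order comes from `scipy.signal.cheb2ord` and
the design from `cheby2` in second-order-section form — at order ≳ 20 a
transfer-function polynomial representation overflows double precision
while an SOS cascade is stable; designs that still overflow (e.g., an
attenuation contract of 1000 dB) are reported as explicit design errors
rather than returned. Every design is verified post hoc on a 10 000-point
grid (0.1 dB slack for floating point): deviation from unity ≤ ripple
across the passband, attenuation ≥ the contract at and beyond both stopband
edges. Application is forward–backward (`sosfiltfilt`), so events incur no
group delay; a causal single-pass mode exists behind a flag.

## STE detector

Per channel, on the band-passed signal, in epochs (default 600 s; a shorter
recording is one epoch):

1. moving RMS with a 3 ms centered window (trailing available by flag);
   shrunken windows at the edges;
2. threshold `mean + 5·SD` of the RMS trace, moments computed per epoch;
3. suprathreshold runs lasting ≥ 6 ms are kept; runs separated by < 10 ms
   merge (merge before validation);
4. each run is widened outward to where the RMS trace falls back to the
   epoch mean — the threshold crossing marks the event's *core*, the
   mean-crossing its extent. Without this step a detector reports only the
   tip of an oscillation's envelope (the suprathreshold region of a
   Gaussian-enveloped burst covers roughly half its visible support), which
   systematically biases boundary-sensitive downstream comparisons;
5. a run must contain ≥ 6 local maxima of the rectified signal above
   `mean + 3·SD` (local maxima are strict sign changes of the first
   difference; plateaus resolve to their leftmost sample);
6. events abutting across an epoch boundary merge in a post-pass.

All constants above are `SteParams` fields, not literals. Because epoch
statistics scale with the signal, detections are invariant under positive
rescaling and (up to filter leakage) under DC offsets.

## MNI detector

Per channel: band-pass 80–450 Hz, energy = moving RMS (10 ms), epochs of
10 s scanned in 125 ms segments.

*Baseline discovery.* A segment is baseline when the Gabor-wavelet entropy
of its normalized autocorrelation exceeds 0.67 of the theoretical maximum
`log(n_scales)`. The entropy bank uses 32 linear scales across the band:
the fraction-of-maximum criterion is only meaningful when the bank is fine
enough that noise-like segments actually approach the maximum (with very
few, spectrally broad scales, both noise and oscillations land in a narrow
mid-range and the fraction separates nothing). The Gabor transform runs as
one FFT-domain matrix operation over all scales.

*Thresholding.* With ≥ 5 s of baseline in the epoch, the threshold is the
99.9999-percentile of a **gamma CDF fitted** (maximum likelihood, zero
location) to the baseline energy values. A fitted quantile, unlike an
empirical percentile of this order (which is simply the pool maximum), is
robust to the residual event fringes that inevitably leak past the entropy
screen; a half-window guard band around non-baseline segments additionally
keeps moving-RMS leakage out of the pool. When the pool exceeds 20 000
values it is subsampled with the per-channel generator — the detector's
only randomness, which is why identical seeds give bitwise-identical
events. With insufficient baseline, the iterative branch fits a gamma to
the energy of all not-yet-detected samples, emits supra-threshold stretches
(≥ 10 ms) at the 95th percentile, removes them, and refits, for up to 10
rounds. Both branches widen events to the baseline-mean crossing and merge
across gaps < 10 ms, as in STE.

Per-channel seeds derive from the master seed plus a CRC of the channel
name, so results are invariant to channel order and to the number of worker
processes (`n_jobs`).

## Event images and augmentation

Windows cover ±285 ms around the event midpoint (zero-padded at recording
edges, pads recorded). Two encodings, both 128×128 in [0, 1]:

* **time-frequency** — magnitude of a 6-cycle Morlet/Gabor transform at 128
  linear frequencies over 10–290 Hz (≈ 2.19 Hz/px), computed directly at
  the target resolution (no frequency-axis resize); the time axis is
  linearly resampled to 128 columns (≈ 4.45 ms/px); min–max normalized per
  image with a zero-range guard; low frequencies at the bottom. The raw
  (unfiltered) segment is transformed — the 10 Hz floor requires content
  the band-pass would remove; a flag selects the filtered segment instead.
* **amplitude coding** — the raw segment resampled to 128 columns and
  scaled by its peak |amplitude| (scale-invariant); each column fills
  outward from the midline over rows proportional to |amplitude|, above the
  midline for positive polarity, below for negative.

Geometry presets from 32×32 (10–80 Hz, ±72 ms) to 224×224 (10–500 Hz,
±500 ms) keep the per-pixel resolution constant. Training-time augmentation
draws a center shift uniformly from ±50 ms, re-extracts the window (the
shift exposes new samples), then flips the segment in time with probability
1/2 (order: shift → extract → flip; the flip probability is a parameter,
0.5 by default). Evaluation paths never augment.

## Classifiers, training protocol, pruning

Two binary CNNs act in cascade: artifact model (1 input channel:
time-frequency) then spk model (2 channels: time-frequency + amplitude
coding) on the survivors. The network is a compact 4-stage stack — three
3×3 convolution + ReLU + max-pool blocks (widths 8/16/32, pools 4/4/2) and
a 32-unit dense head — about 2.7 M MACs at 128×128, deliberately far below
the ~600 M of a pre-pruning reference-scale model; widths are
configuration. No compatibility with any externally published weights is
claimed. Inference runs on CPU in fixed-size batches.

Training: Adam, learning rate 3·10⁻⁴, batch 128, 30 epochs, unweighted
cross-entropy (no class weighting), checkpoint = argmin of validation loss.
Evaluation: 5-fold cross-validation — shuffled fold assignment, each sample
in exactly one test fold, the remaining 80% split 7:1 into train/validation
(70%/10% of the whole set) — reporting mean and normal-based 95% confidence
intervals over folds (a t-based interval over 5 folds is ~27% wider; the
normal interval was chosen and is the convention flag's default). Events
whose window touches the first or last second of the recording are labelled
artifact unconditionally, overriding the model.

MACs are counted analytically: output elements × kernel fan-in for
convolutions, weight-matrix size for dense layers. Pruning removes one
convolution output channel per iteration — the smallest-L2-norm filter —
and propagates the removal to the consumer (next convolution's input slice,
or the dense rows that flattening maps to that channel), fine-tuning every
`fine_tune_every` iterations; reference cadence 5000/250/5, with a reduced
preset (8/4/2) used in tests. The criterion is deliberately simple
(magnitude-based with dependency propagation) and swappable.

## Synthetic benchmark

The simulator generates per-channel 1/f^α background noise (spectral
shaping of seeded white noise; α = 1 by default, RMS 10 µV) and injects
three event classes with known intervals:

* **HFO** — Gaussian-enveloped sinusoid; the truth interval is the ±3σ
  envelope support, with duration drawn uniformly from 30–100 ms. Frequency
  is coupled to duration through a fixed cycle count (8 by default, the
  convention of simulated-ripple validation studies), clipped into
  80–250 Hz: a 30 ms "HFO" at 80 Hz would contain 2.4 cycles and fail the
  definitional minimum of several consecutive oscillations; setting
  `hfo_cycles = 0` restores independent draws. Amplitude is an RMS
  signal-to-noise ratio: burst RMS at the envelope peak = `hfo_amplitude` ×
  broadband background RMS (default 6).
* **spkHFO** — an HFO plus a biphasic (derivative-of-Gaussian) spike
  transient.
* **artifact** — a broadband noise burst under the same envelope.

Events are placed round-robin across channels, non-overlapping, ≥ 200 ms
apart, and clear of a 1 s edge margin. Everything derives from one seed.

What the benchmark shows: the full pipeline recovers known high-SNR
injections with correct boundaries, is deterministic, and its stages
compose. What it does not show: performance on clinical iEEG — real
background is nonstationary with physiological rhythms and artifacts far
richer than shaped noise, real HFO morphology is not a windowed sinusoid,
and class boundaries (artifact vs HFO vs spkHFO) are vastly harder than the
high-SNR synthetic separation. Synthetic classification accuracies are
sanity checks of the training protocol, not performance claims.

## Problem sizes in the default test run

The recovery benchmark uses 4 channels × 60 s at 2 kHz with 20 injected
ripples; classifier checks use 300 synthetic events at full 128×128
geometry trained for 30 epochs, and the pruning check 10 epochs plus the
reduced preset. These sizes were chosen so the complete suite runs
comfortably on a single CPU core while still exercising every stage at its
default geometry.

## Known limitations

* Event-level artifact reasoning only; no cross-channel artifact logic.
* No ripple / fast-ripple sub-band separation; one band per run.
* The amplitude-coding construction is a documented column-fill encoding;
  compatibility with any externally published feature pipeline or weights
  is not claimed.
* The MNI reference's randomness location is not publicly specified beyond
  seed exposure; here all draws are centralized in the baseline-pool
  subsampling, documented above.
* EDF reading covers continuous 16-bit EDF/EDF+; BrainVision/BioSemi
  formats and EDF+ discontinuous files are out of scope.
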