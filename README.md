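# hfokit

High-frequency-oscillation (HFO) analysis for intracranial EEG: calibrated
EDF reading, Chebyshev type-II ripple-band filtering, STE and MNI event
detection with channel-parallel execution, CNN-based artifact/spike
classification of detected events, detector-concordance evaluation, and a
synthetic-EEG simulator that makes the whole pipeline testable without
clinical recordings.

## Who this is for

Interictal HFOs (brief oscillations above ~80 Hz in intracranial EEG) are a
candidate biomarker of epileptogenic tissue. Clinical workflows detect them
with automatic detectors, then refine the detections by rejecting artifacts
and separating HFOs that co-occur with epileptiform spikes (spkHFO) from
those that do not. `hfokit` packages that workflow for epilepsy researchers
and engineers: a library plus a small CLI covering read → filter → detect →
classify → export, and the tooling to compare two detectors' outputs
event-by-event.

## The core methods

**Calibration.** EDF stores digital integers; physical values follow the
affine map `V = R·D + O` with `R = (V_max − V_min)/(D_max − D_min)` and
`O = V_min − R·D_min`, exact at both digital range endpoints. (Gain-only
readers that drop `O` leave a DC offset; `hfokit` keeps it.)

**Filtering.** A Chebyshev type-II bandpass (default passband 80–500 Hz,
passband ripple ≤ 0.5 dB, stopband attenuation ≥ 93 dB at 2 kHz sampling),
realized as second-order sections and applied forward–backward (zero
phase). The realized response is verified against the contract on a dense
grid at design time.

**STE detector.** Moving RMS (3 ms window) of the band-passed signal,
thresholded per epoch at `mean + 5·SD`; suprathreshold runs ≥ 6 ms are kept,
runs closer than 10 ms merge, and a run must contain ≥ 6 rectified-signal
peaks above `mean + 3·SD`. Reported boundaries extend outward to where the
RMS trace returns to the epoch mean.

**MNI detector.** Band-pass 80–450 Hz; 125 ms segments are classified as
baseline when the wavelet (Gabor) entropy of their autocorrelation exceeds
0.67 of the theoretical maximum. With ≥ 5 s of baseline per 10 s epoch the
energy threshold is a high quantile (99.9999%) of a gamma CDF fitted to the
baseline energy; otherwise an iterative branch fits a gamma to segment
energies, emits supra-threshold stretches, removes them and refits. All
randomness (baseline subsampling) flows from one user-visible seed, so runs
are bit-for-bit reproducible.

**Classification.** Each detected event is windowed ±285 ms around its
center and rendered as a 128×128 time-frequency image (Gabor scalogram,
10–290 Hz) and a 128×128 amplitude-coding image. A compact CNN cascade
labels events: the artifact model (time-frequency input) separates artifacts
from real HFOs; the spk model (both images) splits real HFOs into
spkHFO/non-spkHFO. Events in the first or last recording second are always
artifacts. Training: Adam (lr 3·10⁻⁴), batch 128, 30 epochs with ±50 ms
shift / time-flip augmentation on the training split only, checkpoint at
minimum validation loss, 5-fold cross-validation with a 70/10/20 split.
Model cost is tracked in MACs, and structured channel pruning (smallest
filter norm, dependencies propagated, periodic fine-tuning) shrinks it.

**Concordance.** Two event sets are compared per channel by the overlap
ratio (interval intersection over union); events pair one-to-one when the
ratio reaches a threshold, maximizing the number of pairs, and the
discrepancy is `(new_A + new_B) / |A|`.

## Worked example

```bash
hfokit simulate --seed 9 --out rec.edf --truth truth.npz
hfokit detect --input rec.edf --detector ste --seed 7 \
              --out events.npz --xlsx report.xlsx
hfokit compare --events-a truth.npz --events-b events.npz
```

The `detect` step prints a JSON run log:

```
{"detector": "ste", "seed": 7, "n_jobs": 1, "params": {...},
 "n_events": 20, "channels": {"CH1": 5, "CH2": 5, "CH3": 5, "CH4": 5}}
```

and `compare` prints the agreement table (counts at exact, 90% and 50%
overlap, plus the events unique to each side):

```
channel  total_a  total_b  exact  overlap_90  overlap_50  new_a  new_b
    CH1        5        5      0           1           5      0      0
    CH2        5        5      0           0           5      0      0
    CH3        5        5      0           1           5      0      0
    CH4        5        5      0           0           5      0      0
  TOTAL       20       20      0           2          20      0      0
```

Here all 20 injected ripples are recovered at ≥ 50% overlap (none are
missed, none invented); boundaries rarely agree to the sample with the
±3σ ground-truth support, so the `exact` row is 0 — exactly the behaviour
the overlap-ratio comparison is designed to quantify.

The same pipeline is available as library calls
(`hfokit.simulate_recording`, `hfokit.detect`, `hfokit.match_events`, …);
see `docs/methods.md` for the model details and parameter meanings.

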