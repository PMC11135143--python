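"""STE / MNI detector behaviour: sub-steps, recovery, invariances."""

import numpy as np
import pytest

import hfokit as hk
from hfokit.detectors import (MniParams, SteParams, channel_seed,
                              detect_mni_channel, detect_ste_channel,
                              fit_gamma_threshold, moving_rms)
from hfokit.filtering import FilterSpec, apply_zero_phase, design_bandpass


def _keys(events):
    return [(e.channel, e.start, e.end) for e in events]


class TestMovingRms:
    def test_constant_signal(self):
        out = moving_rms(np.full(500, -3.0), 0.01, 1000.0)
        assert np.allclose(out, 3.0)

    def test_zero_signal(self):
        assert np.allclose(moving_rms(np.zeros(500), 0.01, 1000.0), 0.0)

    def test_sine_rms_is_inv_sqrt2(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 50.0 * t)
        out = moving_rms(x, 0.02, fs)  # window = one full period
        inner = out[200:-200]
        assert np.allclose(inner, 1 / np.sqrt(2), atol=0.02)

    def test_same_length_and_window_validation(self):
        x = np.arange(100.0)
        assert moving_rms(x, 0.01, 1000.0).size == 100
        with pytest.raises(ValueError):
            moving_rms(x, -1.0, 1000.0)
        with pytest.raises(ValueError):
            moving_rms(x, 1.0, 1000.0)  # window >= signal


class TestGammaThreshold:
    def test_exponential_quantile_oracle(self):
        """Exp(1) is gamma(shape=1): its 95% quantile is -ln(0.05)."""
        rng = np.random.default_rng(42)
        values = rng.exponential(1.0, size=100_000)
        thr = fit_gamma_threshold(values, 95.0)
        assert thr == pytest.approx(-np.log(0.05), rel=0.02)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(3.0, 2.0, size=5000)
        thrs = [fit_gamma_threshold(values, p) for p in (50, 80, 95, 99, 99.999)]
        assert all(a < b for a, b in zip(thrs, thrs[1:]))

    def test_zero_percentile_gives_zero(self):
        rng = np.random.default_rng(0)
        assert fit_gamma_threshold(rng.gamma(2.0, 1.0, 1000), 0.0) == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_threshold(np.ones(100), 95.0)
        with pytest.raises(ValueError):
            fit_gamma_threshold(np.array([1.0, 2.0, -3.0] * 20), 95.0)
        with pytest.raises(ValueError):
            fit_gamma_threshold(np.arange(1.0, 11.0), 95.0)  # too few


@pytest.fixture(scope="module")
def ripple_coeffs():
    return design_bandpass(FilterSpec(pass_low=80.0, pass_high=500.0))


def _noise_with_bursts(centers_s, fs=2000.0, dur_s=10.0, freq=120.0,
                       burst_ms=80.0, snr=8.0, seed=0):
    """Pink noise plus Gaussian-windowed tone bursts; returns (raw, truth)."""
    from hfokit.synthetic import pink_noise
    rng = np.random.default_rng(seed)
    n = int(dur_s * fs)
    x = pink_noise(n, 1.0, rng)
    truth = []
    for c in centers_s:
        sigma = burst_ms / 1000.0 / 6.0
        t = np.arange(n) / fs - c
        x += snr * np.sqrt(2) * np.exp(-t**2 / (2 * sigma**2)) \
            * np.sin(2 * np.pi * freq * t)
        truth.append((int((c - 3 * sigma) * fs), int((c + 3 * sigma) * fs)))
    return x, truth


class TestSteChannel:
    def test_all_zero_no_events(self):
        assert detect_ste_channel(np.zeros(20000), SteParams(), 2000.0) == []

    def test_empty_signal_errors(self):
        with pytest.raises(ValueError):
            detect_ste_channel(np.array([]), SteParams(), 2000.0)

    def test_single_burst_recovered(self, ripple_coeffs):
        raw, truth = _noise_with_bursts([5.0], seed=3)
        filt = apply_zero_phase(raw, ripple_coeffs)
        events = detect_ste_channel(filt, SteParams(), 2000.0)
        assert len(events) == 1
        assert hk.overlap_ratio(events[0], truth[0]) >= 0.5

    def test_two_bursts_vs_merged(self, ripple_coeffs):
        far, _ = _noise_with_bursts([4.0, 6.0], seed=5)
        events = detect_ste_channel(apply_zero_phase(far, ripple_coeffs),
                                    SteParams(), 2000.0)
        assert len(events) == 2
        near, _ = _noise_with_bursts([5.0, 5.06], seed=5)
        events = detect_ste_channel(apply_zero_phase(near, ripple_coeffs),
                                    SteParams(), 2000.0)
        assert len(events) == 1  # abutting bursts collapse to one event

    def test_gap_merge_rule(self):
        from hfokit.detectors import _merge_runs
        runs = [(0, 100), (105, 200), (230, 300)]
        assert _merge_runs(runs, 10) == [(0, 200), (230, 300)]
        assert _merge_runs(runs, 40) == [(0, 300)]
        assert _merge_runs([], 10) == []

    def test_threshold_monotonicity(self, ripple_coeffs):
        raw, _ = _noise_with_bursts([2.0, 5.0, 8.0], seed=9)
        filt = apply_zero_phase(raw, ripple_coeffs)
        counts = [len(detect_ste_channel(filt, SteParams(rms_threshold_sd=k),
                                         2000.0))
                  for k in (3.0, 5.0, 8.0, 15.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_events_sorted_disjoint_min_duration(self, ripple_coeffs):
        raw, _ = _noise_with_bursts([2.0, 4.0, 6.0, 8.0], seed=11)
        params = SteParams()
        events = detect_ste_channel(apply_zero_phase(raw, ripple_coeffs),
                                    params, 2000.0)
        min_len = int(params.min_event_s * 2000.0)
        for (s1, e1), (s2, e2) in zip(events, events[1:]):
            assert e1 <= s2
        for s, e in events:
            assert e - s >= min_len


class TestMniChannel:
    def test_all_zero_no_events(self):
        assert detect_mni_channel(np.zeros(40000), MniParams(), 2000.0, 0) == []

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            detect_mni_channel(np.zeros(100), MniParams(), 2000.0, 0)

    def test_same_seed_bitwise_identical(self):
        raw, _ = _noise_with_bursts([2.0, 5.0, 8.0], dur_s=20.0, seed=13)
        a = detect_mni_channel(raw, MniParams(), 2000.0, 99)
        b = detect_mni_channel(raw, MniParams(), 2000.0, 99)
        assert a == b

    def test_high_snr_bursts_recovered(self):
        centers = [2.0, 5.0, 8.0, 12.0, 16.0]
        raw, truth = _noise_with_bursts(centers, dur_s=20.0, seed=17)
        events = detect_mni_channel(raw, MniParams(), 2000.0, 1)
        hits = sum(
            any(hk.overlap_ratio(ev, tr) >= 0.5 for ev in events)
            for tr in truth
        )
        assert hits >= 4


class TestDetectOrchestration:
    def test_njobs_equivalence(self, sim_recording):
        rec, _ = sim_recording
        r1 = hk.detect(rec, "ste", n_jobs=1, seed=7)
        r4 = hk.detect(rec, "ste", n_jobs=4, seed=7)
        assert _keys(r1.events) == _keys(r4.events)

    def test_single_channel_composition(self, sim_recording, ripple_coeffs):
        rec, _ = sim_recording
        one = rec.pick([rec.channel_names[0]])
        res = hk.detect(one, "ste", n_jobs=1, seed=0)
        direct = detect_ste_channel(
            apply_zero_phase(one.signals[0], ripple_coeffs), SteParams(), 2000.0)
        assert [(e.start, e.end) for e in res.events] == direct

    def test_channel_permutation(self, sim_recording):
        rec, _ = sim_recording
        perm = rec.pick(list(reversed(rec.channel_names)))
        a = hk.detect(rec, "mni", n_jobs=1, seed=5)
        b = hk.detect(perm, "mni", n_jobs=1, seed=5)
        assert sorted(_keys(a.events)) == sorted(_keys(b.events))

    def test_scale_and_dc_invariance(self, sim_recording):
        rec, _ = sim_recording
        base = hk.detect(rec, "ste", n_jobs=1, seed=0)
        moved = hk.Recording(rec.channel_names, rec.sample_rate,
                             rec.signals * 4.2 + 120.0)
        assert _keys(hk.detect(moved, "ste", n_jobs=1, seed=0).events) \
            == _keys(base.events)

    def test_unknown_detector_and_bad_params(self, sim_recording):
        rec, _ = sim_recording
        with pytest.raises(ValueError):
            hk.detect(rec, "hilbert")
        with pytest.raises(TypeError):
            hk.detect(rec, "mni", params=SteParams())

    def test_channel_seed_stability(self):
        assert channel_seed(3, "LA1") == channel_seed(3, "LA1")
        assert channel_seed(3, "LA1") != channel_seed(3, "LA2")
        assert 0 <= channel_seed(2**30, "X") < 2**31


class TestRecovery:
    """End-to-end recovery on the default synthetic study conditions."""

    def test_ste_sensitivity_and_specificity(self, sim_recording,
                                             noise_recording):
        rec, truth = sim_recording
        res = hk.detect(rec, "ste", n_jobs=1, seed=3)
        m = hk.match_events(truth, res.events, threshold=0.5)
        assert len(m) / len(truth) >= 0.95
        clean = hk.detect(noise_recording, "ste", n_jobs=1, seed=3)
        assert len(clean.events) <= 2

    def test_mni_recovery_and_boundaries(self, sim_recording):
        rec, truth = sim_recording
        res = hk.detect(rec, "mni", n_jobs=1, seed=3)
        m = hk.match_events(truth, res.events, threshold=0.5)
        assert len(m) / len(truth) >= 0.8
        errs = []
        for ia, ib, _ in m.pairs:
            errs.append(abs(truth[ia].start - res.events[ib].start))
            errs.append(abs(truth[ia].end - res.events[ib].end))
        assert np.median(errs) / rec.sample_rate <= 0.010
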