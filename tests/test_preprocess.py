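import numpy as np
import pytest
from scipy import signal

from haptic_eeg.bands import BANDS, BROADBAND
from haptic_eeg.preprocess import (band_decompose, bandpass, notch,
                                   preprocess_recording, remove_artifacts,
                                   rereference_car, resample,
                                   segment_sessions)
from haptic_eeg.recording import RawRecording


def _sine_rec(freqs, fs=1000.0, dur=10.0, amps=None, n_ch=2):
    t = np.arange(int(dur * fs)) / fs
    amps = amps or [1.0] * len(freqs)
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
    data = np.tile(x, (n_ch, 1))
    names = [f"ch{i}" for i in range(n_ch)]
    return RawRecording(data, fs, names)


def _band_power(x, fs, lo, hi):
    f, p = signal.periodogram(x, fs=fs)
    return p[(f >= lo) & (f <= hi)].sum()


class TestResample:
    def test_length_ratio(self):
        rec = _sine_rec([10.0], fs=1000.0, dur=10.0)
        out = resample(rec, 200.0)
        assert out.n_samples == 2000
        assert out.fs == 200.0

    def test_passband_amplitude_preserved(self):
        rec = _sine_rec([30.0], fs=1000.0, dur=10.0)
        out = resample(rec, 200.0)
        # compare against the analytic sinusoid on the new grid (skip edges)
        t = np.arange(out.n_samples) / out.fs
        ref = np.sin(2 * np.pi * 30.0 * t)
        mid = slice(200, -200)
        amp = np.abs(out.samples[0][mid]).max()
        assert amp == pytest.approx(1.0, rel=0.01)
        assert np.allclose(out.samples[0][mid], ref[mid], atol=0.02)

    def test_aliased_component_suppressed(self):
        rec = _sine_rec([150.0], fs=1000.0, dur=10.0)
        out = resample(rec, 200.0)
        residual = _band_power(out.samples[0], 200.0, 1, 99)
        original = _band_power(rec.samples[0], 1000.0, 140, 160)
        assert 10 * np.log10(original / max(residual, 1e-300)) > 40

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(_sine_rec([10.0], fs=200.0), 400.0)


class TestFilters:
    def test_dc_removed_by_bandpass(self):
        rec = RawRecording(np.full((2, 2000), 7.5), 200.0, ("a", "b"))
        out = bandpass(rec, 1.0, 50.0)
        assert np.abs(out.samples.mean()) < 0.05

    def test_passband_tone_unchanged(self):
        rec = _sine_rec([20.0], fs=200.0, dur=20.0)
        out = bandpass(rec, 1.0, 50.0)
        # RMS-based amplitude: the sample grid misses the sine peaks
        mid = slice(500, -500)
        amp = np.sqrt(2) * np.std(out.samples[0][mid])
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_notch_attenuates_line(self):
        rec = _sine_rec([50.0], fs=200.0, dur=20.0)
        out = notch(rec, 50.0)
        steady = slice(400, -400)  # exclude filter edge transients
        before = _band_power(rec.samples[0][steady], 200.0, 49, 51)
        after = _band_power(out.samples[0][steady], 200.0, 49, 51)
        assert 10 * np.log10(before / max(after, 1e-300)) > 30

    def test_invalid_corners(self):
        rec = _sine_rec([10.0], fs=200.0)
        with pytest.raises(ValueError):
            bandpass(rec, 50.0, 1.0)
        with pytest.raises(ValueError):
            bandpass(rec, 1.0, 150.0)


class TestICA:
    @pytest.fixture
    def clean_rec(self, rng):
        fs = 200.0
        data = rng.normal(0, 10, size=(6, 4000))
        sos = signal.butter(4, (1, 50), "bandpass", fs=fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
        names = ("Fp1", "Fp2", "F3", "F4", "O1", "O2")
        return RawRecording(data, fs, names)

    def test_clean_recording_nearly_unchanged(self, clean_rec):
        out = remove_artifacts(clean_rec, seed=0)
        rel = np.linalg.norm(out.samples - clean_rec.samples) / \
            np.linalg.norm(clean_rec.samples)
        assert rel < 0.05

    def test_frontal_bursts_suppressed(self, clean_rec, rng):
        fs = clean_rec.fs
        burst = np.zeros(clean_rec.n_samples)
        for i0 in (300, 1400, 2600, 3300):
            burst[i0:i0 + 160] += 120 * np.hanning(160)
        noisy = clean_rec.samples.copy()
        noisy[0] += burst
        noisy[1] += burst
        rec = clean_rec.with_samples(noisy)
        out = remove_artifacts(rec, seed=0)
        before = _band_power(rec.samples[0], fs, 0.3, 3)
        after = _band_power(out.samples[0], fs, 0.3, 3)
        assert after < 0.5 * before
        assert out.meta["ica"]["rejected"]

    def test_seed_determinism(self, clean_rec):
        a = remove_artifacts(clean_rec, seed=3)
        b = remove_artifacts(clean_rec, seed=3)
        assert np.array_equal(a.samples, b.samples)

    def test_single_channel_rejected(self):
        rec = RawRecording(np.zeros((1, 100)), 100.0, ("Fp1",))
        with pytest.raises(ValueError):
            remove_artifacts(rec)


class TestCAR:
    def test_channel_mean_zero(self, rng):
        rec = RawRecording(rng.normal(0, 5, (6, 500)), 100.0,
                           ("a", "b", "c", "d", "e", "f"))
        out = rereference_car(rec)
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-9

    def test_reference_channel_recovered(self, rng):
        rec = RawRecording(rng.normal(0, 5, (4, 500)), 100.0,
                           ("a", "b", "c", "d"))
        out = rereference_car(rec)
        assert out.channel_names[-1] == "FCz"
        assert out.n_channels == 5

    def test_idempotent(self, rng):
        rec = RawRecording(rng.normal(0, 5, (4, 500)), 100.0,
                           ("a", "b", "c", "d"))
        once = rereference_car(rec)
        twice = rereference_car(once)
        assert np.allclose(once.samples, twice.samples, atol=1e-12)
        assert once.channel_names == twice.channel_names

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_car(RawRecording(np.zeros((1, 10)), 10.0, ("a",)))


class TestSegmentation:
    def test_two_segments_per_session(self, experiment, segments0):
        cfg, _, annotations, _ = experiment
        n_sessions = len([a for a in annotations if a.subject == 0])
        assert len(segments0) == 2 * n_sessions
        conditions = {s.condition for s in segments0}
        assert conditions == {"non-haptic", "haptic"}

    def test_half_lengths_and_baseline(self, experiment, segments0):
        cfg, _, _, _ = experiment
        half = int(cfg.clip_duration_s / 2 * 200)
        for s in segments0:
            assert s.n_samples == half
            assert s.baseline.shape[1] == int(5.0 * 200)

    def test_out_of_bounds_annotation_named(self, experiment):
        import dataclasses
        _, recordings, annotations, _ = experiment
        bad = dataclasses.replace(annotations[0], session_id=99,
                                  clip_onset_s=1e6, haptic_onset_s=1e6 + 4,
                                  clip_end_s=1e6 + 8)
        with pytest.raises(ValueError, match="99"):
            segment_sessions(recordings[0], [bad])


class TestBandDecompose:
    def test_five_bands(self, segments0):
        bands = band_decompose(segments0[0])
        assert [b.band for b in bands] == [b.name for b in BANDS]

    def test_variance_partition(self, segments0):
        seg = segments0[0]
        bands = band_decompose(seg)
        total = seg.samples.var(axis=1)
        summed = sum(b.samples.var(axis=1) for b in bands)
        ratio = summed / total
        assert np.all(ratio > 0.9) and np.all(ratio < 1.1)

    def test_pure_alpha_tone_lands_in_alpha(self):
        from haptic_eeg.preprocess import SessionSegment
        fs = 200.0
        t = np.arange(int(10 * fs)) / fs
        seg = SessionSegment(np.sin(2 * np.pi * 10 * t)[None, :], fs, ("Cz",),
                             0, 0, "joy", "haptic1", "haptic")
        bands = band_decompose(seg)
        variances = {b.band: b.samples.var() for b in bands}
        assert variances["alpha"] / sum(variances.values()) >= 0.95


def test_chain_is_reproducible(experiment):
    cfg, recordings, annotations, _ = experiment
    anns = [a for a in annotations if a.subject == 1]
    a = preprocess_recording(recordings[1], anns, run_ica=True, ica_seed=5)
    b = preprocess_recording(recordings[1], anns, run_ica=True, ica_seed=5)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.samples, sb.samples)
    assert a[0].channel_names[-1] == "FCz"
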