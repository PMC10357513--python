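import numpy as np
import pytest
from scipy import signal

from haptic_eeg.bands import BANDS
from haptic_eeg.montage import TEMPORAL_CHANNELS
from haptic_eeg.simulate import (BandPowerProfile, GeneratorConfig,
                                 default_profile, generate_experiment,
                                 generate_volume_trace, scaled_config)


def _tiny(**kw):
    return scaled_config(n_subjects=1, clip_duration_s=8.0, rest_s=1.0, **kw)


class TestProtocolStructure:
    def test_16_sessions_with_8_8_pattern_split(self, experiment):
        _, recordings, annotations, manifest = experiment
        for subject in manifest.subject.unique():
            sub = manifest[manifest.subject == subject]
            assert len(sub) == 16
            assert sub.pattern.value_counts().to_dict() == {
                "haptic1": 8, "haptic2": 8}
            # per-emotion balance keeps every class present per pattern
            per = sub.groupby(["emotion", "pattern"]).size()
            assert set(per) == {2}

    def test_haptic_onset_is_clip_midpoint(self, experiment):
        _, _, _, manifest = experiment
        mid = (manifest.clip_onset_s + manifest.clip_end_s) / 2
        assert np.allclose(manifest.haptic_onset_s, mid)

    def test_cue_precedes_clip_by_cue_s(self, experiment):
        cfg, _, _, manifest = experiment
        assert np.allclose(manifest.clip_onset_s - manifest.cue_onset_s, cfg.cue_s)

    def test_one_recording_per_subject(self, experiment):
        cfg, recordings, _, _ = experiment
        assert len(recordings) == cfg.n_subjects
        assert all(r.n_channels == 63 for r in recordings)

    def test_determinism_same_seed(self):
        a = generate_experiment(_tiny(seed=42))
        b = generate_experiment(_tiny(seed=42))
        assert np.array_equal(a[0][0].samples, b[0][0].samples)
        assert a[2].equals(b[2])

    def test_different_seed_differs(self):
        a = generate_experiment(_tiny(seed=1))
        b = generate_experiment(_tiny(seed=2))
        assert not np.array_equal(a[0][0].samples, b[0][0].samples)


class TestConfigValidation:
    def test_sessions_not_divisible_by_emotions(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_sessions=15)

    def test_haptic_gain_below_one(self):
        with pytest.raises(ValueError):
            GeneratorConfig(haptic_gain=0.5)

    def test_nonpositive_variance_rejected(self):
        prof = default_profile()
        with pytest.raises(ValueError):
            BandPowerProfile(base={**prof.base, "alpha": 0.0},
                             groups=prof.groups, gains=prof.gains)

    def test_unknown_group_rejected(self):
        prof = default_profile()
        with pytest.raises(ValueError):
            BandPowerProfile(base=prof.base, groups=prof.groups,
                             gains={"joy": {("nowhere", "gamma"): 2.0}})


class TestSignalModel:
    def test_alpha_only_profile_concentrates_variance(self):
        prof = default_profile()
        base = {b.name: (10.0 if b.name == "alpha" else 1e-8) for b in BANDS}
        cfg = _tiny(seed=3, line_amp=0.0, eog_amp=0.0,
                    profile=BandPowerProfile(base=base, groups=prof.groups,
                                             gains={"neutral": {}}))
        rec = generate_experiment(cfg)[0][0]
        x = rec.samples[10]
        f, p = signal.periodogram(x, fs=cfg.fs)
        in_band = p[(f >= 8) & (f <= 14)].sum() / p.sum()
        assert in_band >= 0.95

    def test_unit_gain_halves_exchangeable(self):
        # with no separation gain, haptic and non-haptic halves of a session
        # have the same band variance distribution
        cfg = _tiny(seed=9, haptic_gain=1.0, line_amp=0.0, eog_amp=0.0)
        recs, anns, _ = generate_experiment(cfg)
        rec = recs[0]
        ti = [rec.channel_index(c) for c in TEMPORAL_CHANNELS]
        log_ratios = []
        for a in anns:
            i0 = int(a.clip_onset_s * cfg.fs)
            im = int(a.haptic_onset_s * cfg.fs)
            i1 = int(a.clip_end_s * cfg.fs)
            v_non = rec.samples[ti, i0:im].var(axis=1)
            v_hap = rec.samples[ti, im:i1].var(axis=1)
            log_ratios.append(np.log(v_hap / v_non).mean())
        from scipy import stats
        t, p = stats.ttest_1samp(log_ratios, 0.0)
        assert p > 0.01

    def test_separation_gain_raises_haptic_half_variance(self):
        cfg = _tiny(seed=9, haptic_gain=2.0, line_amp=0.0, eog_amp=0.0)
        recs, anns, _ = generate_experiment(cfg)
        rec = recs[0]
        ti = [rec.channel_index(c) for c in TEMPORAL_CHANNELS]
        joy = [a for a in anns if a.emotion == "joy"]
        ratios = []
        for a in joy:
            i0 = int(a.clip_onset_s * cfg.fs)
            im = int(a.haptic_onset_s * cfg.fs)
            i1 = int(a.clip_end_s * cfg.fs)
            ratios.append(rec.samples[ti, im:i1].var(axis=1).mean()
                          / rec.samples[ti, i0:im].var(axis=1).mean())
        assert np.mean(ratios) > 1.1

    def test_separation_confined_to_configured_channels(self):
        # occipital/parietal channels carry no emotion signal in gamma
        cfg = _tiny(seed=12, line_amp=0.0, eog_amp=0.0)
        recs, anns, _ = generate_experiment(cfg)
        rec = recs[0]
        oi = [rec.channel_index(c) for c in ("O1", "Oz", "O2", "Pz")]
        sos = signal.butter(4, (31, 50), "bandpass", fs=cfg.fs, output="sos")
        g = signal.sosfiltfilt(sos, rec.samples[oi], axis=1)
        by_emotion = {}
        for a in anns:
            i0 = int(a.clip_onset_s * cfg.fs)
            i1 = int(a.clip_end_s * cfg.fs)
            by_emotion.setdefault(a.emotion, []).append(g[:, i0:i1].var(axis=1).mean())
        means = {k: np.mean(v) for k, v in by_emotion.items()}
        assert max(means.values()) / min(means.values()) < 1.15


class TestVolumeTrace:
    def test_nonnegative_with_silences(self, rng):
        vol = generate_volume_trace(rng, 60.0)
        assert np.all(vol.samples >= 0)
        assert np.any(vol.samples == 0)

    def test_haptic2_sessions_have_events(self, experiment):
        _, _, annotations, _ = experiment
        h2 = [a for a in annotations if a.haptic_pattern == "haptic2"]
        assert all(len(a.schedule) > 0 for a in h2)

    def test_neutral_haptic1_sessions_have_no_events(self, experiment):
        _, _, annotations, _ = experiment
        neutral1 = [a for a in annotations
                    if a.haptic_pattern == "haptic1" and a.emotion == "neutral"]
        assert neutral1 and all(len(a.schedule) == 0 for a in neutral1)
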