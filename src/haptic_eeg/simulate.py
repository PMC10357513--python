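"""Synthetic haptic-EEG experiment generator.

Stands in for the study protocol's (undeposited) recordings: 63-channel
10-20 EEG at 1 kHz, 16 sessions per subject, each a 5-s cue followed by a
movie clip with vibrotactile stimulation confined to the clip's second half.
Four emotion classes (joy, sadness, fear, neutral) leave their signature as
class-dependent beta/gamma band-power concentrated in lateral-temporal and
prefrontal channels.

Signal model: each channel is a sum over the five canonical bands of
band-limited Gaussian noise (filtered white noise), stationary within a
condition half.  Emotion classes multiply the variance of discriminative
(channel-group, band) components; the haptic separation gain amplifies that
class deviation during the haptic half, so ``haptic_gain = 1`` makes the two
halves statistically exchangeable.  50 Hz line interference and low-frequency
frontal EOG-like bursts are added on top.  No 1/f shaping or volume
conduction beyond per-band variances is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BANDS, BandDefinition
from .haptics import (HapticSchedule, NoScheduleError, VolumeTrace,
                      haptic1_schedule, haptic2_schedule)
from .montage import PREFRONTAL_CHANNELS, TEMPORAL_CHANNELS, standard_montage
from .recording import EventMarker, RawRecording

__all__ = [
    "BandPowerProfile",
    "GeneratorConfig",
    "SessionAnnotation",
    "default_profile",
    "generate_experiment",
    "generate_volume_trace",
    "EMOTIONS",
]

EMOTIONS = ("joy", "sadness", "fear", "neutral")

#: frontal channels receiving the EOG source, with scalp fall-off weights
_EOG_WEIGHTS = {"Fp1": 1.0, "Fp2": 1.0, "AF7": 0.8, "AF3": 0.7,
                "AF4": 0.7, "AF8": 0.8}


@dataclass(frozen=True)
class BandPowerProfile:
    """Target band variances and emotion-discriminative gains.

    ``base`` maps band name -> background variance (µV²) on every channel.
    ``groups`` names channel groups; ``gains`` maps emotion ->
    {(group, band): variance multiplier} applied on top of the background
    within the clip.  Emotions absent from ``gains`` (neutral) carry no
    deviation, and so no haptic modulation either.
    """

    base: dict[str, float]
    groups: dict[str, tuple[str, ...]]
    gains: dict[str, dict[tuple[str, str], float]]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.base.values()):
            raise ValueError("base band variances must be positive")
        for emo, g in self.gains.items():
            for (grp, band), mult in g.items():
                if grp not in self.groups:
                    raise ValueError(f"unknown channel group {grp!r} for {emo}")
                if band not in self.base:
                    raise ValueError(f"unknown band {band!r} for {emo}")
                if mult <= 0:
                    raise ValueError("gain multipliers must be positive")


def default_profile() -> BandPowerProfile:
    """Defaults chosen once for the stated world (see the methods note).

    Background variances fall with frequency (a coarse 1/f stand-in); each
    non-neutral emotion boosts beta/gamma variance in temporal and/or
    prefrontal groups with distinct signatures so a linear classifier can
    separate the four classes from entropy features.
    """
    left_t = tuple(c for c in TEMPORAL_CHANNELS if c.endswith(("7", "9")) or c == "C5")
    right_t = tuple(c for c in TEMPORAL_CHANNELS if c not in left_t)
    left_p = ("Fp1", "AF7", "AF3")
    right_p = ("Fp2", "AF8", "AF4")
    return BandPowerProfile(
        base={"delta": 20.0, "theta": 12.0, "alpha": 10.0,
              "beta": 6.0, "gamma": 4.0},
        groups={"temporal_left": left_t, "temporal_right": right_t,
                "prefrontal_left": left_p, "prefrontal_right": right_p},
        # approach emotions lean left, withdrawal emotions lean right, giving
        # the hemispheric-asymmetry features a class signal as well
        gains={
            "joy": {("temporal_left", "gamma"): 2.8, ("temporal_right", "gamma"): 2.2,
                    ("temporal_left", "beta"): 1.6, ("temporal_right", "beta"): 1.4},
            "sadness": {("prefrontal_left", "beta"): 2.0, ("prefrontal_right", "beta"): 2.4,
                        ("prefrontal_left", "gamma"): 1.6, ("prefrontal_right", "gamma"): 2.0},
            "fear": {("temporal_left", "beta"): 2.0, ("temporal_right", "beta"): 2.4,
                     ("temporal_left", "gamma"): 1.6, ("temporal_right", "gamma"): 1.6,
                     ("prefrontal_left", "gamma"): 1.4, ("prefrontal_right", "gamma"): 1.4},
            "neutral": {},
        },
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 16
    n_sessions: int = 16
    emotions: tuple[str, ...] = EMOTIONS
    clip_duration_s: float = 240.0
    cue_s: float = 5.0
    rest_s: float = 5.0  # inter-session gap (self-assessment/rest, collapsed)
    fs: float = 1000.0
    profile: BandPowerProfile = field(default_factory=default_profile)
    haptic_gain: float = 1.5
    session_jitter_sd: float = 0.15  # lognormal sd of per-session log-gains
    line_amp: float = 5.0   # 50 Hz interference amplitude, µV
    line_freq: float = 50.0
    eog_amp: float = 60.0   # frontal EOG burst amplitude, µV
    eog_rate_hz: float = 0.1  # burst rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions % len(self.emotions):
            raise ValueError("n_sessions must be divisible by the number of emotions")
        if self.n_sessions // len(self.emotions) % 2:
            raise ValueError("sessions per emotion must be even for the 50/50 "
                             "haptic-pattern split")
        if self.haptic_gain < 1:
            raise ValueError("haptic_gain must be >= 1")
        if self.clip_duration_s <= 0 or self.cue_s <= 0 or self.fs <= 0:
            raise ValueError("durations and sampling rate must be positive")
        for b in BANDS:
            if b.hi > self.fs / 2:
                raise ValueError(f"band {b.name} exceeds Nyquist at fs={self.fs}")


@dataclass(frozen=True)
class SessionAnnotation:
    subject: int
    session_id: int
    emotion: str
    haptic_pattern: str  # "haptic1" | "haptic2"
    cue_onset_s: float
    clip_onset_s: float
    haptic_onset_s: float
    clip_end_s: float
    schedule: HapticSchedule | None = None

    def __post_init__(self) -> None:
        mid = 0.5 * (self.clip_onset_s + self.clip_end_s)
        if abs(self.haptic_onset_s - mid) > 1e-6:
            raise ValueError("haptic onset must be the clip midpoint")


def _band_noise(rng: np.random.Generator, n_ch: int, n: int,
                band: BandDefinition, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, channels independent."""
    sos = signal.butter(4, (band.lo, band.hi), "bandpass", fs=fs, output="sos")
    # white-noise energy gain of the forward-backward filter, computed once
    w, h = signal.sosfreqz(sos, worN=4096, fs=fs)
    gain2 = float(np.mean(np.abs(h) ** 4))  # |H|^4: filtfilt applies H twice
    x = rng.standard_normal((n_ch, n))
    y = signal.sosfiltfilt(sos, x, axis=1)
    return y / np.sqrt(gain2)


def generate_volume_trace(rng: np.random.Generator, duration_s: float,
                          rate: float = 10.0) -> VolumeTrace:
    """Smoothed nonnegative loudness with occasional silences.

    Emulates a clip soundtrack well enough to exercise the adaptive haptic
    pattern's silence threshold.
    """
    n = max(int(round(duration_s * rate)), 1)
    x = rng.standard_normal(n + 20)
    kernel = np.hanning(21)
    smooth = np.convolve(x, kernel / kernel.sum(), mode="same")[10:10 + n]
    vol = np.abs(smooth)
    # carve out silences: a few randomly placed gaps of ~10% total duration
    n_gaps = max(1, int(duration_s / 10))
    for _ in range(n_gaps):
        start = rng.integers(0, n)
        width = int(rng.integers(1, max(2, n // 10)))
        vol[start:start + width] = 0.0
    return VolumeTrace(vol, rate)


def _session_layout(cfg: GeneratorConfig) -> tuple[list[dict], int]:
    """Session timing grid (in seconds, sample-aligned) and total samples."""
    t = cfg.cue_s  # lead-in before the first cue
    out = []
    for k in range(cfg.n_sessions):
        cue = t
        clip = cue + cfg.cue_s
        end = clip + cfg.clip_duration_s
        out.append({"cue": cue, "clip": clip,
                    "haptic": clip + cfg.clip_duration_s / 2, "end": end})
        t = end + cfg.rest_s
    n_total = int(round((t + cfg.cue_s) * cfg.fs))
    return out, n_total


def _assign_sessions(rng: np.random.Generator, cfg: GeneratorConfig
                     ) -> list[tuple[str, str]]:
    """Shuffled (emotion, pattern) list with a balanced 8/8 pattern split.

    Each emotion's sessions are split evenly between the two patterns so
    that per-pattern evaluation always sees every class.
    """
    per = cfg.n_sessions // len(cfg.emotions)
    slots = []
    for emo in cfg.emotions:
        patterns = ["haptic1"] * (per // 2) + ["haptic2"] * (per // 2)
        rng.shuffle(patterns)
        slots.extend((emo, p) for p in patterns)
    order = rng.permutation(len(slots))
    return [slots[i] for i in order]


def _generate_subject(rng: np.random.Generator, cfg: GeneratorConfig,
                      subject: int, channels: tuple[str, ...]
                      ) -> tuple[RawRecording, list[SessionAnnotation]]:
    layout, n_total = _session_layout(cfg)
    assignment = _assign_sessions(rng, cfg)
    n_ch = len(channels)
    fs = cfg.fs
    ch_index = {c: i for i, c in enumerate(channels)}
    prof = cfg.profile

    data = np.zeros((n_ch, n_total))
    for band in BANDS:
        noise = _band_noise(rng, n_ch, n_total, band, fs)
        noise *= np.sqrt(prof.base[band.name])
        for (emo, _pat), times in zip(assignment, layout):
            gains = prof.gains.get(emo, {})
            i_clip = int(round(times["clip"] * fs))
            i_mid = int(round(times["haptic"] * fs))
            i_end = int(round(times["end"] * fs))
            jitters: dict = {}
            for (grp, bname), mult in sorted(gains.items()):
                if bname != band.name:
                    continue
                # per-session arousal jitter, shared within a bilateral region
                # so asymmetry ratios stay stable; the haptic half amplifies
                # the class deviation (m - 1) by the separation gain
                fam = grp.removesuffix("_left").removesuffix("_right")
                jitter = jitters.setdefault(
                    (fam, bname),
                    float(np.exp(rng.normal(0.0, cfg.session_jitter_sd))))
                m0 = mult * jitter
                m1 = 1.0 + (m0 - 1.0) * cfg.haptic_gain
                rows = np.array([ch_index[c] for c in prof.groups[grp]
                                 if c in ch_index])
                noise[rows, i_clip:i_mid] *= np.sqrt(m0)
                noise[rows, i_mid:i_end] *= np.sqrt(m1)
        data += noise
        del noise

    # 50 Hz line interference, common to all channels
    t = np.arange(n_total) / fs
    phase = rng.uniform(0, 2 * np.pi)
    data += cfg.line_amp * np.sin(2 * np.pi * cfg.line_freq * t + phase)

    # EOG: one low-frequency burst source projected onto frontal channels
    if cfg.eog_amp > 0:
        n_bursts = rng.poisson(cfg.eog_rate_hz * n_total / fs)
        source = np.zeros(n_total)
        width = int(0.8 * fs)
        for _ in range(n_bursts):
            i0 = int(rng.integers(0, max(n_total - width, 1)))
            amp = cfg.eog_amp * rng.uniform(0.6, 1.4) * rng.choice([1.0, -1.0], p=[0.8, 0.2])
            source[i0:i0 + width] += amp * np.hanning(width)[:n_total - i0][:width]
        for c, w in _EOG_WEIGHTS.items():
            if c in ch_index:
                data[ch_index[c]] += w * source

    annotations: list[SessionAnnotation] = []
    markers: list[EventMarker] = []
    for k, ((emo, pat), times) in enumerate(zip(assignment, layout)):
        if pat == "haptic1":
            try:
                sched = haptic1_schedule(emo, cfg.clip_duration_s / 2)
            except NoScheduleError:
                sched = HapticSchedule(())  # no fixed pattern defined for neutral
        else:
            vol = generate_volume_trace(rng, cfg.clip_duration_s / 2)
            thr = float(np.quantile(vol.samples, 0.3))
            sched = haptic2_schedule(vol, threshold=thr)
        annotations.append(SessionAnnotation(
            subject, k, emo, pat, times["cue"], times["clip"],
            times["haptic"], times["end"], sched))
        markers.append(EventMarker(times["cue"], cfg.cue_s, f"cue/{k}"))
        markers.append(EventMarker(times["clip"], cfg.clip_duration_s,
                                   f"clip/{k}/{emo}/{pat}"))
        markers.append(EventMarker(times["haptic"], cfg.clip_duration_s / 2,
                                   f"haptic/{k}"))
    rec = RawRecording(data, fs, channels, tuple(markers),
                       meta={"subject": subject})
    return rec, annotations


def generate_experiment(cfg: GeneratorConfig
                        ) -> tuple[list[RawRecording], list[SessionAnnotation],
                                   pd.DataFrame]:
    """One recording per subject + session annotations + manifest table.

    Identical config (including seed) yields bit-identical output.
    """
    montage = standard_montage()
    channels = montage.usable_channels  # FCz reference is implicit, not recorded
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    recordings, annotations = [], []
    for s, ss in enumerate(streams):
        rec, anns = _generate_subject(np.random.default_rng(ss), cfg, s, channels)
        recordings.append(rec)
        annotations.extend(anns)
    manifest = pd.DataFrame([{
        "subject": a.subject, "session": a.session_id, "emotion": a.emotion,
        "pattern": a.haptic_pattern, "cue_onset_s": a.cue_onset_s,
        "clip_onset_s": a.clip_onset_s, "haptic_onset_s": a.haptic_onset_s,
        "clip_end_s": a.clip_end_s,
        "n_haptic_events": len(a.schedule) if a.schedule else 0,
    } for a in annotations])
    return recordings, annotations, manifest


def scaled_config(**overrides) -> GeneratorConfig:
    """A desk-scale config: short clips, 200 Hz, fewer subjects.

    Used by tests and analysis drivers; statistical structure is unchanged,
    only durations/rates shrink.
    """
    defaults = dict(n_subjects=2, clip_duration_s=24.0, cue_s=5.0,
                    rest_s=2.0, fs=200.0)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
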