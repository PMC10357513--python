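"""Vibrotactile stimulus scheduling for the haptic vest.

Two patterns are modelled.  Pattern 1 is the fixed scheme from the wearable
affective-haptics literature: each emotion maps to a constant pulse rate and
intensity (joy 1.4 Hz at 90 %, sadness 0.45 Hz at 50 %, fear 0.5 Hz at 90 %;
no vibration is defined for neutral clips).  Pattern 2 is adaptive: intensity
follows the clip's audio volume through a clipped affine map, and a silence
threshold gates the rhythm (no vibration below the threshold).

The vest's 5x4 motor matrix is collapsed to a single global intensity
channel; spatial motor patterns are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HapticEvent",
    "HapticSchedule",
    "VolumeTrace",
    "HAPTIC1_PARAMS",
    "adaptive_intensity",
    "haptic1_schedule",
    "haptic2_schedule",
    "NoScheduleError",
]

#: Fixed-pattern parameters: emotion -> (pulse frequency Hz, intensity %).
HAPTIC1_PARAMS: dict[str, tuple[float, float]] = {
    "joy": (1.4, 90.0),
    "sadness": (0.45, 50.0),
    "fear": (0.5, 90.0),
}


class NoScheduleError(ValueError):
    """Raised when no haptic schedule is defined for the requested emotion."""


@dataclass(frozen=True)
class HapticEvent:
    onset_s: float
    duration_s: float
    intensity: float  # percent, 0-100

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity <= 100.0):
            raise ValueError(f"intensity {self.intensity} outside [0, 100]")
        if self.duration_s < 0 or self.onset_s < 0:
            raise ValueError("negative onset/duration")


@dataclass(frozen=True)
class HapticSchedule:
    events: tuple[HapticEvent, ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for ev in self.events:
            if ev.onset_s < prev_end - 1e-12:
                raise ValueError("haptic events overlap or are out of order")
            prev_end = ev.onset_s + ev.duration_s

    def __len__(self) -> int:
        return len(self.events)

    def intensity_trace(self, fs: float, duration_s: float) -> np.ndarray:
        """Sample the schedule to a regular intensity trace (percent)."""
        n = int(round(duration_s * fs))
        out = np.zeros(n)
        for ev in self.events:
            i0 = int(round(ev.onset_s * fs))
            i1 = int(round((ev.onset_s + ev.duration_s) * fs))
            out[i0:min(i1, n)] = ev.intensity
        return out


@dataclass(frozen=True)
class VolumeTrace:
    """Nonnegative loudness samples of a clip's audio track."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, float))
        if self.samples.size and self.samples.min() < 0:
            raise ValueError("volume samples must be nonnegative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def haptic1_schedule(emotion: str, duration_s: float,
                     pulse_duration_s: float = 0.2) -> HapticSchedule:
    """Fixed-rhythm pattern: periodic discrete pulses for the whole duration.

    ``pulse_duration_s`` is clipped to the pulse period so events never
    overlap at the highest rate.
    """
    if emotion not in HAPTIC1_PARAMS:
        raise NoScheduleError(
            f"no fixed haptic parameters defined for emotion {emotion!r}")
    freq, intensity = HAPTIC1_PARAMS[emotion]
    period = 1.0 / freq
    width = min(pulse_duration_s, 0.5 * period)
    events = []
    k = 0
    while k * period + width <= duration_s + 1e-12:
        events.append(HapticEvent(k * period, width, intensity))
        k += 1
    return HapticSchedule(tuple(events))


def adaptive_intensity(v: np.ndarray, threshold: float, i_min: float,
                       i_max: float, v_max: float) -> np.ndarray:
    """Per-sample volume -> intensity map of the adaptive pattern.

    Zero at or below the threshold, then affine in loudness, clipped to
    [i_min, i_max].  Monotone nondecreasing in ``v`` by construction.
    """
    v = np.asarray(v, float)
    span = v_max - threshold
    if span <= 0:
        inten = np.full(v.shape, i_max)
    else:
        inten = i_min + (np.clip(v, threshold, v_max) - threshold) / span * (i_max - i_min)
    return np.where(v > threshold, inten, 0.0)


def haptic2_schedule(vol: VolumeTrace, threshold: float,
                     i_min: float = 30.0, i_max: float = 100.0,
                     v_max: float | None = None) -> HapticSchedule:
    """Adaptive pattern: intensity tracks volume, silence gates the rhythm.

    Samples at or below ``threshold`` produce no vibration.  Above it the
    intensity is an affine, clipped, monotone nondecreasing map of loudness
    onto [i_min, i_max]; ``v_max`` (default: trace maximum) is the loudness
    that saturates at ``i_max``.  Consecutive above-threshold samples merge
    into one event carrying their mean intensity.
    """
    if i_min > i_max:
        raise ValueError("i_min must not exceed i_max")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    v = vol.samples
    if v.size == 0:
        return HapticSchedule(())
    if v_max is None:
        v_max = float(v.max())
    active = v > threshold
    if not active.any():
        return HapticSchedule(())
    inten = adaptive_intensity(v, threshold, i_min, i_max, v_max)
    dt = 1.0 / vol.rate
    events = []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], active, [False]))))
    for start, stop in edges.reshape(-1, 2):
        events.append(HapticEvent(start * dt, (stop - start) * dt,
                                  float(np.clip(inten[start:stop].mean(), 0, 100))))
    return HapticSchedule(tuple(events))
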