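"""In-memory containers for multichannel EEG recordings and event markers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EventMarker", "RawRecording"]


@dataclass(frozen=True)
class EventMarker:
    """A timed annotation on a recording (onset/duration in seconds)."""

    onset_s: float
    duration_s: float
    description: str


@dataclass
class RawRecording:
    """channels x samples signal (microvolts) with its sampling rate and events."""

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    annotations: tuple[EventMarker, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        self.channel_names = tuple(self.channel_names)
        self.annotations = tuple(self.annotations)
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def with_samples(self, samples: np.ndarray, fs: float | None = None,
                     channel_names=None) -> "RawRecording":
        return replace(
            self, samples=samples,
            fs=self.fs if fs is None else fs,
            channel_names=self.channel_names if channel_names is None
            else tuple(channel_names),
            meta=dict(self.meta))
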