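"""Frequency-domain feature extraction: PSD, DE, DASM, DCAU.

All features are computed on non-overlapping 1-s windows:

* PSD — mean spectral energy per band from a 256-point short-time Fourier
  transform of the Hanning-tapered window (200 samples at 200 Hz, zero-padded
  to 256).
* DE — differential entropy of the band-filtered window under a Gaussian
  model, ``h(X) = 1/2 ln(2 pi e sigma^2)`` in nats, with sigma^2 the sample
  variance.  For a fixed-length Gaussian series this equals the logarithmic
  spectral energy in the band up to an additive constant, which is exploited
  as a cross-check in the test suite.
* DASM — DE difference between the 28 left-right homologous electrode pairs.
* DCAU — DE difference between the 22 frontal-posterior electrode pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bands import BAND_NAMES, BANDS, BandDefinition
from .montage import ElectrodePair
from .preprocess import SessionSegment

__all__ = [
    "FeatureTensor",
    "FeatureDataset",
    "differential_entropy",
    "psd_features",
    "de_features",
    "dasm",
    "dcau",
    "assemble_dataset",
]

WINDOW_S = 1.0
NFFT = 256
#: variance floor for degenerate (all-zero) windows
VAR_FLOOR = 1e-30


@dataclass
class FeatureTensor:
    """windows x units x bands feature values with labelled axes."""

    kind: str  # PSD | DE | DASM | DCAU
    values: np.ndarray
    units_axis: tuple[str, ...]
    band_axis: tuple[str, ...]
    window_s: float = WINDOW_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.units_axis = tuple(self.units_axis)
        self.band_axis = tuple(self.band_axis)
        if self.values.ndim != 3:
            raise ValueError("feature values must be windows x units x bands")
        if self.values.shape[1:] != (len(self.units_axis), len(self.band_axis)):
            raise ValueError("axis labels inconsistent with value shape")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def unit_index(self, label: str) -> int:
        try:
            return self.units_axis.index(label)
        except ValueError:
            raise KeyError(f"unit {label!r} not in feature tensor") from None

    def select_units(self, labels) -> "FeatureTensor":
        idx = [self.unit_index(u) for u in labels]
        return FeatureTensor(self.kind, self.values[:, idx, :],
                             tuple(labels), self.band_axis, self.window_s)

    def band_slice(self, band: str) -> np.ndarray:
        return self.values[:, :, self.band_axis.index(band)]


@dataclass
class FeatureDataset:
    """Classifier-ready matrix: one row per window, session-tagged."""

    X: np.ndarray
    y: np.ndarray          # emotion labels
    groups: np.ndarray     # session ids, for group-aware folding
    kind: str
    band_selection: str    # one band name or "total"
    subject: int | None = None
    condition: str | None = None
    pattern: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must align row-wise")
        if self.X.size and not np.isfinite(self.X).all():
            raise ValueError("non-finite feature values")


def differential_entropy(variance: np.ndarray) -> np.ndarray:
    """Gaussian differential entropy in nats: 1/2 ln(2 pi e sigma^2)."""
    v = np.maximum(np.asarray(variance, float), VAR_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * np.e * v)


def _windows(samples: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Reshape channels x time into windows x channels x window-samples."""
    wlen = int(round(fs * window_s))
    n_win = samples.shape[1] // wlen
    cut = samples[:, :n_win * wlen]
    return cut.reshape(samples.shape[0], n_win, wlen).transpose(1, 0, 2)


def _band_bins(fs: float, nfft: int, band: BandDefinition) -> np.ndarray:
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return np.flatnonzero((freqs >= band.lo) & (freqs <= band.hi))


def psd_features(seg: SessionSegment,
                 bands: tuple[BandDefinition, ...] = BANDS,
                 nfft: int = NFFT) -> FeatureTensor:
    """Mean in-band STFT energy per 1-s window per channel per band."""
    wlen = int(round(seg.fs * WINDOW_S))
    if wlen > nfft:
        raise ValueError(f"window of {wlen} samples exceeds {nfft}-point FFT")
    if seg.n_samples < wlen:
        warnings.warn("segment shorter than one window; empty PSD tensor",
                      RuntimeWarning, stacklevel=2)
        return FeatureTensor("PSD", np.empty((0, len(seg.channel_names), len(bands))),
                             seg.channel_names, tuple(b.name for b in bands))
    win = _windows(seg.samples, seg.fs, WINDOW_S) * np.hanning(wlen)
    spec = np.abs(np.fft.rfft(win, n=nfft, axis=2)) ** 2
    vals = np.stack([spec[:, :, _band_bins(seg.fs, nfft, b)].mean(axis=2)
                     for b in bands], axis=2)
    return FeatureTensor("PSD", vals, seg.channel_names,
                         tuple(b.name for b in bands))


def de_features(band_segs: list[SessionSegment],
                use_baseline: bool = False) -> FeatureTensor:
    """DE per 1-s window per channel for a band-decomposed segment list.

    With ``use_baseline`` the segments' pre-clip baseline arrays are windowed
    instead of the condition signal (for baseline-subtracted topographies).
    """
    if not band_segs:
        raise ValueError("no band segments supplied")
    names = [s.band for s in band_segs]
    if any(n is None for n in names):
        raise ValueError("segments must be band-decomposed (band attribute set)")
    ref = band_segs[0]
    per_band = []
    for s in band_segs:
        if s.channel_names != ref.channel_names or s.fs != ref.fs:
            raise ValueError("band segments disagree on channels or rate")
        data = s.baseline if use_baseline else s.samples
        if data is None:
            raise ValueError("segment has no baseline data")
        win = _windows(data, s.fs, WINDOW_S)
        if win.shape[0] == 0:
            warnings.warn("segment shorter than one window; empty DE tensor",
                          RuntimeWarning, stacklevel=2)
        per_band.append(differential_entropy(win.var(axis=2)))
    return FeatureTensor("DE", np.stack(per_band, axis=2),
                         ref.channel_names, tuple(names))


def _pair_difference(de: FeatureTensor, pairs: list[ElectrodePair],
                     kind: str) -> FeatureTensor:
    if de.kind != "DE":
        raise ValueError(f"{kind} is defined on DE tensors, got {de.kind}")
    ia = [de.unit_index(p.a) for p in pairs]
    ib = [de.unit_index(p.b) for p in pairs]
    vals = de.values[:, ia, :] - de.values[:, ib, :]
    labels = tuple(f"{p.a}-{p.b}" for p in pairs)
    return FeatureTensor(kind, vals, labels, de.band_axis, de.window_s)


def dasm(de: FeatureTensor, pairs: list[ElectrodePair]) -> FeatureTensor:
    """Hemispheric asymmetry: left DE minus right DE for the 28 pairs."""
    return _pair_difference(de, pairs, "DASM")


def dcau(de: FeatureTensor, pairs: list[ElectrodePair]) -> FeatureTensor:
    """Caudality: frontal DE minus posterior DE for the 22 pairs."""
    return _pair_difference(de, pairs, "DCAU")


def assemble_dataset(session_tensors: list[tuple[FeatureTensor, int, str]],
                     band_selection: str = "total",
                     subject: int | None = None,
                     condition: str | None = None,
                     pattern: str | None = None,
                     average_windows: bool = False) -> FeatureDataset:
    """Stack per-session tensors into a classifier matrix.

    ``band_selection`` is one band name or ``"total"`` (concatenation of all
    five band slices).  One row per window by default; ``average_windows``
    collapses each session to its window mean (one row per session).
    """
    if not session_tensors:
        raise ValueError("no feature tensors supplied")
    kinds = {t.kind for t, _, _ in session_tensors}
    if len(kinds) != 1:
        raise ValueError(f"mixed feature kinds {kinds}")
    rows, ys, gs = [], [], []
    for tensor, session_id, emotion in session_tensors:
        if band_selection == "total":
            mat = tensor.values.reshape(tensor.n_windows, -1)
        else:
            mat = tensor.band_slice(band_selection)
        if average_windows and len(mat):
            mat = mat.mean(axis=0, keepdims=True)
        rows.append(mat)
        ys.extend([emotion] * len(mat))
        gs.extend([session_id] * len(mat))
    X = np.vstack(rows)
    return FeatureDataset(X, np.array(ys), np.array(gs), kinds.pop(),
                          band_selection, subject, condition, pattern)
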