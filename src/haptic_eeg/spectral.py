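"""Wavelet time-frequency summaries and baseline-subtracted DE topographies.

The time-frequency map uses a complex Morlet wavelet (7 cycles by default) on
a log-spaced 1-50 Hz frequency grid, with squared-magnitude energy averaged
inside non-overlapping 5-s windows.  Topographic values are window-mean DE
minus window-mean baseline DE per channel and band, interpolated onto the
unit-disc head model with radial basis functions when a gridded map is
needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import RBFInterpolator

from .features import FeatureTensor
from .montage import Montage
from .preprocess import SessionSegment

__all__ = [
    "TimeFrequencyMap",
    "TopoValues",
    "morlet_cwt",
    "tf_wavelet",
    "topo_de",
    "interpolate_scalp",
]

DEFAULT_FREQS = np.geomspace(1.0, 50.0, 40)
N_CYCLES = 7.0
TF_WINDOW_S = 5.0


@dataclass
class TimeFrequencyMap:
    energy: np.ndarray      # frequencies x windows (or channels x f x w)
    freq_axis: np.ndarray   # Hz
    window_s: float
    aggregation: str        # per-channel | channel-mean

    def __post_init__(self) -> None:
        if np.any(self.energy < 0):
            raise ValueError("wavelet energy must be nonnegative")


@dataclass
class TopoValues:
    values: np.ndarray           # channels x bands, baseline-subtracted DE (nats)
    channel_names: tuple[str, ...]
    band_axis: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.channel_names), len(self.band_axis)):
            raise ValueError("topographic value shape inconsistent with axes")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite topographic values")


def _morlet_kernel(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    return kernel / np.linalg.norm(kernel)


def morlet_cwt(x: np.ndarray, fs: float,
               freqs: np.ndarray = DEFAULT_FREQS,
               n_cycles: float = N_CYCLES) -> np.ndarray:
    """Continuous wavelet transform magnitude-squared energy.

    ``x`` is 1-D (time) or 2-D (channels x time); output gains a leading
    frequency axis: freqs x time or channels x freqs x time.
    """
    x = np.asarray(x, float)
    single = x.ndim == 1
    data = np.atleast_2d(x)
    out = np.empty((data.shape[0], len(freqs), data.shape[1]))
    for i, f in enumerate(freqs):
        k = _morlet_kernel(f, fs, n_cycles)
        coef = signal.fftconvolve(data, k[None, :], mode="same", axes=1)
        out[:, i, :] = np.abs(coef) ** 2
    return out[0] if single else out


def tf_wavelet(seg: SessionSegment, window_s: float = TF_WINDOW_S,
               freqs: np.ndarray = DEFAULT_FREQS,
               n_cycles: float = N_CYCLES,
               aggregation: str = "channel-mean") -> TimeFrequencyMap:
    """Morlet energy averaged in non-overlapping ``window_s`` windows."""
    wlen = int(round(window_s * seg.fs))
    n_win = seg.n_samples // wlen
    if n_win < 1:
        raise ValueError(f"segment shorter than one {window_s}-s window")
    energy = morlet_cwt(seg.samples, seg.fs, freqs, n_cycles)
    energy = energy[:, :, :n_win * wlen].reshape(
        energy.shape[0], len(freqs), n_win, wlen).mean(axis=3)
    if aggregation == "channel-mean":
        energy = energy.mean(axis=0)
    elif aggregation != "per-channel":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return TimeFrequencyMap(energy, np.asarray(freqs, float), window_s, aggregation)


def topo_de(de: FeatureTensor, baseline_de: FeatureTensor) -> TopoValues:
    """Window-mean DE minus window-mean baseline DE, per channel per band.

    Both tensors may be stacked across subjects/sessions along the window
    axis; the mean over windows is then the subject-mean map.
    """
    if de.units_axis != baseline_de.units_axis or de.band_axis != baseline_de.band_axis:
        raise ValueError("DE and baseline tensors have mismatched axes")
    if de.n_windows == 0 or baseline_de.n_windows == 0:
        raise ValueError("empty feature tensor")
    diff = de.values.mean(axis=0) - baseline_de.values.mean(axis=0)
    return TopoValues(diff, de.units_axis, de.band_axis)


def interpolate_scalp(tv: TopoValues, m: Montage, band: str,
                      grid_n: int = 64) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radial-basis interpolation of one band's values on the unit disc.

    Returns (xs, ys, grid) where grid is ``grid_n x grid_n`` with NaN outside
    the head circle.  Values at electrode sites are reproduced exactly
    (interpolating thin-plate spline, no smoothing).
    """
    if len(tv.channel_names) < 4:
        raise ValueError("need at least 4 positioned channels to interpolate")
    pos = np.array([m.position(c) for c in tv.channel_names])
    vals = tv.values[:, tv.band_axis.index(band)]
    rbf = RBFInterpolator(pos, vals, kernel="thin_plate_spline")
    xs = np.linspace(-1, 1, grid_n)
    ys = np.linspace(-1, 1, grid_n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    grid = rbf(pts).reshape(grid_n, grid_n)
    grid[gx ** 2 + gy ** 2 > 1.0] = np.nan
    return xs, ys, grid
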