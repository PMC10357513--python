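"""The five canonical EEG frequency bands used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandDefinition", "BANDS", "BAND_NAMES", "band_by_name", "BROADBAND"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float  # Hz
    hi: float  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")


BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 31.0),
    BandDefinition("gamma", 31.0, 50.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)

#: Broadband analysis range (the 1-50 Hz bandpass of the preprocessing chain).
BROADBAND = BandDefinition("broadband", 1.0, 50.0)

_BY_NAME = {b.name: b for b in BANDS}


def band_by_name(name: str) -> BandDefinition:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; expected one of {BAND_NAMES}") from None
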