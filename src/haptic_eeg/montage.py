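"""Standard 64-channel 10-20 montage and asymmetry electrode-pair tables.

The cap dialect used here carries 63 usable data channels recorded against an
FCz online reference with the ground at Fpz.  Two fixed pair tables drive the
asymmetry features: 28 left-right homologous pairs (hemispheric asymmetry) and
22 frontal-posterior pairs (caudality).  2-D electrode coordinates are an
azimuthal-equidistant projection onto the unit disc (nose +y, left -x),
shipped as a plain-text resource.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

__all__ = [
    "Montage",
    "ElectrodePair",
    "MontageError",
    "standard_montage",
    "dasm_pairs",
    "dcau_pairs",
    "TEMPORAL_CHANNELS",
    "PREFRONTAL_CHANNELS",
]

REFERENCE = "FCz"
GROUND = "Fpz"

# Left-right homologous pairs for hemispheric asymmetry (left listed first).
_DASM_PAIRS = [
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("FT7", "FT8"),
    ("FC3", "FC4"), ("T7", "T8"), ("P7", "P8"), ("C3", "C4"),
    ("TP7", "TP8"), ("CP3", "CP4"), ("P3", "P4"), ("O1", "O2"),
    ("AF3", "AF4"), ("F5", "F6"), ("FC5", "FC6"), ("FC1", "FC2"),
    ("C5", "C6"), ("C1", "C2"), ("CP5", "CP6"), ("CP1", "CP2"),
    ("AF7", "AF8"), ("P5", "P6"), ("P1", "P2"), ("PO7", "PO8"),
    ("PO3", "PO4"), ("FT9", "FT10"), ("TP9", "TP10"), ("F1", "F2"),
]

# Frontal-posterior pairs for caudality (frontal listed first).  Note the
# frontal member of the fifth pair is the online reference FCz, which only
# exists after reference recovery during common-average re-referencing.
_DCAU_PAIRS = [
    ("FT7", "TP7"), ("FC5", "CP5"), ("FC3", "CP3"), ("FC1", "CP1"),
    ("FCz", "CPz"), ("FC2", "CP2"), ("FC4", "CP4"), ("FC6", "CP6"),
    ("FT8", "TP8"), ("F7", "P7"), ("F5", "P5"), ("F3", "P3"),
    ("F1", "P1"), ("Fz", "Pz"), ("F2", "P2"), ("F4", "P4"),
    ("F6", "P6"), ("F8", "P8"), ("Fp1", "O1"), ("Fp2", "O2"),
    ("AF3", "CB1"), ("AF4", "CB2"),
]

# Channel groups used by the synthetic generator and topographic checks.
TEMPORAL_CHANNELS = ("FT9", "FT7", "T7", "TP7", "TP9", "C5",
                     "FT10", "FT8", "T8", "TP8", "TP10", "C6")
PREFRONTAL_CHANNELS = ("Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8")


class MontageError(ValueError):
    """Raised when a montage/pair-table configuration is inconsistent."""


@dataclass(frozen=True)
class ElectrodePair:
    a: str
    b: str
    kind: Literal["hemispheric", "frontal-posterior"]

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise MontageError(f"degenerate pair ({self.a}, {self.b})")


@dataclass(frozen=True)
class Montage:
    """Electrode layout: ordered labels, reference/ground, 2-D positions."""

    channel_names: tuple[str, ...]
    reference: str = REFERENCE
    ground: str = GROUND
    positions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise MontageError("duplicate channel labels in montage")

    @property
    def usable_channels(self) -> tuple[str, ...]:
        """Data channels: everything except the reference and the ground."""
        return tuple(c for c in self.channel_names
                     if c not in (self.reference, self.ground))

    def position(self, label: str) -> tuple[float, float]:
        try:
            return self.positions[label]
        except KeyError:
            raise MontageError(f"no position for channel {label!r}") from None

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["label", "x", "y"])
            for name in self.channel_names:
                x, y = self.positions[name]
                w.writerow([name, f"{x:.6f}", f"{y:.6f}"])

    @classmethod
    def from_csv(cls, path, reference: str = REFERENCE,
                 ground: str = GROUND) -> "Montage":
        names: list[str] = []
        pos: dict[str, tuple[float, float]] = {}
        with open(path, newline="") as f:
            for row in csv.DictReader(f):
                names.append(row["label"])
                pos[row["label"]] = (float(row["x"]), float(row["y"]))
        return cls(tuple(names), reference, ground, pos)


def standard_montage() -> Montage:
    """The canonical 64-channel cap: 63 usable channels + FCz ref, Fpz ground."""
    ref = resources.files("haptic_eeg.resources") / "montage_standard64.csv"
    with resources.as_file(ref) as path:
        m = Montage.from_csv(path)
    if len(m.usable_channels) != 63:  # defensive: resource is hand-curated
        raise MontageError(
            f"standard montage has {len(m.usable_channels)} usable channels, expected 63")
    return m


def _resolve_pairs(m: Montage, raw: list[tuple[str, str]],
                   kind: Literal["hemispheric", "frontal-posterior"],
                   available: set[str] | None = None,
                   warn=None) -> list[ElectrodePair]:
    known = set(m.channel_names)
    out = []
    for a, b in raw:
        if a not in known or b not in known:
            raise MontageError(f"pair ({a}, {b}) references unknown channel")
        if available is not None and (a not in available or b not in available):
            if warn is not None:
                warn(f"dropping pair ({a}, {b}): channel missing from recording")
            continue
        out.append(ElectrodePair(a, b, kind))
    return out


def dasm_pairs(m: Montage | None = None, available=None, warn=None) -> list[ElectrodePair]:
    """The 28 hemispheric (left minus right) pairs, in canonical order.

    ``available`` optionally restricts to channels present in a recording;
    missing-channel pairs are dropped with a warning callback.
    """
    m = m if m is not None else standard_montage()
    return _resolve_pairs(m, _DASM_PAIRS, "hemispheric",
                          set(available) if available is not None else None, warn)


def dcau_pairs(m: Montage | None = None, available=None, warn=None) -> list[ElectrodePair]:
    """The 22 frontal-posterior (frontal minus posterior) pairs, in order."""
    m = m if m is not None else standard_montage()
    return _resolve_pairs(m, _DCAU_PAIRS, "frontal-posterior",
                          set(available) if available is not None else None, warn)
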