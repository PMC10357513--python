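"""Reading and writing EEG recordings (BrainVision, EDF) and run manifests.

Neither a BrainVision nor an EDF library is assumed; both formats are simple
enough to implement directly for the subset this pipeline needs:

* BrainVision: INI-style ``.vhdr`` header, ``.vmrk`` marker file, and a
  multiplexed IEEE float32 ``.eeg`` data file.  Event markers round-trip
  natively through the marker file at sample resolution.
* EDF: fixed-width ASCII header with 16-bit digitized samples.  Plain EDF has
  no annotation channel, so event markers round-trip through a companion
  ``<stem>.events.csv`` sidecar instead of EDF+ TAL framing.

All µV sample data are written at runtime; nothing binary ships with the
package.
"""

from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EventMarker, RawRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_brainvision",
    "read_brainvision",
    "write_edf",
    "read_edf",
    "write_manifest",
    "read_manifest",
]

_EDF_DIG_MAX = 32767


# ---------------------------------------------------------------- BrainVision

def write_brainvision(rec: RawRecording, path) -> Path:
    """Write a vhdr/vmrk/eeg triplet; returns the ``.vhdr`` path."""
    stem = Path(path)
    if stem.suffix == ".vhdr":
        stem = stem.with_suffix("")
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    rec.samples.T.astype("<f4").tofile(eeg)

    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.fs:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names, 1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    for i, ann in enumerate(rec.annotations, 2):
        pos = int(round(ann.onset_s * rec.fs)) + 1  # 1-based data points
        dur = int(round(ann.duration_s * rec.fs))
        mlines.append(f"Mk{i}=Stimulus,{ann.description},{pos},{dur},0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    cur: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            cur = sections.setdefault(line[1:-1], {})
        elif "=" in line:
            k, v = line.split("=", 1)
            cur[k.strip()] = v.strip()
    return sections


def read_brainvision(path) -> RawRecording:
    vhdr = Path(path)
    ini = _parse_ini(vhdr.read_text(encoding="utf-8"))
    common = ini["Common Infos"]
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED BrainVision data supported")
    fmt = ini.get("Binary Infos", {}).get("BinaryFormat", "IEEE_FLOAT_32")
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}.get(fmt)
    if dtype is None:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    chans, scales = [], []
    for i in range(1, n_ch + 1):
        fields = ini["Channel Infos"][f"Ch{i}"].split(",")
        chans.append(fields[0])
        scales.append(float(fields[2]) if len(fields) > 2 and fields[2] else 1.0)
    raw = np.fromfile(vhdr.parent / common["DataFile"], dtype=dtype)
    data = raw.reshape(-1, n_ch).T.astype(float) * np.asarray(scales)[:, None]

    anns = []
    mpath = vhdr.parent / common.get("MarkerFile", "")
    if common.get("MarkerFile") and mpath.exists():
        mk = _parse_ini(mpath.read_text(encoding="utf-8")).get("Marker Infos", {})
        for key in sorted(mk, key=lambda k: int(k[2:])):
            f = mk[key].split(",")
            mtype, desc, pos, dur = f[0], f[1], int(f[2]), int(f[3])
            if mtype == "New Segment":
                continue
            anns.append(EventMarker((pos - 1) / fs, dur / fs, desc))
    return RawRecording(data, fs, tuple(chans), tuple(anns))


# ------------------------------------------------------------------------ EDF

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_num(v: float) -> str:
    """Format a physical-range value into EDF's 8-character numeric field."""
    for p in range(7, 0, -1):
        s = f"{v:.{p}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"


def write_edf(rec: RawRecording, path) -> Path:
    """Write a plain EDF file (16-bit), events in a ``.events.csv`` sidecar.

    One data record per sample keeps any signal length representable without
    padding; the record duration field then equals the sampling interval.
    """
    path = Path(path).with_suffix(".edf")
    ns = rec.n_channels
    n_records = rec.n_samples
    rec_dur = 1.0 / rec.fs
    rd = f"{rec_dur:.7f}".rstrip("0")
    if len(rd) > 8:
        raise ValueError(f"sampling interval {rec_dur} not representable in EDF")

    amp = np.abs(rec.samples).max(axis=1)
    # digitize against the header-representable (rounded) physical range so
    # the read-back scaling matches exactly
    phys_max = np.array([float(_edf_num(m)) * (1 + 1e-6)
                         for m in np.where(amp > 0, amp, 1.0)])
    phys_max = np.array([float(_edf_num(m)) for m in phys_max])
    digital = np.round(rec.samples / phys_max[:, None] * _EDF_DIG_MAX)
    digital = np.clip(digital, -_EDF_DIG_MAX - 1, _EDF_DIG_MAX).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(rd, 8),
        _edf_field(ns, 4),
    ])
    per_sig = b"".join([
        b"".join(_edf_field(c, 16) for c in rec.channel_names),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(_edf_num(-m), 8) for m in phys_max),
        b"".join(_edf_field(_edf_num(m), 8) for m in phys_max),
        b"".join(_edf_field(-_EDF_DIG_MAX - 1, 8) for _ in range(ns)),
        b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(1, 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as f:
        f.write(header + per_sig)
        digital.T.tofile(f)  # record-major = sample-major at 1 sample/record

    if rec.annotations:
        with open(path.with_suffix(".events.csv"), "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["onset_s", "duration_s", "description"])
            for a in rec.annotations:
                w.writerow([repr(a.onset_s), repr(a.duration_s), a.description])
    return path


def read_edf(path) -> RawRecording:
    path = Path(path)
    with open(path, "rb") as f:
        head = f.read(256)
        n_records = int(head[236:244])
        rec_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = f.read(256 * ns)

        def fields(offset, width):
            base = offset * ns
            return [sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                    for i in range(ns)]

        labels = fields(0, 16)
        phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        if any(s != spr[0] for s in spr):
            raise ValueError("heterogeneous samples-per-record not supported")
        data = np.fromfile(f, dtype="<i2")

    per_rec = spr[0]
    data = data.reshape(n_records, ns, per_rec)
    data = np.moveaxis(data, 1, 0).reshape(ns, -1).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    fs = per_rec / rec_dur

    anns = []
    sidecar = path.with_suffix(".events.csv")
    if sidecar.exists():
        with open(sidecar, newline="") as f:
            for row in csv.DictReader(f):
                anns.append(EventMarker(float(row["onset_s"]),
                                        float(row["duration_s"]),
                                        row["description"]))
    return RawRecording(data, fs, tuple(labels), tuple(anns))


# ------------------------------------------------------------------- dispatch

def write_recording(rec: RawRecording, path, format: str = "brainvision") -> Path:
    fmt = format.lower()
    if fmt == "brainvision":
        return write_brainvision(rec, path)
    if fmt == "edf":
        return write_edf(rec, path)
    raise ValueError(f"unsupported recording format {format!r}")


def read_recording(path) -> RawRecording:
    path = Path(path)
    if path.suffix == ".vhdr":
        return read_brainvision(path)
    if path.suffix == ".edf":
        return read_edf(path)
    raise ValueError(f"cannot infer format from {path.name!r}")


# ------------------------------------------------------------------- manifest

def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
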