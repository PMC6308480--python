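"""Reading and writing ECG records and fiducial annotations.

Two on-disk dialects are supported:

* **CSV** — one row per sample, one column per channel, with ``#``-prefixed
  header comments carrying the sampling frequency, channel names and units.
  Diffable, and the native format of the synthetic generator.
* **WFDB** — the PhysioNet signal format (``.hea`` header + format-16
  ``.dat``) and the MIT binary annotation format, as used by QT-DB and
  MIT-BIH. Support is intentionally minimal (single segment, format 16).

All sample indices are 0-based throughout the package; WFDB annotation
sample numbers are adopted unchanged (WFDB is itself 0-based).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _wfdb

__all__ = [
    "EcgRecord",
    "AnnotationSet",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
]

#: Canonical fiducial labels used throughout the package.
QON = "Qon"
RPEAK = "Rpeak"
SOFF = "Soff"


@dataclass
class EcgRecord:
    """A sampled multi-channel ECG.

    Parameters
    ----------
    data:
        Array of shape ``(n_samples, n_channels)`` in the units declared per
        channel (mV once gain metadata has been applied).
    fs:
        Sampling frequency in Hz.
    channel_names:
        One label per channel (e.g. ``"MLII"``, ``"V5"``).
    units:
        One unit string per channel.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        if self.data.shape[0] == 1 and self.data.shape[1] > 1 and not self.channel_names:
            # a bare 1-D vector came in as a row; treat it as one channel
            self.data = self.data.T
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.n_samples < 1:
            raise ValueError("record must contain at least one sample")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if not self.units:
            self.units = ["mV"] * self.n_channels
        if len(self.channel_names) != self.n_channels or len(self.units) != self.n_channels:
            raise ValueError("channel_names/units length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, which: int | str = 0) -> np.ndarray:
        """Return one channel as a 1-D array."""
        if isinstance(which, str):
            which = self.channel_names.index(which)
        return self.data[:, which]


@dataclass
class AnnotationSet:
    """An ordered list of ``(sample_index, label)`` fiducial annotations.

    Labels are free strings; the canonical ones are ``"Qon"``, ``"Rpeak"``
    and ``"Soff"``. Entries are kept sorted by sample index, and indices
    must be strictly increasing within each label stream.
    """

    entries: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [(int(s), str(lab)) for s, lab in self.entries]
        for s, _ in self.entries:
            if s < 0:
                raise ValueError(f"negative sample index {s}")
        self.entries.sort(key=lambda e: e[0])
        seen: dict[str, int] = {}
        for s, lab in self.entries:
            if lab in seen and s <= seen[lab]:
                raise ValueError(f"duplicate sample index {s} for label {lab!r}")
            seen[lab] = s

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def samples(self, label: str) -> np.ndarray:
        """Sample indices carrying ``label``, in increasing order."""
        return np.array([s for s, lab in self.entries if lab == label], dtype=int)

    def labels(self) -> list[str]:
        out: list[str] = []
        for _, lab in self.entries:
            if lab not in out:
                out.append(lab)
        return out


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".hea", ".dat", ""):
        return "wfdb"
    return "csv"


def read_record(path: str, format: str | None = None) -> EcgRecord:
    """Read an ECG record from ``path``.

    ``format`` is ``"csv"`` or ``"wfdb"``; when omitted it is inferred from
    the extension (``.hea``/``.dat``/bare → WFDB, anything else CSV). For
    WFDB, ``path`` may be the record name with or without the ``.hea``
    extension; amplitudes are converted to physical units using the header
    gain and baseline.
    """
    fmt = _infer_format(path, format)
    if fmt == "wfdb":
        data, fs, names, units = _wfdb.read_signal(path)
        return EcgRecord(data, fs, names, units)
    if fmt != "csv":
        raise ValueError(f"unknown record format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fs = None
    names: list[str] = []
    units: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip().lower()
                    if key == "fs":
                        fs = float(val)
                    elif key == "channels":
                        names = [v.strip() for v in val.split(",")]
                    elif key == "units":
                        units = [v.strip() for v in val.split(",")]
                continue
            rows.append([float(v) for v in line.split(",")])
    if fs is None:
        raise ValueError(f"{path}: CSV record lacks a '# fs=...' header comment")
    if not rows:
        raise ValueError(f"{path}: no samples")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: inconsistent channel counts per row: {sorted(widths)}")
    return EcgRecord(np.array(rows, dtype=float), fs, names, units)


def write_record(record: EcgRecord, path: str, format: str | None = None) -> None:
    """Write ``record`` to ``path`` in CSV or WFDB (format 16) dialect."""
    fmt = _infer_format(path, format)
    if fmt == "wfdb":
        _wfdb.write_signal(path, record.data, record.fs, record.channel_names, record.units)
        return
    if fmt != "csv":
        raise ValueError(f"unknown record format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        fh.write(f"# channels={','.join(record.channel_names)}\n")
        fh.write(f"# units={','.join(record.units)}\n")
        for row in record.data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str, format: str | None = None) -> AnnotationSet:
    """Read fiducial annotations from a CSV (``sample,label`` rows) or a
    binary MIT-format WFDB annotation file.

    WFDB waveform-onset marks ``(`` map to ``Qon``, waveform-offset marks
    ``)`` to ``Soff`` and beat labels to ``Rpeak``; any other code is kept
    as its WFDB mnemonic.
    """
    fmt = format
    if fmt is None:
        fmt = "csv" if path.lower().endswith(".csv") else "wfdb"
    if fmt == "wfdb":
        return AnnotationSet(_wfdb.read_annotations(path))
    if fmt != "csv":
        raise ValueError(f"unknown annotation format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    entries: list[tuple[int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            s, _, lab = line.partition(",")
            idx = int(s)
            if idx < 0:
                raise ValueError(f"{path}: negative sample index {idx}")
            entries.append((idx, lab.strip()))
    return AnnotationSet(entries)


def write_annotations(ann: AnnotationSet, path: str, format: str | None = None) -> None:
    """Write annotations as CSV rows or as a binary MIT-format file."""
    fmt = format
    if fmt is None:
        fmt = "csv" if path.lower().endswith(".csv") else "wfdb"
    if fmt == "wfdb":
        _wfdb.write_annotations(path, list(ann.entries))
        return
    if fmt != "csv":
        raise ValueError(f"unknown annotation format {fmt!r}")
    with open(path, "w") as fh:
        for s, lab in ann.entries:
            fh.write(f"{s},{lab}\n")
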