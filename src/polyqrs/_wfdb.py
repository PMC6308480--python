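"""Minimal WFDB (PhysioNet) format support.

Implements just enough of the WFDB conventions for this package: single-
segment records with all channels interleaved in one format-16 ``.dat``
file, and MIT binary annotation files. Sample numbers are 0-based, as in
WFDB itself.

Layout notes (from the published format definition):

* header: ``name nsig fs [nsamples]`` then one line per signal
  ``file fmt gain(baseline)/units adcres adczero initval chksum blksz desc``.
* format 16: little-endian int16, channel-interleaved;
  physical = (digital - baseline) / gain.
* annotations: a stream of little-endian 16-bit words; code = word >> 10,
  time increment = word & 0x3FF. Code 59 (SKIP) is followed by a 32-bit
  interval stored high word first; code 63 (AUX) is followed by `increment`
  bytes of text, padded to even length; codes 60-62 carry NUM/SUB/CHN
  fields; a zero word terminates the stream.
"""

from __future__ import annotations

import os
import struct

import numpy as np

# WFDB annotation code <-> mnemonic (ecgcodes table)
_CODE_TO_MNEMONIC = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_MNEMONIC_TO_CODE = {v: k for k, v in _CODE_TO_MNEMONIC.items()}

# package-level fiducial labels mapped onto WFDB codes
_LABEL_TO_CODE = {"Qon": 39, "Soff": 40, "Rpeak": 1}
_CODE_TO_LABEL = {39: "Qon", 40: "Soff", 1: "Rpeak"}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _base(path: str) -> str:
    for ext in (".hea", ".dat", ".atr"):
        if path.endswith(ext):
            return path[: -len(ext)]
    return path


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def read_signal(path: str):
    """Read a format-16 record; returns (data, fs, names, units) with data
    in physical units, shape (n_samples, n_channels)."""
    base = _base(path)
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    lines = []
    with open(hea) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                lines.append(line)
    if not lines:
        raise ValueError(f"{hea}: empty header")
    head = lines[0].split()
    if len(head) < 3:
        raise ValueError(f"{hea}: malformed record line {lines[0]!r}")
    nsig = int(head[1])
    fs = float(head[2].split("/")[0])
    nsamp = int(head[3]) if len(head) > 3 else None
    if len(lines) - 1 < nsig:
        raise ValueError(f"{hea}: expected {nsig} signal lines")
    gains, baselines, units, names, dat_files, fmts = [], [], [], [], [], []
    for line in lines[1 : 1 + nsig]:
        tok = line.split()
        dat_files.append(tok[0])
        fmts.append(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain_tok = tok[2] if len(tok) > 2 else "200"
        unit = "mV"
        if "/" in gain_tok:
            gain_tok, unit = gain_tok.split("/", 1)
        baseline = None
        if "(" in gain_tok:
            gain_tok, rest = gain_tok.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gain = float(gain_tok) if gain_tok else 200.0
        if gain == 0:
            gain = 200.0
        adczero = int(tok[4]) if len(tok) > 4 else 0
        gains.append(gain)
        baselines.append(adczero if baseline is None else baseline)
        units.append(unit)
        names.append(tok[8] if len(tok) > 8 else f"ch{len(names)}")
    if len(set(dat_files)) != 1:
        raise ValueError("only single-.dat records are supported")
    if any(f != "16" for f in fmts):
        raise ValueError(f"unsupported WFDB signal format(s) {sorted(set(fmts))}; only 16")
    dat = os.path.join(os.path.dirname(hea), dat_files[0])
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size % nsig:
        raise ValueError(f"{dat}: sample count not a multiple of {nsig} channels")
    dig = raw.reshape(-1, nsig)
    if nsamp is not None:
        dig = dig[:nsamp]
    data = (dig.astype(float) - np.array(baselines)) / np.array(gains)
    return data, fs, names, units


def write_signal(path: str, data: np.ndarray, fs: float, names, units,
                 gain: float = 1000.0) -> None:
    """Write a format-16 record (``.hea`` + ``.dat``) with the given ADC gain."""
    base = _base(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 1 and data.shape[1] > 1:
        data = data.T
    nsamp, nsig = data.shape
    dig = np.clip(np.rint(data * gain), -32768, 32767).astype("<i2")
    name = os.path.basename(base)
    with open(base + ".hea", "w") as fh:
        fh.write(f"{name} {nsig} {fs:g} {nsamp}\n")
        for ch in range(nsig):
            chk = int(np.asarray(dig[:, ch], dtype=np.int64).sum() % 65536)
            if chk >= 32768:
                chk -= 65536
            first = int(dig[0, ch])
            fh.write(
                f"{name}.dat 16 {gain:g}(0)/{units[ch]} 16 0 {first} {chk} 0 {names[ch]}\n"
            )
    dig.reshape(-1).tofile(base + ".dat")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file into (sample, label) pairs."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    buf = open(path, "rb").read()
    entries: list[tuple[int, str]] = []
    t = 0
    pending_skip = 0
    i = 0
    pending_aux: str | None = None
    while i + 1 < len(buf):
        word = buf[i] | (buf[i + 1] << 8)
        i += 2
        code = word >> 10
        inc = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(buf):
                raise ValueError(f"{path}: truncated SKIP")
            hi = buf[i] | (buf[i + 1] << 8)
            lo = buf[i + 2] | (buf[i + 3] << 8)
            i += 4
            interval = (hi << 16) | lo
            if interval >= 1 << 31:
                interval -= 1 << 32
            pending_skip += interval
        elif code == _AUX:
            aux = buf[i : i + inc]
            i += inc + (inc & 1)
            pending_aux = aux.rstrip(b"\x00").decode("latin-1")
            # an AUX string after a '?' mark carries a free-text label
            if pending_aux and entries and entries[-1][1] == "?":
                entries[-1] = (entries[-1][0], pending_aux)
            pending_aux = None
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            t += pending_skip + inc
            pending_skip = 0
            label = _CODE_TO_LABEL.get(code) or _CODE_TO_MNEMONIC.get(code, f"code{code}")
            entries.append((t, label))
    return entries


def write_annotations(path: str, entries: list[tuple[int, str]]) -> None:
    """Write (sample, label) pairs as an MIT-format annotation file.

    Labels outside the WFDB mnemonic table are written as code ``?`` with
    the label text attached as an AUX string, so arbitrary labels survive a
    round trip.
    """
    entries = sorted(((int(s), str(lab)) for s, lab in entries), key=lambda e: e[0])
    out = bytearray()
    prev = 0
    for s, lab in entries:
        if s < 0:
            raise ValueError(f"negative sample index {s}")
        code = _LABEL_TO_CODE.get(lab) or _MNEMONIC_TO_CODE.get(lab)
        aux = None
        if code is None:
            code, aux = 30, lab.encode("latin-1")  # '?' + AUX text
        delta = s - prev
        prev = s
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        if aux is not None:
            out += struct.pack("<H", (_AUX << 10) | len(aux))
            out += aux
            if len(aux) & 1:
                out += b"\x00"
    out += b"\x00\x00"
    with open(path, "wb") as fh:
        fh.write(bytes(out))
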