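"""Minimal WFDB (PhysioNet) record support, implemented natively.

Reads the text header (``.hea``), the binary signal file in the two common
formats (16: little-endian int16, interleaved; 212: packed 12-bit pairs),
and the MIT annotation file (``.atr``) for R-peak marks.  Gain and baseline
from the header convert ADC units to millivolts.  A format-16 writer is
provided so round-trip fixtures can be created at test time.

This is intentionally a small subset of the WFDB specification: single- or
multi-channel signal files with one samples-per-frame, no multi-segment
records.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .errors import FormatError, IoError
from .record import EcgRecord, FiducialMarks

__all__ = ["read_wfdb_record", "write_wfdb_record",
           "read_wfdb_annotations", "write_wfdb_annotations"]

#: MIT annotation type codes that mark a beat (QRS) of some kind.
_BEAT_CODES = set(range(1, 50))
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


def _parse_header(hea_path: Path) -> Tuple[str, int, float, int, List[_SignalSpec]]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"{hea_path}: malformed record line")
    name = head[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    specs: List[_SignalSpec] = []
    for ln in lines[1: 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"{hea_path}: malformed signal line {ln!r}")
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, 0, "mV"
        if len(tok) > 2:
            gfield = tok[2]
            if "/" in gfield:
                gfield, units = gfield.split("/", 1)
            if "(" in gfield:
                gpart, bpart = gfield.split("(", 1)
                gain = float(gpart) if gpart else 200.0
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gfield) if gfield else 200.0
        desc = " ".join(tok[8:]) if len(tok) > 8 else ""
        specs.append(_SignalSpec(fname, fmt, gain if gain != 0 else 200.0,
                                 baseline, units, desc))
    return name, n_samp, fs, n_sig, specs


def _read_signal(path: Path, fmt: int, n_sig: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        usable = (data.size // n_sig) * n_sig
        return data[:usable].reshape(-1, n_sig)
    if fmt == 212:
        if n_sig not in (1, 2):
            raise FormatError("format 212 supported for 1 or 2 signals only")
        b = np.frombuffer(raw, dtype=np.uint8)
        usable = (b.size // 3) * 3
        b = b[:usable].reshape(-1, 3).astype(np.int32)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        inter = np.empty(first.size * 2, dtype=np.int32)
        inter[0::2] = first
        inter[1::2] = second
        usable = (inter.size // n_sig) * n_sig
        return inter[:usable].reshape(-1, n_sig)
    raise FormatError(f"unsupported WFDB signal format {fmt}")


def read_wfdb_record(path, channel: Optional[int] = None) -> EcgRecord:
    """Read a WFDB record (path with or without ``.hea``) into millivolts.

    The first channel is used unless ``channel`` selects another.  If a
    ``.atr`` annotation file is present its beat marks populate
    ``annotations.r_peak`` (other marks are flagged missing).
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise IoError(f"no WFDB header: {hea}")
    name, n_samp, fs, n_sig, specs = _parse_header(hea)
    sig_file = hea.parent / specs[0].file_name
    if not sig_file.exists():
        raise IoError(f"no WFDB signal file: {sig_file}")
    adc = _read_signal(sig_file, specs[0].fmt, n_sig)
    if n_samp and adc.shape[0] < n_samp:
        raise IoError(
            f"{sig_file}: truncated signal ({adc.shape[0]} < {n_samp} samples)")
    if n_samp:
        adc = adc[:n_samp]
    ch = channel if channel is not None else 0
    if not (0 <= ch < n_sig):
        raise FormatError(f"channel {ch} out of range for {n_sig} signals")
    spec = specs[ch]
    mv = (adc[:, ch].astype(np.float64) - spec.baseline) / spec.gain

    ann = None
    atr = hea.with_suffix(".atr")
    if atr.exists():
        r = read_wfdb_annotations(atr)
        r = r[r < mv.size]
        if r.size:
            miss = np.full(r.size, -1, dtype=np.int64)
            ann = FiducialMarks(p_onset=miss.copy(), p_peak=miss.copy(),
                                qrs_onset=miss.copy(), r_peak=r,
                                qrs_offset=miss.copy(), t_peak=miss.copy(),
                                t_offset=miss.copy())
    return EcgRecord(samples=mv, sampling_rate=fs, annotations=ann,
                     meta={"record": name, "units": spec.units,
                           "description": spec.description})


def write_wfdb_record(record: EcgRecord, path, gain: float = 200.0) -> None:
    """Write a single-channel format-16 WFDB record (header + signal)."""
    path = Path(path)
    base = path.with_suffix("")
    adc = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    (base.parent / (base.name + ".dat")).write_bytes(adc.tobytes())
    header = (f"{base.name} 1 {record.sampling_rate:g} {adc.size}\n"
              f"{base.name}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0]) if adc.size else 0} 0 0 ECG\n")
    (base.parent / (base.name + ".hea")).write_text(header)
    if record.annotations is not None and record.annotations.n_beats:
        write_wfdb_annotations(record.annotations.r_peak,
                               base.parent / (base.name + ".atr"))


def read_wfdb_annotations(path) -> np.ndarray:
    """Beat (QRS) annotation sample indices from a MIT-format file."""
    raw = Path(path).read_bytes()
    t = 0
    peaks: List[int] = []
    i = 0
    n = len(raw)
    while i + 1 < n:
        lo, hi = raw[i], raw[i + 1]
        i += 2
        code = hi >> 2
        interval = ((hi & 0x03) << 8) | lo
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 4 > n:
                raise FormatError(f"{path}: truncated SKIP annotation")
            interval = struct.unpack("<i", bytes([raw[i + 2], raw[i + 3],
                                                  raw[i], raw[i + 1]]))[0]
            i += 4
            t += interval
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            aux_len = interval
            i += aux_len + (aux_len & 1)
            continue
        t += interval
        if code in _BEAT_CODES:
            peaks.append(t)
    return np.asarray(peaks, dtype=np.int64)


def write_wfdb_annotations(r_peaks: np.ndarray, path) -> None:
    """Write beat annotations (code NORMAL) in MIT format."""
    out = bytearray()
    prev = 0
    for p in np.asarray(r_peaks, dtype=np.int64):
        interval = int(p - prev)
        prev = int(p)
        while interval > 1023:
            # SKIP pseudo-annotation carries a 32-bit interval
            out += bytes([0, _SKIP << 2])
            chunk = interval - 1023
            b = struct.pack("<i", chunk)
            out += bytes([b[2], b[3], b[0], b[1]])
            interval = 1023
        code = 1  # NORMAL beat
        out += bytes([interval & 0xFF, (code << 2) | ((interval >> 8) & 0x03)])
    out += bytes([0, 0])
    Path(path).write_bytes(bytes(out))
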