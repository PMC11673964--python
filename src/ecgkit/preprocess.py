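"""Two-stage digital filtering: low-pass, band-pass, baseline removal, notch.

All filters are 4th-order Butterworth designs (2nd order for the DC-blocking
high-pass) applied forward-backward (``sosfiltfilt``) for zero-phase
response, so fiducial timing is preserved.  Cutoffs follow the acquisition
chain they model: a 100 Hz anti-alias low-pass, a 0.5-100 Hz band-pass over
the diagnostic ECG band, a sub-1 Hz high-pass for baseline wander, and an
optional 50/60 Hz notch for mains interference (the band-pass alone cannot
remove in-band powerline coupling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError, NyquistError
from .record import EcgRecord

__all__ = [
    "FilterSpec",
    "lowpass_100",
    "bandpass_05_100",
    "remove_baseline",
    "notch_powerline",
]

DEFAULT_ORDER = 4


@dataclass(frozen=True)
class FilterSpec:
    """A declarative filter description used by the CLI and pipeline config."""

    kind: str  # lowpass | bandpass | highpass | notch
    cutoffs: Tuple[float, ...]
    order: int = DEFAULT_ORDER
    design: str = "butterworth"

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass", "highpass", "notch"):
            raise InvalidConfigError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise InvalidConfigError("filter order must be positive")
        if any(c <= 0 for c in self.cutoffs):
            raise InvalidConfigError("cutoffs must be positive")
        if self.kind == "bandpass" and (len(self.cutoffs) != 2 or self.cutoffs[0] >= self.cutoffs[1]):
            raise InvalidConfigError("bandpass needs cutoffs (low, high) with low < high")


def _check_nyquist(fs: float, *cutoffs: float) -> None:
    for c in cutoffs:
        if c >= fs / 2.0:
            raise NyquistError(f"cutoff {c} Hz not below Nyquist ({fs / 2.0} Hz)")


def _apply_sos(record: EcgRecord, sos: np.ndarray) -> EcgRecord:
    y = sps.sosfiltfilt(sos, record.samples)
    return record.with_samples(y)


def lowpass_100(record: EcgRecord, cutoff: float = 100.0,
                order: int = DEFAULT_ORDER) -> EcgRecord:
    """Zero-phase Butterworth low-pass, default 100 Hz cutoff.

    Requires ``sampling_rate > 200`` so the cutoff sits below Nyquist.
    """
    fs = record.sampling_rate
    if fs <= 2 * cutoff:
        raise NyquistError(f"sampling rate {fs} Hz too low for a {cutoff} Hz low-pass")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return _apply_sos(record, sos)


def bandpass_05_100(record: EcgRecord, low: float = 0.5, high: float = 100.0,
                    order: int = DEFAULT_ORDER) -> EcgRecord:
    """Zero-phase Butterworth band-pass over the diagnostic band, default 0.5-100 Hz."""
    fs = record.sampling_rate
    if low >= high:
        raise InvalidConfigError("bandpass requires low < high")
    if fs <= 2 * high:
        raise NyquistError(f"sampling rate {fs} Hz too low for a {high} Hz band edge")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return _apply_sos(record, sos)


def remove_baseline(record: EcgRecord, cutoff: float = 0.1,
                    order: int = 2) -> EcgRecord:
    """Remove baseline wander with a zero-phase high-pass below 1 Hz.

    The default 0.1 Hz cutoff preserves ST-segment morphology while rejecting
    respiration-band drift and DC offset.
    """
    fs = record.sampling_rate
    if cutoff >= fs / 2.0:
        raise NyquistError(f"cutoff {cutoff} Hz not below Nyquist")
    if not (0.0 < cutoff < 1.0):
        raise InvalidConfigError("baseline-removal cutoff must lie in (0, 1) Hz")
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return _apply_sos(record, sos)


def notch_powerline(record: EcgRecord, mains: float = 50.0,
                    q: float = 35.0) -> EcgRecord:
    """Zero-phase IIR notch at the mains frequency (50 or 60 Hz).

    Quality factor 35 gives > 20 dB rejection at the mains frequency and
    < 1 dB ripple 5 Hz away.
    """
    if mains not in (50.0, 60.0, 50, 60):
        raise InvalidConfigError("mains frequency must be 50 or 60 Hz")
    fs = record.sampling_rate
    if mains >= fs / 2.0:
        raise NyquistError(f"mains {mains} Hz not below Nyquist")
    b, a = sps.iirnotch(mains, q, fs=fs)
    y = sps.filtfilt(b, a, record.samples)
    return record.with_samples(y)
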