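"""Core containers: a sampled single-lead ECG and its per-beat fiducial marks.

Amplitudes are millivolts, sample indices are 0-based, and intervals are
seconds everywhere inside the package; unit conversion happens only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidConfigError

#: Sentinel sample index for a fiducial mark that could not be located.
MISSING = -1

#: Canonical per-beat mark names, in the order they occur inside one beat.
MARK_NAMES = (
    "p_onset",
    "p_peak",
    "qrs_onset",
    "r_peak",
    "qrs_offset",
    "t_peak",
    "t_offset",
)


@dataclass
class FiducialMarks:
    """Per-beat fiducial sample indices (0-based); ``MISSING`` flags a failed search.

    Each attribute is an int array of length ``n_beats``.  Within a beat the
    present marks must be strictly increasing in the order of ``MARK_NAMES``,
    and the R-peak sequence must be strictly increasing across beats.
    """

    p_onset: np.ndarray
    p_peak: np.ndarray
    qrs_onset: np.ndarray
    r_peak: np.ndarray
    qrs_offset: np.ndarray
    t_peak: np.ndarray
    t_offset: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, name), dtype=np.int64) for name in MARK_NAMES]
        n = arrays[0].shape[0]
        for name, arr in zip(MARK_NAMES, arrays):
            if arr.ndim != 1 or arr.shape[0] != n:
                raise InvalidConfigError("all fiducial mark arrays must be 1-D and equal length")
            setattr(self, name, arr)
        r = self.r_peak
        if n and (np.any(r < 0) or np.any(np.diff(r) <= 0)):
            raise InvalidConfigError("r_peak indices must be non-negative and strictly increasing")
        stacked = np.stack(arrays, axis=1)  # (n_beats, n_marks)
        for beat in stacked:
            present = beat[beat != MISSING]
            if np.any(np.diff(present) <= 0):
                raise InvalidConfigError("fiducial marks within a beat must be strictly ordered")

    @property
    def n_beats(self) -> int:
        return int(self.r_peak.shape[0])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_beats


@dataclass
class EcgRecord:
    """A uniformly sampled single-lead ECG trace in millivolts.

    Parameters
    ----------
    samples : array-like of float
        Amplitude sequence, mV.
    sampling_rate : float
        Samples per second.
    annotations : FiducialMarks, optional
        Ground-truth or detected fiducial marks.
    label : str, optional
        Rhythm-class label (``normal`` / ``tachycardia`` / ``bradycardia`` or
        any user-defined class).
    """

    samples: np.ndarray
    sampling_rate: float
    annotations: Optional[FiducialMarks] = None
    label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidConfigError("samples must be a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidConfigError("samples must be finite")
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.annotations is not None and self.annotations.n_beats:
            last = max(
                int(np.max(getattr(self.annotations, name)))
                for name in MARK_NAMES
            )
            if last >= self.samples.size:
                raise InvalidConfigError("annotation indices exceed record length")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of this record with new samples, keeping rate/annotations/label."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_samples
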