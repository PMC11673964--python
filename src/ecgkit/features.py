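"""R-peak detection, wave delineation, and RR/beat feature extraction.

The R-peak detector is a Pan-Tompkins-style pipeline: 5-15 Hz band-pass,
differentiation, squaring, 150 ms moving-window integration, then an
adaptive signal/noise threshold with a 200 ms refractory period.  Detected
envelope peaks are refined to the local extremum of the input trace.

Feature groups mirror the standard HRV taxonomy:

* time domain      - mean/median RR, RMSSD, average/maximum deviation,
                     >50 ms successive-pair count, 32-bin RR histogram;
* frequency domain - Welch band powers (ULF < 0.003, VLF 0.003-0.04,
                     LF 0.04-0.15, HF 0.15-0.4 Hz) on the 4 Hz-resampled
                     RR series, plus the LF/HF ratio;
* statistical      - mean, median, SD, excess kurtosis, range, skewness;
* per-beat vector  - mean and SD of heart rate, QRS amplitude, QRS duration
                     and PR interval (the eight rhythm-class statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .errors import (
    InsufficientDataError,
    MissingFeatureError,
    NoBeatsError,
    TooShortError,
)
from .record import MISSING, EcgRecord, FiducialMarks

__all__ = [
    "RrSeries",
    "FeatureVector",
    "detect_r_peaks",
    "delineate",
    "rr_time_features",
    "rr_freq_features",
    "rr_stat_features",
    "beat_feature_vector",
    "rule_label",
    "rr_from_peaks",
]

REFRACTORY_S = 0.200
HIST_RANGE_S = (0.3, 2.0)
HIST_BINS = 32
HRV_BANDS = {"ulf": (0.0, 0.003), "vlf": (0.003, 0.04),
             "lf": (0.04, 0.15), "hf": (0.15, 0.4)}


@dataclass
class RrSeries:
    """Consecutive RR intervals in seconds."""

    intervals: np.ndarray
    sampling_rate: float = 0.0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        if self.intervals.ndim != 1:
            raise InsufficientDataError("intervals must be 1-D")
        if np.any(self.intervals <= 0):
            raise InsufficientDataError("RR intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals.size)


def rr_from_peaks(r_peaks: np.ndarray, sampling_rate: float) -> RrSeries:
    """RR series (s) from R-peak sample indices."""
    r = np.asarray(r_peaks, dtype=np.int64)
    if r.size < 2:
        raise InsufficientDataError("need at least two R peaks for RR intervals")
    return RrSeries(np.diff(r) / sampling_rate, sampling_rate)


# ---------------------------------------------------------------------------
# Detection and delineation
# ---------------------------------------------------------------------------

def detect_r_peaks(record: EcgRecord) -> np.ndarray:
    """Detect R-peak sample indices with an adaptive-threshold envelope detector.

    Deterministic; enforces a 200 ms refractory period.  Records shorter than
    2 s are rejected.
    """
    fs = record.sampling_rate
    if record.duration < 2.0:
        raise TooShortError("detect_r_peaks needs at least 2 s of signal")
    x = record.samples
    if not np.any(x):
        return np.asarray([], dtype=np.int64)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    der = np.gradient(bp)
    sq = der * der
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refr = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integ, distance=refr)
    if cand.size == 0:
        return np.asarray([], dtype=np.int64)

    # Adaptive signal/noise levels (Pan-Tompkins style running estimates).
    init = integ[: int(2 * fs)]
    spki = 0.4 * float(np.max(init))
    npki = 0.5 * float(np.mean(init))
    accepted = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if integ[c] >= thr:
            accepted.append(c)
            spki = 0.125 * integ[c] + 0.875 * spki
        else:
            npki = 0.125 * integ[c] + 0.875 * npki

    # Refine each envelope peak to the dominant local extremum of the trace.
    half = int(round(0.100 * fs))
    peaks = []
    for c in accepted:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        seg = x[lo:hi]
        k = lo + int(np.argmax(np.abs(seg - np.median(seg))))
        peaks.append(k)
    peaks = np.unique(np.asarray(peaks, dtype=np.int64))
    # Re-enforce refractory after refinement, keeping the taller peak.
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < refr:
            if abs(x[p]) > abs(x[keep[-1]]):
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.asarray(keep, dtype=np.int64)


def _edge_search(x: np.ndarray, start: int, base: float, forward: bool,
                 frac: float, max_span: int, ref: float) -> int:
    """Walk from ``start`` toward baseline until the trace settles within
    ``frac * ref`` of it; returns the edge sample or MISSING on failure."""
    if ref <= 0:
        return MISSING
    step = 1 if forward else -1
    k = start
    for _ in range(max_span):
        nxt = k + step
        if nxt < 0 or nxt >= len(x):
            return MISSING
        k = nxt
        if abs(x[k] - base) < frac * ref:
            return k
    return MISSING


def delineate(record: EcgRecord, r_peaks: np.ndarray) -> FiducialMarks:
    """Locate per-beat fiducial marks around each detected R peak.

    QRS onset/offset by amplitude/slope search within +/-120 ms of R, P peak
    as the local maximum in the 200 to 40 ms pre-QRS window, T peak as the
    local maximum 100-400 ms after the QRS offset.  Failed searches are
    flagged ``MISSING`` rather than fabricated.
    """
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if r_peaks.size == 0:
        raise NoBeatsError("delineate requires at least one R peak")
    x = record.samples
    fs = record.sampling_rate
    base = float(np.median(x))
    w120 = int(round(0.120 * fs))
    marks: Dict[str, list] = {k: [] for k in
                              ("p_onset", "p_peak", "qrs_onset", "r_peak",
                               "qrs_offset", "t_peak", "t_offset")}
    for r in r_peaks:
        r = int(r)
        lo = max(0, r - w120)
        hi = min(len(x), r + w120 + 1)
        q = lo + int(np.argmin(x[lo: r + 1])) if r > lo else r
        s = r + int(np.argmin(x[r:hi])) if hi > r + 1 else r
        r_amp = abs(x[r] - base)
        qrs_on = _edge_search(x, q if x[q] < base else r, base, forward=False,
                              frac=0.02, max_span=w120, ref=r_amp)
        qrs_off = _edge_search(x, s if x[s] < base else r, base, forward=True,
                               frac=0.02, max_span=w120, ref=r_amp)
        if qrs_on != MISSING and qrs_on >= r:
            qrs_on = MISSING
        if qrs_off != MISSING and qrs_off <= r:
            qrs_off = MISSING

        p_pk = p_on = MISSING
        if qrs_on != MISSING:
            w_lo = max(0, qrs_on - int(round(0.200 * fs)))
            w_hi = max(0, qrs_on - int(round(0.040 * fs)))
            if w_hi - w_lo > 2:
                seg = x[w_lo:w_hi]
                # prefer the last internal local maximum: at short RR the
                # previous beat's T wave can lean into the window's far end
                locs, _ = sps.find_peaks(seg)
                if locs.size:
                    cand = w_lo + int(locs[-1])
                else:
                    cand = w_lo + int(np.argmax(seg))
                if x[cand] - base > 0.02:  # mV floor: flat segment has no P
                    p_pk = cand
                    p_on = _edge_search(x, p_pk, base, forward=False, frac=0.02,
                                        max_span=int(round(0.120 * fs)),
                                        ref=abs(x[cand] - base))
                    if p_on != MISSING and p_on >= qrs_on:
                        p_on = MISSING
        if p_on == MISSING:
            p_pk = MISSING  # an unanchored peak is not reported

        t_pk = t_off = MISSING
        anchor = qrs_off if qrs_off != MISSING else r
        w_lo = min(len(x), anchor + int(round(0.100 * fs)))
        w_hi = min(len(x), anchor + int(round(0.400 * fs)))
        if w_hi - w_lo > 2:
            seg = x[w_lo:w_hi]
            cand = w_lo + int(np.argmax(seg))
            if x[cand] - base > 0.02:
                t_pk = cand
                t_off = _edge_search(x, t_pk, base, forward=True, frac=0.02,
                                     max_span=int(round(0.200 * fs)),
                                     ref=abs(x[cand] - base))
                if t_off != MISSING and t_off <= t_pk:
                    t_off = MISSING
        if t_off == MISSING:
            t_pk = MISSING

        marks["p_onset"].append(p_on)
        marks["p_peak"].append(p_pk)
        marks["qrs_onset"].append(qrs_on)
        marks["r_peak"].append(r)
        marks["qrs_offset"].append(qrs_off)
        marks["t_peak"].append(t_pk)
        marks["t_offset"].append(t_off)
    return FiducialMarks(**{k: np.asarray(v, dtype=np.int64) for k, v in marks.items()})


# ---------------------------------------------------------------------------
# RR feature groups
# ---------------------------------------------------------------------------

def rr_time_features(rr: RrSeries) -> Dict[str, object]:
    """Time-domain HRV features; requires at least 2 intervals."""
    iv = rr.intervals
    if iv.size < 2:
        raise InsufficientDataError("rr_time_features needs >= 2 intervals")
    d = np.diff(iv)
    hist, edges = np.histogram(iv, bins=HIST_BINS, range=HIST_RANGE_S)
    return {
        "rr_mean": float(np.mean(iv)),
        "rr_median": float(np.median(iv)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "avg_deviation": float(np.mean(np.abs(iv - np.mean(iv)))),
        "max_deviation": float(np.max(np.abs(iv - np.mean(iv)))),
        "nn50": int(np.count_nonzero(np.abs(d) > 0.050)),
        "histogram": hist,
        "histogram_edges": edges,
    }


def rr_freq_features(rr: RrSeries, resample_hz: float = 4.0) -> Dict[str, float]:
    """Frequency-domain HRV features from a Welch PSD of the resampled series.

    The unevenly spaced RR sequence is linearly interpolated onto a uniform
    ``resample_hz`` grid; band powers are integrated from the periodogram.
    Requires at least 64 intervals for spectral stability.
    """
    iv = rr.intervals
    if iv.size < 64:
        raise InsufficientDataError("rr_freq_features needs >= 64 intervals")
    t = np.cumsum(iv)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    even = np.interp(grid, t, iv)
    even = even - np.mean(even)
    nperseg = min(256, even.size)
    f, pxx = sps.welch(even, fs=resample_hz, nperseg=nperseg)
    out: Dict[str, float] = {}
    for name, (lo, hi) in HRV_BANDS.items():
        m = (f >= lo) & (f < hi)
        out[f"{name}_power"] = float(np.trapezoid(pxx[m], f[m])) if np.any(m) else 0.0
    hf = out["hf_power"]
    out["lf_hf_ratio"] = float(out["lf_power"] / hf) if hf > 0 else math.nan
    out["total_power"] = float(np.trapezoid(pxx, f))
    return out


def rr_stat_features(rr: RrSeries) -> Dict[str, float]:
    """Distribution statistics of the RR series; requires >= 4 intervals.

    Kurtosis is the excess (Fisher) kurtosis; for a degenerate constant
    series skewness/kurtosis are 0/0 and reported as NaN.
    """
    iv = rr.intervals
    if iv.size < 4:
        raise InsufficientDataError("rr_stat_features needs >= 4 intervals")
    sd = float(np.std(iv, ddof=1))
    if sd == 0.0:
        skew = kurt = math.nan
    else:
        skew = float(spstats.skew(iv))
        kurt = float(spstats.kurtosis(iv, fisher=True))
    return {
        "mean": float(np.mean(iv)),
        "median": float(np.median(iv)),
        "sd": sd,
        "kurtosis": kurt,
        "range": float(np.ptp(iv)),
        "skewness": skew,
    }


# ---------------------------------------------------------------------------
# Beat feature vector and rhythm labelling
# ---------------------------------------------------------------------------

#: Order of the eight per-record statistics used for rhythm classification.
BEAT_FEATURE_NAMES = (
    "hr_mean", "hr_sd", "qrs_amplitude_mean", "qrs_amplitude_sd",
    "qrs_time_mean", "qrs_time_sd", "pr_interval_mean", "pr_interval_sd",
)


@dataclass
class FeatureVector:
    """Per-record beat statistics plus optional RR feature groups."""

    hr_mean: float
    hr_sd: float
    qrs_amplitude_mean: float
    qrs_amplitude_sd: float
    qrs_time_mean: float
    qrs_time_sd: float
    pr_interval_mean: float
    pr_interval_sd: float
    time_domain: Optional[Dict[str, object]] = None
    freq_domain: Optional[Dict[str, float]] = None
    statistical: Optional[Dict[str, float]] = None

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BEAT_FEATURE_NAMES], dtype=np.float64)


def _sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if v.size > 1 else 0.0


def beat_feature_vector(record: EcgRecord, marks: FiducialMarks) -> FeatureVector:
    """The eight per-record beat statistics from delineated marks.

    Heart rate: ``hr_mean = 60 / mean(RR)``; ``hr_sd`` is the SD of per-beat
    instantaneous rates.  QRS amplitude is the R-peak amplitude relative to
    the QRS-onset baseline sample; QRS duration is offset - onset; PR is
    P onset to QRS onset.  Beats with missing marks are excluded from the
    statistics that need them.
    """
    if marks.n_beats < 2:
        raise InsufficientDataError("beat_feature_vector needs >= 2 beats")
    fs = record.sampling_rate
    x = record.samples
    rr = np.diff(marks.r_peak) / fs
    hr_inst = 60.0 / rr
    hr_mean = 60.0 / float(np.mean(rr))

    ok_qrs = (marks.qrs_onset != MISSING) & (marks.qrs_offset != MISSING)
    qrs_amp = x[marks.r_peak[ok_qrs]] - x[marks.qrs_onset[ok_qrs]]
    qrs_time = (marks.qrs_offset[ok_qrs] - marks.qrs_onset[ok_qrs]) / fs
    ok_pr = (marks.p_onset != MISSING) & (marks.qrs_onset != MISSING)
    pr = (marks.qrs_onset[ok_pr] - marks.p_onset[ok_pr]) / fs

    def _mean(v: np.ndarray) -> float:
        return float(np.mean(v)) if v.size else math.nan

    return FeatureVector(
        hr_mean=hr_mean,
        hr_sd=_sd(hr_inst),
        qrs_amplitude_mean=_mean(qrs_amp),
        qrs_amplitude_sd=_sd(qrs_amp),
        qrs_time_mean=_mean(qrs_time),
        qrs_time_sd=_sd(qrs_time),
        pr_interval_mean=_mean(pr),
        pr_interval_sd=_sd(pr),
    )


def rule_label(features: FeatureVector) -> str:
    """Rate-threshold rhythm label: > 100 bpm tachycardia, < 60 bradycardia,
    otherwise normal (boundary rates are normal)."""
    hr = features.hr_mean
    if hr is None or (isinstance(hr, float) and math.isnan(hr)):
        raise MissingFeatureError("hr_mean")
    if hr > 100.0:
        return "tachycardia"
    if hr < 60.0:
        return "bradycardia"
    return "normal"
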