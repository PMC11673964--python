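"""Daubechies filter banks and the two-channel analysis/synthesis step.

The scaling (low-pass) filter ``g`` of the order-N Daubechies family is
constructed by spectral factorization: the half-band product filter's
polynomial ``P(y) = sum_{k<N} C(N-1+k, k) y^k`` is rooted, each root is
mapped to the z-plane, and the minimum-phase factor is combined with the
``(1+z)^N`` vanishing-moment factor.  The high-pass filter follows from the
quadrature-mirror relation ``h[k] = (-1)^k g[2N-1-k]``.

One analysis step computes, with ``x`` periodically extended,

    approx[n] = sum_k x(k) g(2n - k)
    detail[n] = sum_k x(k) h(2n - k)

i.e. circular convolution followed by keeping the even-indexed outputs; the
synthesis step is the exact transpose, which for an orthonormal bank is the
inverse.  Odd-length inputs are wrap-padded by one sample before analysis so
the periodic step stays invertible; reconstruction trims the pad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Tuple

import numpy as np

from .errors import TooShortError, UnsupportedOrderError

__all__ = ["WaveletFilterBank", "daubechies_filters", "dwt_step", "idwt_step"]

MAX_ORDER = 10


@dataclass(frozen=True)
class WaveletFilterBank:
    """Analysis/synthesis filter quadruple for an orthonormal wavelet.

    ``g`` is the analysis low-pass (scaling) filter, ``h`` the analysis
    high-pass (wavelet) filter; for an orthonormal bank the synthesis filters
    are their time reverses.
    """

    order: int
    g: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "g", np.asarray(self.g, dtype=np.float64))
        object.__setattr__(self, "h", np.asarray(self.h, dtype=np.float64))

    @property
    def length(self) -> int:
        return int(self.g.size)

    @property
    def synthesis_g(self) -> np.ndarray:
        return self.g[::-1]

    @property
    def synthesis_h(self) -> np.ndarray:
        return self.h[::-1]


def _daubechies_lowpass(order: int) -> np.ndarray:
    if order == 1:
        return np.array([1.0, 1.0]) / sqrt(2.0)
    # Roots of the binomial half-band polynomial P(y), y = (2 - z - 1/z)/4.
    p = np.array([comb(order - 1 + k, k) for k in range(order)], dtype=np.float64)
    roots_y = np.roots(p[::-1])
    z_roots = []
    for y in roots_y:
        zz = np.roots([1.0, 4.0 * y - 2.0, 1.0])
        z_roots.append(zz[np.argmin(np.abs(zz))])  # minimum-phase choice
    poly = np.poly1d([1.0])
    for zk in z_roots:
        poly = poly * np.poly1d([1.0, -zk])
    for _ in range(order):
        poly = poly * np.poly1d([1.0, 1.0])
    g = np.real(poly.coeffs)
    g = g * sqrt(2.0) / g.sum()
    # Orient so g matches the conventional ascending-index scaling filter
    # (db2 -> [(1+s3),(3+s3),(3-s3),(1-s3)]/(4*sqrt 2)); the factorization
    # above already yields this orientation.
    return g


def daubechies_filters(order: int) -> WaveletFilterBank:
    """Daubechies filter bank of the given order (1 = Haar, ..., 10).

    The returned bank satisfies sum(g) = sqrt(2), sum(h) = 0 and
    ``sum(g**2) = sum(h**2) = 1`` to ~1e-12.
    """
    if not (1 <= int(order) <= MAX_ORDER):
        raise UnsupportedOrderError(f"Daubechies order must be in [1, {MAX_ORDER}]")
    order = int(order)
    g = _daubechies_lowpass(order)
    k = np.arange(2 * order)
    h = ((-1.0) ** k) * g[::-1]
    return WaveletFilterBank(order=order, g=g, h=h)


def _wrap_pad_even(x: np.ndarray) -> np.ndarray:
    """Periodic one-sample pad to even length (identity if already even)."""
    if x.size % 2:
        return np.concatenate([x, x[:1]])
    return x


def dwt_step(signal: np.ndarray, bank: WaveletFilterBank) -> Tuple[np.ndarray, np.ndarray]:
    """One periodic analysis step: (approximation, detail) at half length.

    Output length is ``ceil(len(signal)/2)``; odd inputs are wrap-padded by
    one sample first.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 2:
        raise TooShortError("dwt_step requires at least 2 samples")
    x = _wrap_pad_even(x)
    n = x.size
    half = n // 2
    j = np.arange(bank.length)
    idx = (2 * np.arange(half)[:, None] - j[None, :]) % n
    xs = x[idx]
    approx = xs @ bank.g
    detail = xs @ bank.h
    return approx, detail


def idwt_step(approx: np.ndarray, detail: np.ndarray, bank: WaveletFilterBank,
              out_length: int | None = None) -> np.ndarray:
    """Exact transpose of :func:`dwt_step` (the inverse for orthonormal banks).

    ``out_length`` trims the reconstruction when the forward step wrap-padded
    an odd-length parent.
    """
    a = np.asarray(approx, dtype=np.float64)
    d = np.asarray(detail, dtype=np.float64)
    if a.size != d.size:
        raise TooShortError("approx and detail must have equal length")
    half = a.size
    n = 2 * half
    out = np.zeros(n)
    targets = 2 * np.arange(half)
    for j in range(bank.length):
        pos = (targets - j) % n
        np.add.at(out, pos, bank.g[j] * a + bank.h[j] * d)
    if out_length is not None:
        out = out[:out_length]
    return out
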