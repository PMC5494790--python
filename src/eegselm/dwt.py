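"""Lifting-scheme Daubechies-4 wavelet decomposition of EEG epochs.

EEG is band-limited to 0-32 Hz and decomposed with a three-level dyadic
filter bank into one approximation band A3 (nominally delta, 0-4 Hz) and
three detail bands D3 (theta, 4-8 Hz), D2 (alpha, 8-16 Hz), D1 (beta,
16-32 Hz).  The 4-tap orthonormal Daubechies filter (two vanishing
moments) is applied through its lifting factorisation -- an exactly
invertible sequence of update / predict / scaling steps on the even/odd
polyphase components -- rather than by convolution.

Analysis convention, frozen for reproducibility: even-indexed samples feed
the approximation branch and odd-indexed samples the prediction branch;
with periodic boundary handling the lifting output equals circular
convolution with the quadrature filter pair followed by dyadic decimation
(the detail channel at a two-sample circular delay).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import butter, filtfilt

from .io_synth import EEGSegment

__all__ = [
    "Db4FilterPair",
    "SubbandSet",
    "db4_filters",
    "bandpass_0_32",
    "lifting_step",
    "inverse_lifting_step",
    "decompose3",
    "reconstruct3",
]

_SQRT3 = np.sqrt(3.0)
_SQRT2 = np.sqrt(2.0)

Boundary = Literal["periodic", "zero"]


@dataclass(frozen=True)
class Db4FilterPair:
    """The 4-tap orthonormal analysis filter pair.

    ``highpass`` is the quadrature mirror of ``lowpass``:
    ``(-h3, h2, -h1, h0)``.
    """

    lowpass: tuple[float, float, float, float]
    highpass: tuple[float, float, float, float]


def db4_filters() -> Db4FilterPair:
    """Closed-form Daubechies-4 filter coefficients.

    ``h0 = (1+sqrt3)/(4*sqrt2)``, ``h1 = (3+sqrt3)/(4*sqrt2)``,
    ``h2 = (3-sqrt3)/(4*sqrt2)``, ``h3 = (1-sqrt3)/(4*sqrt2)``;
    the low-pass sums to ``sqrt2`` and the high-pass to 0.
    """
    h0 = (1.0 + _SQRT3) / (4.0 * _SQRT2)
    h1 = (3.0 + _SQRT3) / (4.0 * _SQRT2)
    h2 = (3.0 - _SQRT3) / (4.0 * _SQRT2)
    h3 = (1.0 - _SQRT3) / (4.0 * _SQRT2)
    return Db4FilterPair(lowpass=(h0, h1, h2, h3), highpass=(-h3, h2, -h1, h0))


@dataclass(frozen=True)
class SubbandSet:
    """The four subband coefficient sequences of one epoch.

    For an input of length L divisible by 8: ``len(d1) == L/2``,
    ``len(d2) == L/4`` and ``len(d3) == len(a3) == L/8``.
    """

    a3: np.ndarray  # approximation, nominally 0-4 Hz (delta)
    d3: np.ndarray  # detail level 3, 4-8 Hz (theta)
    d2: np.ndarray  # detail level 2, 8-16 Hz (alpha)
    d1: np.ndarray  # detail level 1, 16-32 Hz (beta)
    epoch_id: str = ""

    def __post_init__(self) -> None:
        for name in ("a3", "d3", "d2", "d1"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate_lengths(self) -> None:
        n3 = self.a3.size
        if self.d3.size != n3 or self.d2.size != 2 * n3 or self.d1.size != 4 * n3:
            raise ValueError(
                "inconsistent subband lengths: expected (n, n, 2n, 4n), got "
                f"({self.a3.size}, {self.d3.size}, {self.d2.size}, {self.d1.size})"
            )

    def bands(self) -> dict[str, np.ndarray]:
        """Subbands keyed by name, in the fixed order A3, D3, D2, D1."""
        return {"A3": self.a3, "D3": self.d3, "D2": self.d2, "D1": self.d1}


def bandpass_0_32(
    segment: EEGSegment, order: int = 4, cutoff: float = 32.0
) -> EEGSegment:
    """Band-limit a segment to 0-32 Hz with a zero-phase Butterworth filter.

    The lower band edge of 0 Hz makes the filter an ordinary low-pass; it is
    applied forward and backward (``filtfilt``) so no group delay is
    introduced and the output length equals the input length.
    """
    if segment.fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {segment.fs} Hz too low for a {cutoff} Hz cutoff "
            f"(need fs > {2 * cutoff} Hz)"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    b, a = butter(order, cutoff, btype="low", fs=segment.fs)
    filtered = filtfilt(b, a, segment.samples)
    return EEGSegment(
        samples=filtered, fs=segment.fs, label=segment.label, segment_id=segment.segment_id
    )


def _shift(x: np.ndarray, k: int, boundary: Boundary) -> np.ndarray:
    """x delayed by k samples (x[l-k]) under the chosen boundary rule."""
    if boundary == "periodic":
        return np.roll(x, k)
    out = np.zeros_like(x)
    if k > 0:
        out[k:] = x[:-k]
    elif k < 0:
        out[:k] = x[-k:]
    else:
        out[:] = x
    return out


def lifting_step(
    even: np.ndarray, odd: np.ndarray, boundary: Boundary = "periodic"
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis stage of the db4 lifting factorisation.

    The caller has already split the signal into even/odd polyphase
    components of equal length.  Steps, in order: an update ``s = even +
    sqrt3*odd``; a predict subtracting ``sqrt3/4 * s_l + (sqrt3-2)/4 *
    s_{l-1}`` from the odd channel; an update subtracting ``d_{l+1}``; and
    the scaling pair ``(sqrt3-1)/sqrt2`` / ``(sqrt3+1)/sqrt2``.  With
    periodic boundaries the result matches convolution/decimation with the
    orthonormal filter pair exactly.
    """
    even = np.asarray(even, dtype=float)
    odd = np.asarray(odd, dtype=float)
    if even.shape != odd.shape:
        raise ValueError(
            f"even/odd length mismatch: {even.shape} vs {odd.shape}"
        )
    s = even + _SQRT3 * odd
    d = odd - (_SQRT3 / 4.0) * s - ((_SQRT3 - 2.0) / 4.0) * _shift(s, 1, boundary)
    s = s - _shift(d, -1, boundary)
    approx = s * (_SQRT3 - 1.0) / _SQRT2
    detail = d * (_SQRT3 + 1.0) / _SQRT2
    return approx, detail


def inverse_lifting_step(
    approx: np.ndarray, detail: np.ndarray, boundary: Boundary = "periodic"
) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`lifting_step`; returns the (even, odd) components.

    Each lifting step only adds a function of the other channel, so the
    inverse simply runs the steps backwards with flipped signs, for any
    boundary rule.
    """
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    if approx.shape != detail.shape:
        raise ValueError(f"length mismatch: {approx.shape} vs {detail.shape}")
    s = approx * _SQRT2 / (_SQRT3 - 1.0)
    d = detail * _SQRT2 / (_SQRT3 + 1.0)
    s = s + _shift(d, -1, boundary)
    odd = d + (_SQRT3 / 4.0) * s + ((_SQRT3 - 2.0) / 4.0) * _shift(s, 1, boundary)
    even = s - _SQRT3 * odd
    return even, odd


def _analysis(x: np.ndarray, boundary: Boundary) -> tuple[np.ndarray, np.ndarray]:
    return lifting_step(x[0::2], x[1::2], boundary=boundary)


def _synthesis(approx: np.ndarray, detail: np.ndarray, boundary: Boundary) -> np.ndarray:
    even, odd = inverse_lifting_step(approx, detail, boundary=boundary)
    x = np.empty(2 * even.size)
    x[0::2] = even
    x[1::2] = odd
    return x


def decompose3(
    epoch: np.ndarray, epoch_id: str = "", boundary: Boundary = "periodic"
) -> SubbandSet:
    """Three-level dyadic decomposition of an epoch into A3/D3/D2/D1.

    D1 comes from level 1, D2 from level 2, and D3 and A3 from level 3;
    each level recurses on the approximation branch.  The input length must
    be divisible by 8 (512 in the standard pipeline).
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be 1-D")
    if x.size == 0 or x.size % 8 != 0:
        raise ValueError(
            f"epoch length must be a positive multiple of 8 for a 3-level "
            f"decomposition, got {x.size}"
        )
    a1, d1 = _analysis(x, boundary)
    a2, d2 = _analysis(a1, boundary)
    a3, d3 = _analysis(a2, boundary)
    return SubbandSet(a3=a3, d3=d3, d2=d2, d1=d1, epoch_id=epoch_id)


def reconstruct3(subbands: SubbandSet, boundary: Boundary = "periodic") -> np.ndarray:
    """Invert :func:`decompose3`; exact to machine precision."""
    subbands.validate_lengths()
    a2 = _synthesis(subbands.a3, subbands.d3, boundary)
    a1 = _synthesis(a2, subbands.d2, boundary)
    return _synthesis(a1, subbands.d1, boundary)
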