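"""Tunable Q-factor wavelet transform (TQWT).

An over-complete discrete wavelet transform built from an iterated two-channel
filter bank whose low-pass and high-pass branches rescale the spectrum by
``alpha`` and ``beta``.  The two free parameters are the Q-factor ``Q``
(center frequency over bandwidth of the sub-bands) and the redundancy ``r``
(total coefficients per input sample as the depth grows)::

    beta  = 2 / (Q + 1)
    alpha = 1 - beta / r

Each analysis stage splits the current low-pass signal into a detail band of
length ``~beta * alpha**(j-1) * N`` and a coarser low-pass of length
``~alpha**j * N``; after ``J`` stages the transform yields ``J + 1`` bands
(details 1..J from high to low frequency, then the final approximation).

The filters are defined directly in the DFT domain with the smooth
power-complementary transition window ``theta(w) = 0.5 (1 + cos w) sqrt(2 -
cos w)``, which makes the transform perfectly invertible to machine
precision under a circular boundary convention.  The implementation uses a
unitary FFT scaling so that analysis is energy preserving (Parseval frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor, log

import numpy as np

from .errors import DataError, LevelError, ParameterError, StructuralError

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "scaling_factors",
    "max_levels",
    "subband_lengths",
    "subband_center_frequencies",
    "forward",
    "inverse",
]

#: Minimum nominal length of the deepest high-pass band; one extra level is
#: refused once ``beta * alpha**J * N`` would drop below this support.
_MIN_SUPPORT = 8


@dataclass(frozen=True)
class TQWTParams:
    """Transform configuration: Q-factor, redundancy and depth.

    Parameters
    ----------
    q_factor : float
        Q-factor, >= 1.  High Q narrows the sub-bands (sustained
        oscillations); Q = 1 approaches a constant-Q dyadic-like analysis
        suited to transients.
    redundancy : float
        Over-sampling rate r > 1; total coefficient count approaches
        ``r * N`` as the depth grows.
    levels : int
        Number of high-pass stages J >= 1; the transform yields J + 1 bands.
    """

    q_factor: float = 1.0
    redundancy: float = 3.0
    levels: int = 9

    def __post_init__(self) -> None:
        if not np.isfinite(self.q_factor) or self.q_factor < 1:
            raise ParameterError(f"q_factor must be >= 1, got {self.q_factor}")
        if not np.isfinite(self.redundancy) or self.redundancy <= 1:
            raise ParameterError(f"redundancy must be > 1, got {self.redundancy}")
        if int(self.levels) != self.levels or self.levels < 1:
            raise ParameterError(f"levels must be a positive integer, got {self.levels}")

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta / self.redundancy

    @property
    def beta(self) -> float:
        return 2.0 / (self.q_factor + 1.0)


@dataclass
class SubbandSet:
    """Output of :func:`forward`: J + 1 ragged coefficient sequences.

    ``coeffs[0] .. coeffs[J-1]`` are detail bands ordered from highest to
    lowest center frequency; ``coeffs[J]`` is the final approximation.
    ``original_length`` is the pre-padding input length (odd inputs are
    zero-padded by one sample for the radix-friendly filter bank and the pad
    is dropped on inversion).
    """

    coeffs: list[np.ndarray]
    params: TQWTParams
    original_length: int
    padded: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.coeffs) != self.params.levels + 1:
            raise StructuralError(
                f"expected {self.params.levels + 1} sub-bands, got {len(self.coeffs)}"
            )
        n_even = self.original_length + (1 if self.padded else 0)
        expected = subband_lengths(self.params, n_even)
        got = [len(c) for c in self.coeffs]
        if got != expected:
            raise StructuralError(f"sub-band lengths {got} do not match {expected}")
        for j, c in enumerate(self.coeffs):
            if not np.all(np.isfinite(c)):
                raise StructuralError(f"sub-band {j} contains NaN/Inf")

    @property
    def total_coefficients(self) -> int:
        return int(sum(len(c) for c in self.coeffs))


def scaling_factors(params: TQWTParams) -> tuple[float, float]:
    """Return ``(alpha, beta)`` = low-pass and high-pass spectral scalings."""
    return params.alpha, params.beta


def _even(x: float) -> int:
    # round-half-to-even on x/2, then double: bit-reproducible even lengths
    return 2 * int(np.round(x / 2.0))


def max_levels(params: TQWTParams, n_samples: int) -> int:
    """Largest usable depth J for an input of ``n_samples``.

    The bound is ``floor(log(beta*N/8) / log(1/alpha))``: the deepest
    high-pass band must keep a nominal length of at least 8 samples.
    """
    if n_samples < 16:
        raise ParameterError(f"n_samples must be >= 16, got {n_samples}")
    alpha, beta = scaling_factors(params)
    arg = beta * n_samples / _MIN_SUPPORT
    if arg < 1.0:
        return 0
    return max(0, floor(log(arg) / log(1.0 / alpha)))


def subband_lengths(params: TQWTParams, n_samples: int) -> list[int]:
    """Lengths of the J + 1 bands for an even input length ``n_samples``.

    Detail level j has length ``2*round(beta * alpha**(j-1) * N / 2)``; the
    final approximation has length ``2*round(alpha**J * N / 2)`` (round half
    to even).
    """
    if n_samples % 2:
        n_samples += 1
    jmax = max_levels(params, n_samples)
    if params.levels > jmax:
        raise LevelError(
            f"levels={params.levels} exceeds max_levels={jmax} for N={n_samples}"
        )
    alpha, beta = scaling_factors(params)
    out = [_even(beta * alpha ** (j - 1) * n_samples) for j in range(1, params.levels + 1)]
    out.append(_even(alpha ** params.levels * n_samples))
    return out


def subband_center_frequencies(params: TQWTParams, fs: float) -> np.ndarray:
    """Approximate center frequency (Hz) of each of the J + 1 bands.

    Detail level j is centered near ``alpha**(j-1) * (2 - beta) * fs / 4``,
    strictly decreasing with j.  The final approximation covers the residual
    low end; its nominal center is reported at half the would-be next detail
    center, keeping the sequence strictly decreasing toward 0.
    """
    if fs <= 0:
        raise ParameterError(f"fs must be positive, got {fs}")
    alpha, beta = scaling_factors(params)
    j = np.arange(1, params.levels + 1)
    detail = alpha ** (j - 1) * (2.0 - beta) * fs / 4.0
    approx = alpha ** params.levels * (2.0 - beta) * fs / 8.0
    return np.concatenate([detail, [approx]])


def _transition(n: int) -> np.ndarray:
    """Interior samples of the power-complementary transition window."""
    v = np.arange(1, n + 1) * (np.pi / (n + 1))
    return 0.5 * (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v))


def _bands_geometry(n: int, n0: int, n1: int) -> tuple[int, int, int]:
    p = (n - n1) // 2          # fully passed low-pass bins (one side)
    t = (n0 + n1 - n) // 2 - 1  # interior transition bins
    s = (n - n0) // 2          # low-pass stop bins == high-pass extra pass
    if p < 0 or t < 0 or s < 0:
        raise LevelError(
            f"invalid filter-bank geometry (N={n}, N0={n0}, N1={n1}); "
            "reduce the number of levels"
        )
    return p, t, s


def _afb(x_hat: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """One analysis stage in the DFT domain (spectrum in, two spectra out)."""
    n = len(x_hat)
    p, t, s = _bands_geometry(n, n0, n1)
    tr = _transition(t)
    v0 = np.zeros(n0, dtype=complex)
    v0[0] = x_hat[0]
    v0[1:p + 1] = x_hat[1:p + 1]
    v0[p + 1:p + t + 1] = x_hat[p + 1:p + t + 1] * tr
    # v0[n0//2] (Nyquist) stays 0: that bin lives in the high-pass branch
    v0[n0 - p - t:n0 - p] = x_hat[n - p - t:n - p] * tr[::-1]
    if p:
        v0[n0 - p:] = x_hat[n - p:]
    v1 = np.zeros(n1, dtype=complex)
    v1[1:t + 1] = x_hat[p + 1:p + t + 1] * tr[::-1]
    v1[t + 1:t + s + 1] = x_hat[p + t + 1:p + t + s + 1]
    v1[n1 // 2] = x_hat[n // 2]
    v1[n1 - t - s:n1 - t] = x_hat[n - p - t - s:n - p - t]
    v1[n1 - t:] = x_hat[n - p - t:n - p] * tr
    return v0, v1


def _sfb(v0: np.ndarray, v1: np.ndarray, n: int) -> np.ndarray:
    """One synthesis stage: exact inverse of :func:`_afb`."""
    n0, n1 = len(v0), len(v1)
    p, t, s = _bands_geometry(n, n0, n1)
    tr = _transition(t)
    y = np.zeros(n, dtype=complex)
    y[0] = v0[0]
    y[1:p + 1] = v0[1:p + 1]
    y[p + 1:p + t + 1] = v0[p + 1:p + t + 1] * tr + v1[1:t + 1] * tr[::-1]
    y[p + t + 1:p + t + s + 1] = v1[t + 1:t + s + 1]
    y[n // 2] = v1[n1 // 2]
    y[n - p - t - s:n - p - t] = v1[n1 - t - s:n1 - t]
    y[n - p - t:n - p] = v0[n0 - p - t:n0 - p] * tr[::-1] + v1[n1 - t:] * tr
    if p:
        y[n - p:] = v0[n0 - p:]
    return y


def forward(x: np.ndarray, params: TQWTParams) -> SubbandSet:
    """Decompose a real 1-D signal into J + 1 TQWT sub-bands.

    Linear, circular-boundary, perfectly invertible (see :func:`inverse`).
    Odd-length inputs are zero-padded by one sample; the pad is recorded and
    dropped on inversion.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DataError(f"expected a 1-D signal, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DataError("input signal contains NaN/Inf")
    n_orig = len(x)
    padded = bool(n_orig % 2)
    if padded:
        x = np.concatenate([x, [0.0]])
    n = len(x)
    jmax = max_levels(params, n)
    if params.levels > jmax:
        raise LevelError(
            f"levels={params.levels} exceeds max_levels={jmax} for N={n} "
            f"(Q={params.q_factor}, r={params.redundancy})"
        )
    alpha, beta = scaling_factors(params)
    x_hat = np.fft.fft(x) / np.sqrt(n)
    coeffs: list[np.ndarray] = []
    for j in range(1, params.levels + 1):
        n0 = _even(alpha ** j * n)
        n1 = _even(beta * alpha ** (j - 1) * n)
        x_hat, w_hat = _afb(x_hat, n0, n1)
        coeffs.append(np.fft.ifft(w_hat * np.sqrt(n1)).real)
    coeffs.append(np.fft.ifft(x_hat * np.sqrt(len(x_hat))).real)
    return SubbandSet(coeffs=coeffs, params=params, original_length=n_orig, padded=padded)


def inverse(sb: SubbandSet) -> np.ndarray:
    """Reconstruct the time signal from a :class:`SubbandSet` exactly."""
    params = sb.params
    alpha, beta = scaling_factors(params)
    n = sb.original_length + (1 if sb.padded else 0)
    approx = sb.coeffs[-1]
    x_hat = np.fft.fft(np.asarray(approx, dtype=float)) / np.sqrt(len(approx))
    for j in range(params.levels, 0, -1):
        n_up = _even(alpha ** (j - 1) * n) if j > 1 else n
        w = np.asarray(sb.coeffs[j - 1], dtype=float)
        w_hat = np.fft.fft(w) / np.sqrt(len(w))
        x_hat = _sfb(x_hat, w_hat, n_up)
    x = np.fft.ifft(x_hat * np.sqrt(n)).real
    return x[:sb.original_length]
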