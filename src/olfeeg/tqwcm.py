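"""Tunable Q-factor wavelet coefficient mapping (TQWCM).

The TQWT yields ragged sub-bands: a high-frequency detail band has many
coefficients (fine time resolution), the approximation has few.  Stacking
them directly would distort the time-frequency tiling, so each band is
linearly interpolated onto a common uniform time axis and the rows are
stacked high-to-low frequency into a scalogram-like image.  Applied per EEG
channel, this gives a (channels x bands x time) tensor - the image the
convolutional feature extractor consumes.

Rows carry raw signed coefficients by default (preserving phase for the
downstream network); a magnitude option is available since either reading of
a "scalogram-like" image is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import EEGTrial
from .errors import StructuralError
from .tqwt import SubbandSet, TQWTParams, forward

__all__ = ["TFImage", "map_subbands", "build_tqwcm"]


@dataclass
class TFImage:
    """Uniform time-frequency image: ``pixels`` is channels x bands x time.

    Band rows are ordered by descending center frequency (row 0 = level-1
    detail, last row = approximation); the time axis is at the original
    sample resolution.
    """

    pixels: np.ndarray
    params: TQWTParams
    fs: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise StructuralError(f"pixels must be 3-D, got shape {self.pixels.shape}")
        if self.pixels.shape[1] != self.params.levels + 1:
            raise StructuralError(
                f"expected {self.params.levels + 1} bands, got {self.pixels.shape[1]}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise StructuralError("TFImage contains NaN/Inf")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_times(self) -> int:
        return self.pixels.shape[2]


def map_subbands(sb: SubbandSet, target_length: int) -> np.ndarray:
    """Interpolate every sub-band onto ``target_length`` uniform points.

    Band sample k of a length-L band sits at abscissa ``k * (T-1) / (L-1)``
    on the target grid ``0..T-1`` (endpoints aligned), and values in between
    are linear.  This keeps the mapping exact on constants and affine ramps
    and reduces to the identity when a band already has the target length.
    Rows are stacked high-to-low frequency (last row = approximation).
    """
    if target_length < 2:
        raise StructuralError(f"target_length must be >= 2, got {target_length}")
    t = np.arange(target_length, dtype=float)
    rows = np.empty((len(sb.coeffs), target_length))
    for j, band in enumerate(sb.coeffs):
        L = len(band)
        if L < 2:
            raise StructuralError(f"sub-band {j} has length {L} < 2; cannot interpolate")
        if L == target_length:
            rows[j] = band
        else:
            rows[j] = np.interp(t, np.arange(L) * (target_length - 1) / (L - 1), band)
    return rows


def build_tqwcm(
    trial: EEGTrial, params: TQWTParams, magnitude: bool = False
) -> TFImage:
    """TQWT + coefficient mapping per EEG channel -> (channels, J+1, N) image."""
    n = trial.n_samples
    chans = np.empty((trial.n_channels, params.levels + 1, n))
    for c in range(trial.n_channels):
        try:
            sb = forward(trial.data[c], params)
        except Exception as exc:
            raise type(exc)(f"channel {c}: {exc}") from exc
        chans[c] = map_subbands(sb, n)
    if magnitude:
        chans = np.abs(chans)
    return TFImage(pixels=chans, params=params, fs=trial.fs)
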