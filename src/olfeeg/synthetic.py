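"""Synthetic olfactory-EEG generator.

Emulates the structure of a small olfactory-stimulation cohort: a handful of
elderly subjects per diagnostic class (healthy, MCI, AD), ~110 two-second
trials each, four frontal/midline channels (Fp1, Fz, Cz, Pz) sampled at
200 Hz and band-limited to 0.5-40 Hz upstream.

Each trial is a sum over the canonical EEG rhythms (delta 0.5-4, theta 4-8,
alpha 8-13, beta 13-30 Hz) of amplitude-modulated band-limited noise
oscillations.  Class identity enters twice:

* **spectrally** - per-class multiplicative gains over the four rhythms
  (the defaults follow the classical "EEG slowing" picture: AD gains power
  in delta/theta and loses alpha/beta relative to healthy controls);
* **spatially** - a per-class orthogonal channel-mixing matrix applied to
  channels with unequal base amplitudes, which imprints a class-specific
  spatial covariance that CSP and tangent-space features can pick up.

Subjects within a class differ by a mild log-normal jitter on the band gains,
so leave-one-subject-out generalization is non-trivial.  A 1/f^k pink-noise
background is added at a configurable SNR.  All randomness flows from one
root seed through ``numpy.random.SeedSequence.spawn``, so each subject's
stream is reproducible independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.linalg import expm

from .dataset import DEFAULT_CHANNELS, EEGTrial, EEGTrialSet, Label, Odor
from .errors import ConfigurationError

__all__ = [
    "BANDS",
    "SyntheticConfig",
    "default_band_gains",
    "strong_band_gains",
    "default_spatial_mixing",
    "strong_spatial_mixing",
    "generate_synthetic_dataset",
]

#: Canonical EEG rhythm edges in Hz (delta, theta, alpha, beta); all below
#: the 40 Hz upstream low-pass.
BANDS: tuple[tuple[float, float], ...] = ((0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0))

_CLASS_ORDER = (Label.HEALTHY, Label.MCI, Label.AD)

#: Probability that a trial is a lemon presentation (the cohort design
#: emitted lemon three times as often as rose).
_LEMON_PROBABILITY = 0.75


def default_band_gains() -> dict[Label, np.ndarray]:
    """Realistic per-class gains over (delta, theta, alpha, beta).

    Healthy controls are alpha-dominant; MCI shows mild theta elevation and
    alpha attenuation; AD shows pronounced slowing (delta/theta up,
    alpha/beta down).
    """
    return {
        Label.HEALTHY: np.array([0.9, 1.0, 1.5, 1.1]),
        Label.MCI: np.array([1.1, 1.3, 1.2, 0.9]),
        Label.AD: np.array([1.4, 1.6, 0.8, 0.7]),
    }


def strong_band_gains() -> dict[Label, np.ndarray]:
    """Exaggerated class signatures for validation studies: each class is
    dominant in a different rhythm (healthy->alpha, MCI->theta, AD->delta)."""
    return {
        Label.HEALTHY: np.array([0.5, 0.7, 2.5, 1.3]),
        Label.MCI: np.array([0.8, 2.5, 0.7, 1.1]),
        Label.AD: np.array([2.5, 0.9, 0.5, 0.7]),
    }


def _skew_generator(class_index: int, n: int) -> np.ndarray:
    """Fixed (seed-free) skew-symmetric generator, distinct per class."""
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    a = np.sin(1.7 * (class_index + 1) + 2.1 * i + 0.9 * j)
    k = a - a.T
    norm = np.linalg.norm(k)
    return k / norm if norm > 0 else k


def _mixing(angle: float, n_channels: int) -> dict[Label, np.ndarray]:
    return {
        lab: expm(angle * _skew_generator(ci, n_channels))
        for ci, lab in enumerate(_CLASS_ORDER)
    }


def default_spatial_mixing(n_channels: int = 4) -> dict[Label, np.ndarray]:
    """Mild class-specific orthogonal channel mixing (rotation angle 0.3)."""
    return _mixing(0.3, n_channels)


def strong_spatial_mixing(n_channels: int = 4) -> dict[Label, np.ndarray]:
    """Pronounced class-specific mixing for validation studies (angle 0.9)."""
    return _mixing(0.9, n_channels)


def validation_study_config(seed: int = 0) -> "SyntheticConfig":
    """Canonical scaled-down validation study: 12 subjects (4 per class),
    40 trials each, exaggerated class signatures at 20 dB SNR.

    This is the configuration the package's end-to-end recovery checks run
    on: small enough for a desktop LOSO study, strong enough that a correct
    pipeline should identify nearly every subject.
    """
    return SyntheticConfig(
        n_subjects_per_class=(4, 4, 4),
        trials_per_subject=40,
        class_band_gains=strong_band_gains(),
        class_spatial_mixing=strong_spatial_mixing(),
        snr_db=20.0,
        seed=seed,
    )


@dataclass
class SyntheticConfig:
    """Generator configuration.

    ``n_subjects_per_class`` is ordered (healthy, MCI, AD); the default
    (15, 7, 13) mirrors a 35-subject cohort, and 110 trials/subject puts the
    default trial count (3,850) near a realistically attrited 120-trial
    protocol.  ``snr_db`` is signal power over pink-noise power per trial
    (``inf`` disables noise); the default 5 dB reflects the low single-trial
    SNR of stimulus-locked EEG.  ``subject_gain_jitter`` is the s.d. of the
    per-subject log-normal jitter applied to the band gains.
    """

    n_subjects_per_class: tuple[int, int, int] = (15, 7, 13)
    trials_per_subject: int = 110
    n_channels: int = 4
    fs: float = 200.0
    epoch_samples: int = 400
    class_band_gains: Mapping[Label, np.ndarray] = field(default_factory=default_band_gains)
    class_spatial_mixing: Mapping[Label, np.ndarray] | None = None
    noise_exponent: float = 1.0
    snr_db: float = 5.0
    subject_gain_jitter: float = 0.08
    amplitude_uv: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_spatial_mixing is None:
            self.class_spatial_mixing = default_spatial_mixing(self.n_channels)
        if len(self.n_subjects_per_class) != 3 or any(
            int(c) != c or c < 1 for c in self.n_subjects_per_class
        ):
            raise ConfigurationError(
                f"n_subjects_per_class must be three positive counts, got {self.n_subjects_per_class}"
            )
        if self.trials_per_subject < 1:
            raise ConfigurationError(f"trials_per_subject must be >= 1, got {self.trials_per_subject}")
        if self.n_channels < 1:
            raise ConfigurationError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.epoch_samples < 16:
            raise ConfigurationError(f"epoch_samples must be >= 16, got {self.epoch_samples}")
        if np.isnan(self.snr_db):
            raise ConfigurationError("snr_db must not be NaN")
        for lab in _CLASS_ORDER:
            g = np.asarray(self.class_band_gains[lab], dtype=float)
            if g.shape != (len(BANDS),) or np.any(g < 0) or not np.all(np.isfinite(g)):
                raise ConfigurationError(
                    f"class_band_gains[{lab.name}] must be {len(BANDS)} nonnegative finite gains"
                )
            m = np.asarray(self.class_spatial_mixing[lab], dtype=float)
            if m.shape != (self.n_channels, self.n_channels):
                raise ConfigurationError(
                    f"class_spatial_mixing[{lab.name}] must be square "
                    f"({self.n_channels}x{self.n_channels}), got {m.shape}"
                )
            if np.linalg.matrix_rank(m) < self.n_channels:
                raise ConfigurationError(
                    f"class_spatial_mixing[{lab.name}] must have full rank"
                )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _band_masks(n_samples: int, fs: float) -> np.ndarray:
    """Raised-cosine-edged band-pass masks on the rfft grid, one per rhythm."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    masks = np.zeros((len(BANDS), len(freqs)))
    for b, (lo, hi) in enumerate(BANDS):
        width = 0.1 * (hi - lo)
        up = np.clip((freqs - (lo - width)) / (2 * width), 0.0, 1.0)
        down = np.clip(((hi + width) - freqs) / (2 * width), 0.0, 1.0)
        masks[b] = 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))
    return masks


def _pink_filter(n_samples: int, fs: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    h = np.zeros_like(freqs)
    h[1:] = freqs[1:] ** (-exponent / 2.0)
    return h


def _unit_rows(x: np.ndarray) -> np.ndarray:
    """Normalize the last axis of x to unit standard deviation."""
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-12)


def generate_synthetic_dataset(cfg: SyntheticConfig) -> EEGTrialSet:
    """Generate a fully seeded :class:`EEGTrialSet` per the configuration."""
    n_samples, fs = cfg.epoch_samples, cfg.fs
    t = np.arange(n_samples) / fs
    masks = _band_masks(n_samples, fs)
    pink = _pink_filter(n_samples, fs, cfg.noise_exponent)
    # fixed unequal per-channel base amplitudes: with class-specific rotations
    # this is what creates class-dependent spatial covariance
    chan_profile = 1.0 - 0.35 * np.arange(cfg.n_channels) / max(cfg.n_channels - 1, 1)

    total_subjects = sum(cfg.n_subjects_per_class)
    streams = np.random.SeedSequence(cfg.seed).spawn(total_subjects)
    trials: list[EEGTrial] = []
    s_idx = 0
    for count, lab in zip(cfg.n_subjects_per_class, _CLASS_ORDER):
        gains = np.asarray(cfg.class_band_gains[lab], dtype=float)
        mix = np.asarray(cfg.class_spatial_mixing[lab], dtype=float)
        for k in range(count):
            rng = np.random.default_rng(streams[s_idx])
            s_idx += 1
            subject_id = f"{lab.name.lower()}-{k + 1:02d}"
            jitter = np.exp(rng.normal(0.0, cfg.subject_gain_jitter, size=len(BANDS)))
            nt = cfg.trials_per_subject
            # band-limited carriers: (trials, channels, bands, samples)
            white = rng.standard_normal((nt, cfg.n_channels, len(BANDS), n_samples))
            spec = np.fft.rfft(white, axis=-1) * masks[None, None, :, :]
            carriers = _unit_rows(np.fft.irfft(spec, n=n_samples, axis=-1))
            # slow amplitude-modulation envelopes, strictly positive
            f_env = rng.uniform(0.3, 1.2, size=(nt, cfg.n_channels, len(BANDS), 1))
            phi = rng.uniform(0.0, 2 * np.pi, size=(nt, cfg.n_channels, len(BANDS), 1))
            env = 1.0 + 0.5 * np.sin(2 * np.pi * f_env * t[None, None, None, :] + phi)
            weights = gains * jitter  # (bands,)
            source = np.einsum(
                "ncbs,b,c->ncs", carriers * env, weights, chan_profile, optimize=True
            )
            mixed = np.einsum("ij,njs->nis", mix, source)
            if np.isfinite(cfg.snr_db):
                nz = rng.standard_normal((nt, cfg.n_channels, n_samples))
                nz = _unit_rows(np.fft.irfft(np.fft.rfft(nz, axis=-1) * pink, n=n_samples, axis=-1))
                p_sig = np.mean(mixed ** 2, axis=(1, 2), keepdims=True)
                scale = np.sqrt(p_sig / 10.0 ** (cfg.snr_db / 10.0))
                mixed = mixed + scale * nz
            mixed *= cfg.amplitude_uv
            odors = np.where(
                rng.random(nt) < _LEMON_PROBABILITY, Odor.LEMON.value, Odor.ROSE.value
            )
            for i in range(nt):
                trials.append(
                    EEGTrial(
                        data=mixed[i],
                        subject_id=subject_id,
                        label=lab,
                        odor=Odor(odors[i]),
                        fs=fs,
                    )
                )
    names = (
        list(DEFAULT_CHANNELS)
        if cfg.n_channels == len(DEFAULT_CHANNELS)
        else [f"ch{i + 1:02d}" for i in range(cfg.n_channels)]
    )
    return EEGTrialSet(trials=trials, channel_names=names)
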