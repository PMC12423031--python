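"""Transformer-fusion classifier over TQWCM images + spatial features.

Architecture
------------
A compact convolutional feature extractor turns each (channels x bands x
time) TQWCM image into one feature vector per wavelet sub-band, then a
transformer encoder fuses those sub-band tokens with one CSP token and one
covariance-tangent-space (CMTS) token, and a 3-layer linear head scores the
three diagnostic classes.

The CNN follows the depthwise/pointwise idiom of compact EEG decoders: a
depthwise time convolution (kernel 1x64, padding 1x32, one kernel per EEG
channel) followed by a 1x1 pointwise mix to 64 feature maps, then a
depthwise-separable block with a shorter 1x16 kernel raising the width to
128.  Every kernel has height 1, so the band axis is never mixed: after
global average pooling over time each band independently yields one
128-vector, which makes the extractor exactly equivariant to band
permutations.  The temporal axis is condensed by average pooling - a
configurable input decimation plus a pooling stage after each depthwise
convolution - so the costly wide pointwise mixes run at coarse time
resolution; batch normalization and ELU follow every convolution.

Tokens: three learned linear projections (CSP, CMTS, and one shared across
sub-bands) map the features to the embedding dimension; a learned
source-type embedding and a learned band-index embedding are added (no
positional encodings - feature sources are unordered, bands are indexed).
Token count is therefore ``2 + (J + 1)``.  The encoder is a standard
pre-norm transformer (2 layers, 4 heads, 4x feed-forward); its mean-pooled
output feeds the linear head (64 -> 32 -> 3, dropout 0.5 between layers).

Everything runs in numpy with explicit backpropagation (see
:mod:`olfeeg.nn`) and is exactly reproducible from the configured seeds on
CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Label
from .errors import ConfigurationError, DivergenceError, StructuralError
from .nn import (
    Adam,
    AvgPoolTime,
    BatchNormChannel,
    ChannelLinear,
    Dense,
    DepthwiseConv1d,
    Dropout,
    ELU,
    GlobalAvgPoolTime,
    Layer,
    TransformerEncoderLayer,
    LayerNorm,
    collect_layers,
    softmax,
    softmax_cross_entropy,
)
from .tqwcm import TFImage

__all__ = [
    "FusionConfig",
    "TrainParams",
    "TokenSequence",
    "FusionModel",
    "FeatureStandardizer",
    "TrainResult",
    "train_fusion_model",
    "predict_trial",
]


@dataclass(frozen=True)
class FusionConfig:
    """Model hyperparameters.  Defaults follow the reference pipeline
    (kernel 1x64 pad 1x32, widths 64/128, dropout 0.3 conv / 0.5 linear,
    4 CSP components on 4 channels)."""

    n_eeg_channels: int = 4
    n_bands: int = 10
    dw_kernel_time: int = 64
    dw_padding_time: int = 32
    pw1_channels: int = 64
    sep_kernel_time: int = 16
    sep_padding_time: int = 8
    pw2_channels: int = 128
    pre_pool_time: int = 2
    pool1_time: int = 16
    pool2_time: int = 2
    csp_dim: int = 4
    cmts_dim: int = 10
    embed_dim: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 2
    head_hidden: tuple[int, int] = (64, 32)
    n_classes: int = 3
    dropout_conv: float = 0.3
    dropout_linear: float = 0.5
    use_source_embeddings: bool = True
    use_band_embeddings: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ConfigurationError(
                f"embed_dim={self.embed_dim} must be divisible by n_heads={self.n_heads}"
            )
        for name in ("dw_kernel_time", "sep_kernel_time", "pool1_time", "pool2_time"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("dropout_conv", "dropout_linear"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")

    @property
    def n_tokens(self) -> int:
        return 2 + self.n_bands


@dataclass(frozen=True)
class TrainParams:
    """Optimization settings: 50 epochs, batch 64, Adam at 1e-3."""

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate < 0:
            raise ConfigurationError("epochs/batch_size must be positive, learning_rate >= 0")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TokenSequence:
    """Embedded fusion input: one CSP token, one CMTS token, one per band."""

    tokens: np.ndarray
    sources: list[str]

    def __post_init__(self) -> None:
        if self.tokens.ndim != 2 or len(self.sources) != self.tokens.shape[0]:
            raise StructuralError("tokens and sources are inconsistent")


class _TokenEmbeddings(Layer):
    """Learned source-type + band-index embeddings added to the token stack."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator, dtype) -> None:
        super().__init__()
        self.cfg = cfg
        self.add_param("source", (0.02 * rng.standard_normal((3, cfg.embed_dim))).astype(dtype))
        self.add_param("band", (0.02 * rng.standard_normal((cfg.n_bands, cfg.embed_dim))).astype(dtype))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cfg = self.cfg
        y = x.copy()
        if cfg.use_source_embeddings:
            src = self.params["source"]
            y[:, 0] += src[0]
            y[:, 1] += src[1]
            y[:, 2:] += src[2]
        if cfg.use_band_embeddings:
            y[:, 2:] += self.params["band"]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        if cfg.use_source_embeddings:
            self.grads["source"][0] += gy[:, 0].sum(axis=0)
            self.grads["source"][1] += gy[:, 1].sum(axis=0)
            self.grads["source"][2] += gy[:, 2:].sum(axis=(0, 1))
        if cfg.use_band_embeddings:
            self.grads["band"] += gy[:, 2:].sum(axis=0)
        return gy


class FusionModel:
    """The full classifier; weights are initialized from ``cfg.seed``."""

    def __init__(self, cfg: FusionConfig) -> None:
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        self.dropout_rng = np.random.default_rng(rng.integers(2 ** 31))
        c, k1, p1 = cfg.n_eeg_channels, cfg.dw_kernel_time, cfg.dw_padding_time
        pre: list[Layer] = [AvgPoolTime(cfg.pre_pool_time)] if cfg.pre_pool_time > 1 else []
        self.conv_stack: list[Layer] = pre + [
            DepthwiseConv1d(c, k1, p1, rng, dtype),
            BatchNormChannel(c, dtype=dtype),
            ELU(),
            AvgPoolTime(cfg.pool1_time),
            ChannelLinear(c, cfg.pw1_channels, rng, dtype),
            BatchNormChannel(cfg.pw1_channels, dtype=dtype),
            ELU(),
            Dropout(cfg.dropout_conv, self.dropout_rng),
            DepthwiseConv1d(cfg.pw1_channels, cfg.sep_kernel_time, cfg.sep_padding_time, rng, dtype),
            BatchNormChannel(cfg.pw1_channels, dtype=dtype),
            ELU(),
            AvgPoolTime(cfg.pool2_time),
            ChannelLinear(cfg.pw1_channels, cfg.pw2_channels, rng, dtype),
            BatchNormChannel(cfg.pw2_channels, dtype=dtype),
            ELU(),
            Dropout(cfg.dropout_conv, self.dropout_rng),
            GlobalAvgPoolTime(),
        ]
        d = cfg.embed_dim
        self.proj_csp = Dense(cfg.csp_dim, d, rng, dtype)
        self.proj_cmts = Dense(cfg.cmts_dim, d, rng, dtype)
        self.proj_band = Dense(cfg.pw2_channels, d, rng, dtype)
        self.embeddings = _TokenEmbeddings(cfg, rng, dtype)
        self.encoder = [
            TransformerEncoderLayer(d, cfg.n_heads, rng, dropout=0.0,
                                    dropout_rng=self.dropout_rng, dtype=dtype)
            for _ in range(cfg.n_encoder_layers)
        ]
        self.final_norm = LayerNorm(d, dtype=dtype)
        h1, h2 = cfg.head_hidden
        self.head: list[Layer] = [
            Dense(d, h1, rng, dtype),
            ELU(),
            Dropout(cfg.dropout_linear, self.dropout_rng),
            Dense(h1, h2, rng, dtype),
            ELU(),
            Dropout(cfg.dropout_linear, self.dropout_rng),
            Dense(h2, cfg.n_classes, rng, dtype),
        ]

    # -- layer bookkeeping -------------------------------------------------
    @property
    def all_layers(self) -> list[Layer]:
        return collect_layers(
            self.conv_stack
            + [self.proj_csp, self.proj_cmts, self.proj_band, self.embeddings]
            + self.encoder
            + [self.final_norm]
            + self.head
        )

    def get_weights(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, lay in enumerate(self.all_layers):
            for k, v in lay.params.items():
                out[f"{i}.{k}"] = v.copy()
            if isinstance(lay, BatchNormChannel):
                out[f"{i}.running_mean"] = lay.running_mean.copy()
                out[f"{i}.running_var"] = lay.running_var.copy()
        return out

    def set_weights(self, state: dict[str, np.ndarray]) -> None:
        for i, lay in enumerate(self.all_layers):
            for k in lay.params:
                lay.params[k][...] = state[f"{i}.{k}"]
            if isinstance(lay, BatchNormChannel):
                lay.running_mean = state[f"{i}.running_mean"].copy()
                lay.running_var = state[f"{i}.running_var"].copy()

    # -- forward / backward ------------------------------------------------
    def _check_image_shape(self, images: np.ndarray) -> None:
        cfg = self.cfg
        if images.shape[1] != cfg.n_eeg_channels or images.shape[2] != cfg.n_bands:
            raise StructuralError(
                f"expected images (*, {cfg.n_eeg_channels}, {cfg.n_bands}, T), "
                f"got {images.shape}"
            )

    def _conv_forward(self, images: np.ndarray, training: bool) -> np.ndarray:
        """(B, C, M, T) -> per-band features (B, M, pw2_channels).

        Bands are folded into the batch axis: every kernel has height 1, so
        this is exactly the 2-D network with (1, k) kernels, and band
        equivariance holds by construction.
        """
        b, c, m, t = images.shape
        x = images.transpose(0, 2, 1, 3).reshape(b * m, c, t).astype(self.dtype)
        for lay in self.conv_stack:
            x = lay.forward(x, training)
        return x.reshape(b, m, -1)

    def _conv_backward(self, g_band: np.ndarray) -> None:
        b, m, f = g_band.shape
        g = g_band.reshape(b * m, f)
        for lay in reversed(self.conv_stack):
            g = lay.backward(g)

    def forward(self, images: np.ndarray, csp: np.ndarray, cmts: np.ndarray,
                training: bool = False) -> np.ndarray:
        self._check_image_shape(images)
        b = images.shape[0]
        band_feats = self._conv_forward(images, training)
        t_csp = self.proj_csp.forward(csp.astype(self.dtype), training)
        t_cmts = self.proj_cmts.forward(cmts.astype(self.dtype), training)
        t_band = self.proj_band.forward(band_feats, training)
        tokens = np.concatenate([t_csp[:, None], t_cmts[:, None], t_band], axis=1)
        tokens = self.embeddings.forward(tokens, training)
        for lay in self.encoder:
            tokens = lay.forward(tokens, training)
        tokens = self.final_norm.forward(tokens, training)
        pooled = tokens.mean(axis=1)
        self._n_tokens = tokens.shape[1]
        x = pooled
        for lay in self.head:
            x = lay.forward(x, training)
        return x

    def backward(self, g_logits: np.ndarray) -> None:
        g = g_logits.astype(self.dtype)
        for lay in reversed(self.head):
            g = lay.backward(g)
        g_tokens = np.repeat(g[:, None, :], self._n_tokens, axis=1) / self._n_tokens
        g_tokens = self.final_norm.backward(g_tokens)
        for lay in reversed(self.encoder):
            g_tokens = lay.backward(g_tokens)
        g_tokens = self.embeddings.backward(g_tokens)
        self.proj_csp.backward(g_tokens[:, 0])
        self.proj_cmts.backward(g_tokens[:, 1])
        g_band = self.proj_band.backward(g_tokens[:, 2:])
        self._conv_backward(g_band)

    # -- public inference pieces ------------------------------------------
    def cnn_extract(self, img: "TFImage | np.ndarray") -> np.ndarray:
        """Per-band CNN features of one image: (n_bands, pw2_channels)."""
        pixels = img.pixels if isinstance(img, TFImage) else np.asarray(img)
        single = pixels.ndim == 3
        batch = pixels[None] if single else pixels
        self._check_image_shape(batch)
        feats = self._conv_forward(batch, training=False)
        return feats[0] if single else feats

    def tokenize(self, csp_vec: np.ndarray, cmts_vec: np.ndarray,
                 band_feats: np.ndarray) -> TokenSequence:
        """Project one sample's features into the 2 + n_bands token stack."""
        cfg = self.cfg
        if csp_vec.shape != (cfg.csp_dim,) or cmts_vec.shape != (cfg.cmts_dim,):
            raise StructuralError(
                f"expected csp ({cfg.csp_dim},) and cmts ({cfg.cmts_dim},), "
                f"got {csp_vec.shape} and {cmts_vec.shape}"
            )
        if band_feats.shape != (cfg.n_bands, cfg.pw2_channels):
            raise StructuralError(
                f"expected band features ({cfg.n_bands}, {cfg.pw2_channels}), "
                f"got {band_feats.shape}"
            )
        t_csp = self.proj_csp.forward(csp_vec[None].astype(self.dtype))
        t_cmts = self.proj_cmts.forward(cmts_vec[None].astype(self.dtype))
        t_band = self.proj_band.forward(band_feats[None].astype(self.dtype))
        tokens = np.concatenate([t_csp[:, None], t_cmts[:, None], t_band], axis=1)
        tokens = self.embeddings.forward(tokens)
        sources = ["CSP", "CMTS"] + [f"subband_{j + 1}" for j in range(cfg.n_bands)]
        return TokenSequence(tokens=tokens[0], sources=sources)

    def encode_and_classify(self, seq: TokenSequence) -> np.ndarray:
        """Transformer encoder + head on one token sequence -> 3 logits."""
        x = seq.tokens[None].astype(self.dtype)
        for lay in self.encoder:
            x = lay.forward(x)
        x = self.final_norm.forward(x).mean(axis=1)
        for lay in self.head:
            x = lay.forward(x)
        return x[0]

    def predict_proba(self, images: np.ndarray, csp: np.ndarray,
                      cmts: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, images.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            out.append(softmax(self.forward(images[sl], csp[sl], cmts[sl], training=False)))
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray, csp: np.ndarray, cmts: np.ndarray) -> np.ndarray:
        # argmax takes the lowest index on exact ties; AD is index 0, which
        # implements the protocol's tie-toward-AD rule
        return np.argmax(self.predict_proba(images, csp, cmts), axis=1)


class FeatureStandardizer:
    """Train-statistics z-scoring for images (per EEG channel) and the CSP /
    CMTS vectors (per feature).  Fit on training folds only."""

    def __init__(self, standardize_images: bool = True) -> None:
        self.standardize_images = standardize_images
        self.fitted = False

    def fit(self, images: np.ndarray, csp: np.ndarray, cmts: np.ndarray,
            trial_ids: list[int] | None = None) -> "FeatureStandardizer":
        self.img_mean = images.mean(axis=(0, 2, 3), keepdims=True)
        self.img_std = np.maximum(images.std(axis=(0, 2, 3), keepdims=True), 1e-12)
        self.csp_mean, self.csp_std = csp.mean(0), np.maximum(csp.std(0), 1e-12)
        self.cmts_mean, self.cmts_std = cmts.mean(0), np.maximum(cmts.std(0), 1e-12)
        self.fit_trial_ids = list(trial_ids) if trial_ids is not None else None
        self.fitted = True
        return self

    def transform(self, images: np.ndarray, csp: np.ndarray,
                  cmts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.fitted:
            raise StructuralError("standardizer is not fitted")
        img = (images - self.img_mean) / self.img_std if self.standardize_images else images
        return (
            img,
            (csp - self.csp_mean) / self.csp_std,
            (cmts - self.cmts_mean) / self.cmts_std,
        )


@dataclass
class TrainResult:
    """Per-epoch mean training loss, plus optional per-epoch eval scores."""

    loss_history: list[float]
    eval_history: list[float] = field(default_factory=list)


def train_fusion_model(
    model: FusionModel,
    images: np.ndarray,
    csp: np.ndarray,
    cmts: np.ndarray,
    labels: np.ndarray,
    tp: TrainParams,
    eval_fn=None,
) -> TrainResult:
    """Minimize unweighted cross-entropy with Adam; fully seeded.

    ``eval_fn(model)`` - if given - is called after every epoch (e.g. held-out
    subject accuracy) and its values collected in ``eval_history``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise StructuralError("empty training set")
    n = labels.size
    images = images.astype(model.dtype, copy=False)
    csp = csp.astype(model.dtype, copy=False)
    cmts = cmts.astype(model.dtype, copy=False)
    rng = np.random.default_rng(tp.seed)
    opt = Adam(model.all_layers, lr=tp.learning_rate)
    losses: list[float] = []
    evals: list[float] = []
    for epoch in range(tp.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, tp.batch_size):
            idx = perm[start:start + tp.batch_size]
            logits = model.forward(images[idx], csp[idx], cmts[idx], training=True)
            loss, grad = softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            total += loss * len(idx)
        losses.append(total / n)
        if eval_fn is not None:
            evals.append(float(eval_fn(model)))
    return TrainResult(loss_history=losses, eval_history=evals)


def predict_trial(model: FusionModel, trial_features: dict) -> tuple[Label, np.ndarray]:
    """Classify one trial from its feature dict {'image', 'csp', 'cmts'}.

    Exact probability ties resolve toward AD (lowest class index).
    """
    for key in ("image", "csp", "cmts"):
        if key not in trial_features:
            raise StructuralError(f"missing feature source {key!r}")
    img = trial_features["image"]
    pixels = img.pixels if isinstance(img, TFImage) else np.asarray(img)
    probs = model.predict_proba(
        pixels[None], trial_features["csp"][None], trial_features["cmts"][None]
    )[0]
    return Label(int(np.argmax(probs))), probs
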