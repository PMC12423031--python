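"""Adam optimizer over the layer parameter dictionaries."""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Adam", "collect_layers"]


def collect_layers(root) -> list[Layer]:
    """Flatten a layer tree: any object with ``params`` counts; children are
    discovered through a ``sub`` attribute."""
    out: list[Layer] = []

    def walk(obj) -> None:
        if isinstance(obj, Layer):
            out.append(obj)
        for child in getattr(obj, "sub", []):
            walk(child)

    if isinstance(root, (list, tuple)):
        for item in root:
            walk(item)
    else:
        walk(root)
    return out


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = layers
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def zero_grad(self) -> None:
        for lay in self.layers:
            lay.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= (self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)).astype(p.dtype)
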