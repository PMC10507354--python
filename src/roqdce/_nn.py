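"""Shared MLP building blocks for the two networks."""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = ["MLP", "lr_at_epoch"]


class MLP:
    """Fully connected ReLU network with He-initialized weights."""

    def __init__(self, sizes: tuple[int, ...], rng: np.random.Generator):
        self.sizes = tuple(sizes)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(fan_out), requires_grad=True))

    @property
    def params(self) -> list[Tensor]:
        return self.weights + self.biases

    def forward(self, x: Tensor) -> Tensor:
        """Linear output layer; ReLU on hidden layers."""
        n = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ w + b
            if i < n - 1:
                x = x.relu()
        return x

    def freeze(self) -> None:
        for p in self.params:
            p.requires_grad = False

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w.data
            out[f"b{i}"] = b.data
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            w.data = np.asarray(state[f"w{i}"], dtype=float)
            b.data = np.asarray(state[f"b{i}"], dtype=float)


def lr_at_epoch(epoch: int, lr0: float, warmup_epochs: int, decay_factor: float) -> float:
    """Learning rate for 1-based ``epoch``: constant for the warmup
    epochs, then multiplied by ``decay_factor`` each subsequent epoch."""
    if epoch <= warmup_epochs:
        return lr0
    return lr0 * decay_factor ** (epoch - warmup_epochs)
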