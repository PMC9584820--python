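"""Small neural-network building blocks and optimizers.

Parameters live in flat ``{name: Tensor}`` dicts so checkpoints serialize to
plain JSON and optimizers can treat every model uniformly.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, sigmoid, tanh

__all__ = ["glorot", "linear_params", "lstm_params", "lstm_step", "Adam", "RMSProp"]


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization for a dense weight matrix."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def linear_params(rng: np.random.Generator, n_in: int, n_out: int, prefix: str,
                  scale: float = 1.0) -> dict[str, Tensor]:
    return {
        f"{prefix}_w": Tensor(glorot(rng, n_in, n_out) * scale, requires_grad=True),
        f"{prefix}_b": Tensor(np.zeros(n_out), requires_grad=True),
    }


def lstm_params(rng: np.random.Generator, n_in: int, n_hidden: int,
                prefix: str = "lstm") -> dict[str, Tensor]:
    """Standard LSTM cell parameters; gate order i, f, g, o; forget bias 1."""
    b = np.zeros(4 * n_hidden)
    b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
    return {
        f"{prefix}_wx": Tensor(glorot(rng, n_in, 4 * n_hidden), requires_grad=True),
        f"{prefix}_wh": Tensor(glorot(rng, n_hidden, 4 * n_hidden), requires_grad=True),
        f"{prefix}_b": Tensor(b, requires_grad=True),
    }


def lstm_step(params: dict[str, Tensor], x: Tensor, h: Tensor, c: Tensor,
              prefix: str = "lstm") -> tuple[Tensor, Tensor]:
    """One LSTM step; ``x`` is [B, n_in], ``h``/``c`` are [B, n_hidden]."""
    n_hidden = params[f"{prefix}_wh"].shape[0]
    gates = x @ params[f"{prefix}_wx"] + h @ params[f"{prefix}_wh"] + params[f"{prefix}_b"]
    i = sigmoid(gates[:, 0 * n_hidden:1 * n_hidden])
    f = sigmoid(gates[:, 1 * n_hidden:2 * n_hidden])
    g = tanh(gates[:, 2 * n_hidden:3 * n_hidden])
    o = sigmoid(gates[:, 3 * n_hidden:4 * n_hidden])
    c_new = f * c + i * g
    h_new = o * tanh(c_new)
    return h_new, c_new


class _Optimizer:
    def __init__(self, params: dict[str, Tensor]):
        self.params = params

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class Adam(_Optimizer):
    """Adam with bias correction (defaults match the imitation trainer)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 4e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class RMSProp(_Optimizer):
    """RMSProp without momentum (defaults match the designer trainer)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 4e-4,
                 decay: float = 0.99, eps: float = 1e-5):
        super().__init__(params)
        self.lr, self.decay, self.eps = lr, decay, eps
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.v[k] = self.decay * self.v[k] + (1 - self.decay) * p.grad**2
            p.data -= self.lr * p.grad / np.sqrt(self.v[k] + self.eps)
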