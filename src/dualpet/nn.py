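"""Neural-network building blocks: dense, LSTM, normalization, dropout, Adam.

Layers follow the conventions of the classifier this package implements:
every fully connected layer is followed by the standard block
(batch normalization, ReLU, dropout), every LSTM layer by layer
normalization. Parameters are float64; initialization is Glorot-uniform
driven by a `numpy.random.Generator` so runs are reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "Parameter",
    "Module",
    "Dense",
    "BatchNorm",
    "LayerNorm",
    "Dropout",
    "LSTM",
    "Adam",
    "glorot_uniform",
]


class Parameter(Tensor):
    """A trainable tensor. ``kernel=True`` marks weights subject to L2 decay
    (dense/LSTM kernels, not biases or normalization scales)."""

    __slots__ = ("kernel",)

    def __init__(self, data, kernel: bool = False):
        super().__init__(data, requires_grad=True)
        self.kernel = kernel


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = False
        self._modules: list[Module] = []
        self._params: list[Parameter] = []

    def add_module(self, m: "Module") -> "Module":
        self._modules.append(m)
        return m

    def add_param(self, p: Parameter) -> Parameter:
        self._params.append(p)
        return p

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules:
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # checkpoint support: flat list of arrays in parameter order
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()] + [
            b.copy() for b in self._buffers_recursive()
        ]

    def load_state_arrays(self, arrays: list) -> None:
        params = self.parameters()
        bufs = self._buffers_recursive()
        if len(arrays) != len(params) + len(bufs):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays[: len(params)]):
            p.data[...] = np.asarray(a, dtype=np.float64)
        for i, a in enumerate(arrays[len(params):]):
            bufs[i][...] = np.asarray(a, dtype=np.float64)

    def _buffers_recursive(self) -> list[np.ndarray]:
        out = list(getattr(self, "_buffers", []))
        for m in self._modules:
            out.extend(m._buffers_recursive())
        return out


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = self.add_param(
            Parameter(glorot_uniform(rng, n_in, n_out, (n_in, n_out)), kernel=True)
        )
        self.b = self.add_param(Parameter(np.zeros(n_out)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class BatchNorm(Module):
    """Batch normalization over the batch axis of (B, F) inputs.

    Training uses batch statistics and updates exponential running estimates;
    inference uses the running estimates, making prediction independent of
    batch composition.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param(Parameter(np.ones(n_features)))
        self.beta = self.add_param(Parameter(np.zeros(n_features)))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self._buffers = [self.running_mean, self.running_var]
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    """Normalize each sample over its feature axis (last axis)."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param(Parameter(np.ones(n_features)))
        self.beta = self.add_param(Parameter(np.zeros(n_features)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class LSTM(Module):
    """A single LSTM layer processing (B, T, F) sequences.

    Gate order in the fused kernel is input, forget, cell, output. Returns the
    full hidden-state sequence as a list of (B, H) tensors so a caller can take
    the last time step or stack further layers.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_hidden = n_hidden
        self.Wx = self.add_param(
            Parameter(glorot_uniform(rng, n_in, n_hidden, (n_in, 4 * n_hidden)), kernel=True)
        )
        self.Wh = self.add_param(
            Parameter(glorot_uniform(rng, n_hidden, n_hidden, (n_hidden, 4 * n_hidden)), kernel=True)
        )
        # forget-gate bias of 1: standard trick for gradient flow at init
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0
        self.b = self.add_param(Parameter(b))

    def __call__(self, steps: list[Tensor]) -> list[Tensor]:
        B = steps[0].shape[0]
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outputs = []
        for x_t in steps:
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = z[:, 0:H].sigmoid()
            f = z[:, H : 2 * H].sigmoid()
            g = z[:, 2 * H : 3 * H].tanh()
            o = z[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h)
        return outputs


class Adam:
    """Adam optimizer with optional decoupled gradient clipping left out:
    the networks here are tiny and full-batch gradients are well scaled."""

    def __init__(self, params: list[Parameter], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sequence_from_array(x: np.ndarray) -> list[Tensor]:
    """Split a (B, T, F) array into per-time-step (B, F) tensors."""
    return [Tensor(x[:, t, :]) for t in range(x.shape[1])]
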