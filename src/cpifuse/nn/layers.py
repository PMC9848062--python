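"""Neural-net building blocks on top of the autograd tensor.

Initialization follows the Glorot-uniform convention; every layer takes the
``numpy.random.Generator`` that seeds it, so a model built twice from the same
seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from cpifuse.nn.autograd import Tensor, concat, sliding_windows


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: recursive named-parameter discovery and train/eval state."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) - set(state)
            extra = set(state) - set(own)
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} "
                    f"vs model {p.data.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine projection f(x) = x W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Parameter(glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class MLP(Module):
    """Stack of Linear layers with ReLU between (none after the last)."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 final_relu: bool = False):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [
            Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.final_relu = final_relu

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_relu:
                x = x.relu()
        return x


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def forward(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        flat = self.weight[ids.reshape(-1)]
        return flat.reshape(ids.shape + (self.weight.shape[1],))


class Conv1d(Module):
    """Same-padded 1-D convolution over (batch, length, channels) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.c_in = c_in
        self.W = Parameter(glorot(rng, kernel * c_in, c_out))
        self.b = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.c_in:
            raise ValueError(
                f"Conv1d expected {self.c_in} channels, got {x.shape[-1]}"
            )
        win = sliding_windows(x, self.kernel, pad=self.kernel // 2)
        return win @ self.W + self.b


class LayerNorm(Module):
    """Normalization over the last axis with learned gain and bias."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** (-0.5)
        return centered * inv * self.gamma + self.beta


def glu(x: Tensor) -> Tensor:
    """Gated linear unit: split channels in half, a * sigmoid(b)."""
    c = x.shape[-1]
    if c % 2 != 0:
        raise ValueError(f"GLU needs an even channel count, got {c}")
    h = c // 2
    idx_a = tuple([slice(None)] * (x.ndim - 1) + [slice(0, h)])
    idx_b = tuple([slice(None)] * (x.ndim - 1) + [slice(h, c)])
    return x[idx_a] * x[idx_b].sigmoid()
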