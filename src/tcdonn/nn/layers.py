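"""Neural-network modules built on the autograd engine.

The inventory is exactly what the residual Self-ONN classifiers need:
`SelfONNConv1d` (operational convolution with Taylor order Q), `BatchNorm1d`,
`Tanh`, `Linear`, `GlobalAvgPool1d`, `LogSoftmax` and `MultiheadAttention1d`.
Modules follow the familiar pattern: parameters are discovered by attribute
traversal, `train()`/`eval()` toggles batch-norm statistics.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, batch_norm_train, conv1d, taylor_expand


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, mode switching, weight (de)serialization."""

    def __init__(self):
        self.training = True

    def modules(self):
        for _, m in self.named_modules():
            yield m

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_modules(f"{path}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{path}.{i}.")

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{path}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for path, m in self.named_modules():
            if isinstance(m, BatchNorm1d):
                state[f"{path}.running_mean"] = m.running_mean.copy()
                state[f"{path}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        from .autograd import default_dtype
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=default_dtype())
        for path, m in self.named_modules():
            if isinstance(m, BatchNorm1d):
                m.running_mean = np.array(state[f"{path}.running_mean"])
                m.running_var = np.array(state[f"{path}.running_var"])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class SelfONNConv1d(Module):
    """1D operational convolution layer with generative neurons.

    Each output position sums, over input channels i, kernel taps r and Taylor
    powers q = 1..Q, the term  w[k,i,r,q] * x[i, m*stride + r - padding]^q.
    With Q = 1 this is a plain convolution.  Weights are drawn uniformly with
    scale 1/sqrt(in_channels * K * Q); bias starts at zero.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 Q: int = 1, stride: int = 1, padding: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if Q < 1 or kernel_size < 1 or stride < 1:
            raise ValueError("Q, kernel_size and stride must be >= 1")
        if padding is None:
            padding = kernel_size // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.Q = Q
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng()
        scale = 1.0 / math.sqrt(in_channels * kernel_size * Q)
        self.weight = Parameter(rng.uniform(
            -scale, scale, size=(out_channels, in_channels, kernel_size, Q)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        xq = taylor_expand(x, self.Q) if self.Q > 1 else x
        O, I, K, Q = self.weight.shape
        # (O, I, K, Q) -> (O, I*Q, K) matching the channel-major power layout
        w = self.weight.transpose(0, 1, 3, 2).reshape(O, I * Q, K)
        return conv1d(xq, w, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm1d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mean, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        mean = Tensor(self.running_mean.reshape(1, -1, 1))
        std = Tensor(np.sqrt(self.running_var + self.eps).reshape(1, -1, 1))
        xhat = (x - mean) / std
        g = self.gamma.reshape(1, self.channels, 1)
        b = self.beta.reshape(1, self.channels, 1)
        return xhat * g + b


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-scale, scale,
                                            size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GlobalAvgPool1d(Module):
    """Average over the time axis: (B, C, L) -> (B, C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=2)


class LogSoftmax(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.log_softmax()


class MultiheadAttention1d(Module):
    """Scaled dot-product attention over time positions of a (B, C, T) map.

    Time positions act as tokens and the C channels as the embedding.  The
    block's identity features supply the query and the value; the residual
    block output supplies the key.  A learned output projection mixes the
    heads back to C channels.
    """

    def __init__(self, channels: int, heads: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % heads != 0:
            raise ValueError(f"{channels} channels not divisible by {heads} heads")
        self.channels = channels
        self.heads = heads
        self.head_dim = channels // heads
        rng = rng or np.random.default_rng()
        scale = 1.0 / math.sqrt(channels)

        def proj():
            return Parameter(rng.uniform(-scale, scale, size=(channels, channels)))

        self.w_query, self.w_key, self.w_value, self.w_out = (
            proj(), proj(), proj(), proj())

    def _split_heads(self, t: Tensor, B: int, T: int) -> Tensor:
        # (B, T, C) -> (B, H, T, C/H)
        return t.reshape(B, T, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, identity: Tensor, block_output: Tensor) -> Tensor:
        if identity.shape != block_output.shape:
            raise ValueError("identity and block output shapes differ: "
                             f"{identity.shape} vs {block_output.shape}")
        B, C, T = identity.shape
        tok_q = identity.transpose(0, 2, 1)       # (B, T, C) tokens
        tok_k = block_output.transpose(0, 2, 1)
        # 1/sqrt(d) scaling folded into the (small) query tokens, not the
        # (T x T) score matrix
        q = self._split_heads((tok_q @ self.w_query) * (1.0 / math.sqrt(self.head_dim)), B, T)
        k = self._split_heads(tok_k @ self.w_key, B, T)
        v = self._split_heads(tok_q @ self.w_value, B, T)
        scores = q @ k.transpose(0, 1, 3, 2)
        attn = scores.softmax()                   # rows sum to 1 per query
        mixed = attn @ v                          # (B, H, T, C/H)
        merged = mixed.transpose(0, 2, 1, 3).reshape(B, T, C)
        out = merged @ self.w_out
        return out.transpose(0, 2, 1)             # back to (B, C, T)
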