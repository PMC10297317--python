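"""Core math of the 1D Self-ONN operational convolution.

A *generative neuron* replaces the linear kernel of a convolutional neuron
with a K x Q kernel: tap r of input channel i contributes
``sum_q w[k, i, r, q] * y_i[m*stride + r - padding]**q`` to output channel k
at position m — a truncated Taylor series whose coefficients are learned, so
the neuron learns its own nonlinearity.  Q = 1 recovers the standard
convolution (correlation convention, zero padding).

This module exposes the array-level operation (`selfonn_conv1d`), a naive
nested-loop oracle used to validate it (`reference_selfonn_oracle`),
initialization, and HDF5 round-tripping of kernels.  The trainable layer
lives in :mod:`tcdonn.nn.layers`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "SelfONNLayerSpec", "GenerativeNeuronKernel", "taylor_feature_powers",
    "selfonn_conv1d", "reference_selfonn_oracle", "init_kernel",
    "output_length", "kernel_to_hdf5", "kernel_from_hdf5",
]


@dataclass(frozen=True)
class SelfONNLayerSpec:
    """Shape/hyperparameter contract of one operational layer."""

    in_channels: int
    out_channels: int
    kernel_size: int
    taylor_order: int
    stride: int = 1
    padding: int = 0
    has_bias: bool = True

    def __post_init__(self):
        if min(self.in_channels, self.out_channels, self.kernel_size,
               self.taylor_order, self.stride) < 1:
            raise ValueError("channels, kernel_size, taylor_order and stride "
                             "must be positive")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")


@dataclass
class GenerativeNeuronKernel:
    """Weights of one operational layer: (out, in, tap, power) plus bias.

    The power axis is 1-based in the math (q = 1..Q) and 0-based in the array
    (index q-1).
    """

    weights: np.ndarray  # (out_channels, in_channels, K, Q)
    bias: np.ndarray     # (out_channels,)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.ndim != 4:
            raise ValueError("weights must be 4D (out, in, tap, power)")
        if self.bias.shape != (self.weights.shape[0],):
            raise ValueError("bias length must equal out_channels")
        if not (np.isfinite(self.weights).all() and np.isfinite(self.bias).all()):
            raise ValueError("kernel entries must be finite")

    def matches(self, spec: SelfONNLayerSpec) -> bool:
        return self.weights.shape == (spec.out_channels, spec.in_channels,
                                      spec.kernel_size, spec.taylor_order)


def output_length(L_in: int, spec: SelfONNLayerSpec) -> int:
    return (L_in + 2 * spec.padding - spec.kernel_size) // spec.stride + 1


def taylor_feature_powers(x: np.ndarray, Q: int) -> np.ndarray:
    """Stack elementwise powers x, x**2, ..., x**Q along a new leading axis.

    Slice q-1 of the output equals x**q; slice 0 is x itself.
    """
    if int(Q) != Q or Q < 1:
        raise ValueError("Taylor order Q must be a positive integer")
    x = np.asarray(x, dtype=np.float64)
    out = np.empty((Q,) + x.shape)
    out[0] = x
    for q in range(1, Q):
        out[q] = out[q - 1] * x
    return out


def _check_input(x: np.ndarray, spec: SelfONNLayerSpec) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:  # (channel, time) convenience
        x = x[None]
    if x.ndim != 3:
        raise ValueError("input must be (batch, channel, time)")
    if x.shape[1] != spec.in_channels:
        raise ValueError(f"input has {x.shape[1]} channels, spec expects "
                         f"{spec.in_channels}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in layer input")
    if output_length(x.shape[2], spec) < 1:
        raise ValueError("input (plus padding) shorter than kernel")
    return x


def selfonn_conv1d(x: np.ndarray, kernel: GenerativeNeuronKernel,
                   spec: SelfONNLayerSpec) -> np.ndarray:
    """Vectorized operational convolution of a (batch, channel, time) array.

    out[b, k, m] = bias[k]
                 + sum_{i, r, q} w[k, i, r, q] * xpad[b, i, m*stride + r]**q
    """
    x = _check_input(x, spec)
    if not kernel.matches(spec):
        raise ValueError("kernel shape does not match layer spec")
    B, C, L = x.shape
    K, Q = spec.kernel_size, spec.taylor_order
    xp = np.pad(x, ((0, 0), (0, 0), (spec.padding, spec.padding)))
    powers = taylor_feature_powers(xp, Q)           # (Q, B, C, Lp)
    xq = powers.transpose(1, 2, 0, 3).reshape(B, C * Q, xp.shape[2])
    win = np.lib.stride_tricks.sliding_window_view(xq, K, axis=2)[:, :, ::spec.stride]
    L_out = win.shape[2]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, L_out, C * Q * K)
    # weights (O, C, K, Q) -> (O, C, Q, K) to match the channel-major powers
    wmat = kernel.weights.transpose(0, 1, 3, 2).reshape(spec.out_channels, C * Q * K)
    out = cols @ wmat.T
    if spec.has_bias:
        out += kernel.bias
    return np.ascontiguousarray(out.transpose(0, 2, 1))


def reference_selfonn_oracle(x: np.ndarray, kernel: GenerativeNeuronKernel,
                             spec: SelfONNLayerSpec) -> np.ndarray:
    """Naive quintuple-loop evaluation of the operational convolution.

    Deliberately scalar — no vectorized shortcuts — so it can serve as an
    independent check of `selfonn_conv1d` and of the trainable layer.
    """
    x = _check_input(x, spec)
    if not kernel.matches(spec):
        raise ValueError("kernel shape does not match layer spec")
    B, C, L = x.shape
    K, Q, s, p = (spec.kernel_size, spec.taylor_order, spec.stride, spec.padding)
    L_out = output_length(L, spec)
    out = np.zeros((B, spec.out_channels, L_out))
    for b in range(B):
        for k in range(spec.out_channels):
            for m in range(L_out):
                acc = kernel.bias[k] if spec.has_bias else 0.0
                for i in range(C):
                    for r in range(K):
                        t = m * s + r - p
                        if t < 0 or t >= L:
                            continue  # zero padding contributes nothing
                        y = x[b, i, t]
                        for q in range(1, Q + 1):
                            acc += kernel.weights[k, i, r, q - 1] * y ** q
                out[b, k, m] = acc
    return out


def init_kernel(spec: SelfONNLayerSpec, seed: int) -> GenerativeNeuronKernel:
    """Fan-in-scaled uniform initialization, deterministic in `seed`.

    Weights ~ U(-s, s) with s = 1/sqrt(in_channels * K * Q); bias zero.  The
    Q in the fan-in keeps the summed Taylor terms at the same magnitude as a
    plain convolution's response for inputs in [-1, 1].
    """
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(spec.in_channels * spec.kernel_size * spec.taylor_order)
    weights = rng.uniform(-scale, scale, size=(spec.out_channels, spec.in_channels,
                                               spec.kernel_size, spec.taylor_order))
    return GenerativeNeuronKernel(weights, np.zeros(spec.out_channels))


_DIM_LABELS = ("out_channel", "in_channel", "tap", "power")


def kernel_to_hdf5(kernel: GenerativeNeuronKernel, path, group: str = "kernel"):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        d = g.create_dataset("weights", data=kernel.weights)
        for ax, label in enumerate(_DIM_LABELS):
            d.dims[ax].label = label
        g.create_dataset("bias", data=kernel.bias)


def kernel_from_hdf5(path, group: str = "kernel") -> GenerativeNeuronKernel:
    with h5py.File(path, "r") as f:
        g = f[group]
        return GenerativeNeuronKernel(g["weights"][()], g["bias"][()])
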