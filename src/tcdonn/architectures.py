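"""Residual Self-ONN classifiers for 1024-sample CBFV segments.

Self-ResNet18 is the classic 18-weighted-layer residual topology with every
convolution replaced by an operational (Taylor-series) layer and ReLU
replaced by tanh: a strided stem (8 filters), four stages of two residual
blocks with channel widths 8/16/32/64, global average pooling and a linear
2-class head finished by log-softmax.  The first block of stages 2-4
downsamples by stride 2 through a 1-tap operational shortcut projection that
carries no batch normalization.

Self-ResAttentioNet18 adds one multi-head attention layer (2 heads) to the
second, non-strided block of each stage: the block's input tokens act as
query and value, the block's output as key, and the attended feature is added
to the block output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .nn import (BatchNorm1d, GlobalAvgPool1d, Linear, LogSoftmax, Module,
                 MultiheadAttention1d, SelfONNConv1d, Tanh, Tensor)

__all__ = ["ArchitectureSpec", "NetworkSummary", "ResidualBlock",
           "SelfResNet", "build_self_resnet18", "build_self_resattentionet18",
           "attention_block_forward", "summarize_network",
           "save_network_hdf5", "load_network_hdf5"]


@dataclass(frozen=True)
class ArchitectureSpec:
    taylor_order: int = 3
    stem_channels: int = 8
    stage_channels: tuple[int, ...] = (8, 16, 32, 64)
    blocks_per_stage: int = 2
    n_classes: int = 2
    attention_enabled: bool = False
    attention_heads: int = 2
    input_length: int = 1024

    def __post_init__(self):
        if self.taylor_order < 1 or self.n_classes < 1 or self.blocks_per_stage < 1:
            raise ValueError("taylor_order, n_classes, blocks_per_stage must be >= 1")
        if self.stage_channels[0] != self.stem_channels or any(
                b != 2 * a for a, b in zip(self.stage_channels,
                                           self.stage_channels[1:])):
            raise ValueError("stage channels must start at stem_channels and "
                             "double at each stage")
        if self.attention_enabled and any(c % self.attention_heads
                                          for c in self.stage_channels):
            raise ValueError("stage channels must be divisible by attention_heads")


@dataclass
class NetworkSummary:
    n_selfonn_layers_main_path: int
    n_shortcut_projections: int
    n_attention_layers: int
    n_weighted_layers_main_path: int
    n_operational_kernel_weights: int
    total_parameters: int


class ResidualBlock(Module):
    """conv-BN-tanh-conv-BN, shortcut add, tanh; optional attention branch."""

    def __init__(self, in_ch: int, out_ch: int, Q: int, stride: int,
                 heads: int | None, rng: np.random.Generator):
        super().__init__()
        self.conv1 = SelfONNConv1d(in_ch, out_ch, 3, Q=Q, stride=stride,
                                   padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm1d(out_ch)
        self.conv2 = SelfONNConv1d(out_ch, out_ch, 3, Q=Q, stride=1,
                                   padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm1d(out_ch)
        self.act = Tanh()
        if stride != 1 or in_ch != out_ch:
            # 1-tap operational projection; no batch norm on the downsample path
            self.shortcut = SelfONNConv1d(in_ch, out_ch, 1, Q=Q, stride=stride,
                                          padding=0, bias=True, rng=rng)
        else:
            self.shortcut = None
        self.attention = (MultiheadAttention1d(out_ch, heads, rng=rng)
                          if heads else None)

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.shortcut is None else self.shortcut(x)
        h = self.act(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        out = h + identity
        if self.attention is not None:
            out = out + self.attention(x, out)
        return self.act(out)


class SelfResNet(Module):
    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        Q = spec.taylor_order
        self.stem = SelfONNConv1d(1, spec.stem_channels, 7, Q=Q, stride=2,
                                  padding=3, bias=False, rng=rng)
        self.stem_bn = BatchNorm1d(spec.stem_channels)
        self.act = Tanh()
        blocks = []
        in_ch = spec.stem_channels
        for s, out_ch in enumerate(spec.stage_channels):
            for b in range(spec.blocks_per_stage):
                stride = 2 if (s > 0 and b == 0) else 1
                last = b == spec.blocks_per_stage - 1
                heads = (spec.attention_heads
                         if spec.attention_enabled and last else None)
                blocks.append(ResidualBlock(in_ch, out_ch, Q, stride, heads, rng))
                in_ch = out_ch
        self.blocks = blocks
        self.pool = GlobalAvgPool1d()
        self.fc = Linear(spec.stage_channels[-1], spec.n_classes, rng=rng)
        self.head = LogSoftmax()

    def forward(self, x: Tensor) -> Tensor:
        """(batch, 1, L) waveforms -> (batch, n_classes) log-probabilities."""
        h = self.act(self.stem_bn(self.stem(x)))
        for block in self.blocks:
            h = block(h)
        return self.head(self.fc(self.pool(h)))

    def predict_log_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            xb = np.asarray(x[i:i + batch_size], dtype=np.float64)
            if xb.ndim == 2:
                xb = xb[:, None, :]
            outs.append(self.forward(Tensor(xb)).data)
        return np.concatenate(outs, axis=0)


def build_self_resnet18(spec: ArchitectureSpec | None = None,
                        seed: int = 0) -> SelfResNet:
    spec = spec or ArchitectureSpec()
    if spec.attention_enabled:
        raise ValueError("attention_enabled must be False for Self-ResNet18")
    return SelfResNet(spec, seed=seed)


def build_self_resattentionet18(spec: ArchitectureSpec | None = None,
                                seed: int = 0) -> SelfResNet:
    spec = spec or ArchitectureSpec(attention_enabled=True)
    if not spec.attention_enabled:
        raise ValueError("attention_enabled must be True for Self-ResAttentioNet18")
    return SelfResNet(spec, seed=seed)


def attention_block_forward(identity: np.ndarray, block_output: np.ndarray,
                            heads: int, projections: dict) -> np.ndarray:
    """Plain-numpy scaled dot-product attention over time tokens.

    `projections` maps 'query'/'key'/'value'/'out' to (C, C) matrices.  Query
    and value come from the identity features, the key from the block output.
    Used directly in tests as an independent route against the trainable
    attention layer.
    """
    identity = np.asarray(identity, dtype=np.float64)
    block_output = np.asarray(block_output, dtype=np.float64)
    if identity.shape != block_output.shape:
        raise ValueError("identity and block_output must have the same shape")
    B, C, T = identity.shape
    if C % heads:
        raise ValueError("channels not divisible by heads")
    d = C // heads
    tok_q = identity.transpose(0, 2, 1)
    tok_k = block_output.transpose(0, 2, 1)

    def split(t):
        return t.reshape(B, T, heads, d).transpose(0, 2, 1, 3)

    q = split(tok_q @ projections["query"])
    k = split(tok_k @ projections["key"])
    v = split(tok_q @ projections["value"])
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(d)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    mixed = (w @ v).transpose(0, 2, 1, 3).reshape(B, T, C)
    return (mixed @ projections["out"]).transpose(0, 2, 1)


def summarize_network(net: SelfResNet) -> NetworkSummary:
    n_main = 0
    n_short = 0
    n_attn = 0
    n_kernel_w = 0
    for block in net.blocks:
        n_main += 2
        if block.shortcut is not None:
            n_short += 1
        if block.attention is not None:
            n_attn += 1
    n_main += 1  # stem
    for m in net.modules():
        if isinstance(m, SelfONNConv1d):
            n_kernel_w += m.weight.data.size
    return NetworkSummary(
        n_selfonn_layers_main_path=n_main,
        n_shortcut_projections=n_short,
        n_attention_layers=n_attn,
        n_weighted_layers_main_path=n_main + 1,  # + final dense layer
        n_operational_kernel_weights=n_kernel_w,
        total_parameters=net.n_parameters(),
    )


def architecture_to_yaml(spec: ArchitectureSpec, path) -> None:
    import yaml
    with open(path, "w") as f:
        yaml.safe_dump(dict(taylor_order=spec.taylor_order,
                            stem_channels=spec.stem_channels,
                            stage_channels=list(spec.stage_channels),
                            blocks_per_stage=spec.blocks_per_stage,
                            n_classes=spec.n_classes,
                            attention_enabled=spec.attention_enabled,
                            attention_heads=spec.attention_heads,
                            input_length=spec.input_length), f)


def architecture_from_yaml(path) -> ArchitectureSpec:
    import yaml
    with open(path) as f:
        d = yaml.safe_load(f) or {}
    if "stage_channels" in d:
        d["stage_channels"] = tuple(d["stage_channels"])
    return ArchitectureSpec(**d)


def save_network_hdf5(net: SelfResNet, path) -> None:
    with h5py.File(path, "w") as f:
        s = net.spec
        f.attrs.update(dict(taylor_order=s.taylor_order,
                            stem_channels=s.stem_channels,
                            stage_channels=list(s.stage_channels),
                            blocks_per_stage=s.blocks_per_stage,
                            n_classes=s.n_classes,
                            attention_enabled=s.attention_enabled,
                            attention_heads=s.attention_heads,
                            input_length=s.input_length))
        f.attrs["input_mean"] = float(getattr(net, "input_mean", 0.0))
        f.attrs["input_scale"] = float(getattr(net, "input_scale", 1.0))
        for name, arr in net.state_dict().items():
            f.create_dataset(name, data=arr)


def load_network_hdf5(path) -> SelfResNet:
    with h5py.File(path, "r") as f:
        a = f.attrs
        spec = ArchitectureSpec(
            taylor_order=int(a["taylor_order"]),
            stem_channels=int(a["stem_channels"]),
            stage_channels=tuple(int(c) for c in a["stage_channels"]),
            blocks_per_stage=int(a["blocks_per_stage"]),
            n_classes=int(a["n_classes"]),
            attention_enabled=bool(a["attention_enabled"]),
            attention_heads=int(a["attention_heads"]),
            input_length=int(a["input_length"]))
        net = SelfResNet(spec)
        net.load_state_dict({k: f[k][()] for k in f.keys()})
        net.input_mean = float(a.get("input_mean", 0.0))
        net.input_scale = float(a.get("input_scale", 1.0))
    return net
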