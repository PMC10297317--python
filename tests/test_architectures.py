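"""Structural and behavioural checks of the two residual classifiers."""

import numpy as np
import pytest

from tcdonn.architectures import (ArchitectureSpec, SelfResNet,
                                  attention_block_forward,
                                  build_self_resattentionet18,
                                  build_self_resnet18, load_network_hdf5,
                                  save_network_hdf5, summarize_network)
from tcdonn.nn import SelfONNConv1d, Tensor
from tcdonn.nn.layers import MultiheadAttention1d


@pytest.fixture(scope="module")
def resnet18():
    return build_self_resnet18(ArchitectureSpec(taylor_order=3), seed=0)


@pytest.fixture(scope="module")
def attentionet18():
    return build_self_resattentionet18(
        ArchitectureSpec(taylor_order=3, attention_enabled=True), seed=0)


class TestStructure:
    def test_weighted_layer_count_is_18(self, resnet18):
        s = summarize_network(resnet18)
        assert s.n_selfonn_layers_main_path == 17
        assert s.n_weighted_layers_main_path == 18

    def test_three_shortcut_projections(self, attentionet18):
        assert summarize_network(attentionet18).n_shortcut_projections == 3

    def test_four_attention_layers_with_two_heads(self, attentionet18):
        assert summarize_network(attentionet18).n_attention_layers == 4
        heads = {m.heads for m in attentionet18.modules()
                 if isinstance(m, MultiheadAttention1d)}
        assert heads == {2}

    def test_no_attention_in_plain_resnet(self, resnet18):
        assert summarize_network(resnet18).n_attention_layers == 0

    def test_stage_channel_widths(self, resnet18):
        assert resnet18.spec.stem_channels == 8
        assert tuple(resnet18.spec.stage_channels) == (8, 16, 32, 64)
        widths = [b.conv1.out_channels for b in resnet18.blocks]
        assert widths == [8, 8, 16, 16, 32, 32, 64, 64]

    def test_layer_counts_invariant_to_q(self):
        for q in (1, 5):
            s = summarize_network(build_self_resnet18(
                ArchitectureSpec(taylor_order=q), seed=0))
            assert (s.n_selfonn_layers_main_path, s.n_shortcut_projections) == (17, 3)

    def test_q3_adds_exactly_two_q1_kernel_weight_sets(self):
        s1 = summarize_network(build_self_resnet18(ArchitectureSpec(taylor_order=1)))
        s3 = summarize_network(build_self_resnet18(ArchitectureSpec(taylor_order=3)))
        assert (s3.total_parameters - s1.total_parameters
                == 2 * s1.n_operational_kernel_weights)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(stage_channels=(8, 16, 32, 65))
        with pytest.raises(ValueError):
            ArchitectureSpec(stem_channels=6, stage_channels=(6, 12, 24, 48),
                             attention_enabled=True, attention_heads=4)
        with pytest.raises(ValueError):
            build_self_resnet18(ArchitectureSpec(attention_enabled=True))
        with pytest.raises(ValueError):
            build_self_resattentionet18(ArchitectureSpec())


class TestForward:
    def test_log_softmax_normalization(self, attentionet18, rng):
        x = Tensor(rng.normal(size=(3, 1, 1024)))
        out = attentionet18.eval()(x)
        assert out.shape == (3, 2)
        np.testing.assert_allclose(np.exp(out.data).sum(axis=1), 1.0, atol=1e-6)

    def test_forward_deterministic(self, attentionet18, rng):
        x = rng.normal(size=(2, 1, 1024))
        a = attentionet18.eval()(Tensor(x)).data
        b = attentionet18.eval()(Tensor(x)).data
        np.testing.assert_array_equal(a, b)

    def test_zeroed_attention_reduces_to_resnet(self, rng):
        """With all attention projections zeroed the attended feature
        vanishes, so the attention network computes the plain residual net."""
        plain = build_self_resnet18(ArchitectureSpec(taylor_order=1), seed=3)
        attn = build_self_resattentionet18(
            ArchitectureSpec(taylor_order=1, attention_enabled=True), seed=3)
        plain_state = plain.state_dict()
        attn_state = attn.state_dict()
        for name in attn_state:
            if "attention" in name:
                attn_state[name] = np.zeros_like(attn_state[name])
            else:
                attn_state[name] = plain_state[name]
        attn.load_state_dict(attn_state)
        x = Tensor(rng.normal(size=(2, 1, 1024)))
        np.testing.assert_allclose(attn.eval()(x).data, plain.eval()(x).data,
                                   atol=1e-5)

    def test_gradient_reaches_every_parameter(self, rng):
        net = build_self_resattentionet18(
            ArchitectureSpec(taylor_order=1, attention_enabled=True), seed=1)
        out = net.train()(Tensor(rng.normal(size=(4, 1, 1024))))
        (out.pow_int(2)).mean().backward()
        dead = [n for n, p in net.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []


class TestAttentionBlock:
    def _projections(self, C, rng=None, identity=False):
        if identity:
            eye = np.eye(C)
            return {k: eye.copy() for k in ("query", "key", "value", "out")}
        return {k: rng.normal(size=(C, C)) for k in ("query", "key", "value", "out")}

    def test_shape_preserved_and_weights_normalized(self, rng):
        C, T, heads = 8, 16, 2
        d = C // heads
        ident = rng.normal(size=(2, C, T))
        blk = rng.normal(size=(2, C, T))
        proj = self._projections(C, rng)
        out = attention_block_forward(ident, blk, heads, proj)
        assert out.shape == (2, C, T)
        # recompute the attention weights and check each query row sums to 1
        tok_q = ident.transpose(0, 2, 1) @ proj["query"]
        tok_k = blk.transpose(0, 2, 1) @ proj["key"]
        q = tok_q.reshape(2, T, heads, d).transpose(0, 2, 1, 3)
        k = tok_k.reshape(2, T, heads, d).transpose(0, 2, 1, 3)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(d)
        w = np.exp(scores - scores.max(axis=-1, keepdims=True))
        w /= w.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_heads_partition_embedding(self):
        # 2 heads over 8 channels -> per-head embedding 4: odd channel counts fail
        with pytest.raises(ValueError, match="divisible"):
            attention_block_forward(np.zeros((1, 9, 4)), np.zeros((1, 9, 4)), 2,
                                    self._projections(9, identity=True))

    def test_constant_value_tokens_are_preserved(self, rng):
        """Identity projections + constant value tokens: every attended token
        is a convex combination of identical vectors, i.e. the vector itself."""
        C, T = 6, 10
        v = rng.normal(size=C)
        ident = np.broadcast_to(v[:, None], (1, C, T)).copy()
        blk = rng.normal(size=(1, C, T))
        out = attention_block_forward(ident, blk, 2, self._projections(C, identity=True))
        np.testing.assert_allclose(out, ident, atol=1e-10)

    def test_zero_key_gives_uniform_attention(self, rng):
        """A zero key makes all scores equal, so attention averages the value
        tokens uniformly over T."""
        C, T = 4, 7
        ident = rng.normal(size=(1, C, T))
        out = attention_block_forward(ident, np.zeros((1, C, T)), 2,
                                      self._projections(C, identity=True))
        expected = np.broadcast_to(ident.mean(axis=2, keepdims=True), ident.shape)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_layer_matches_functional_route(self, rng):
        """The trainable attention layer and the standalone numpy routine are
        independent implementations of the same attention."""
        C, T = 8, 12
        layer = MultiheadAttention1d(C, 2, rng=rng)
        ident = rng.normal(size=(2, C, T))
        blk = rng.normal(size=(2, C, T))
        got = layer(Tensor(ident), Tensor(blk)).data
        proj = {"query": layer.w_query.data.astype(float),
                "key": layer.w_key.data.astype(float),
                "value": layer.w_value.data.astype(float),
                "out": layer.w_out.data.astype(float)}
        expected = attention_block_forward(ident, blk, 2, proj)
        np.testing.assert_allclose(got, expected, atol=1e-4)


def test_architecture_yaml_roundtrip(tmp_path):
    from tcdonn.architectures import architecture_from_yaml, architecture_to_yaml
    spec = ArchitectureSpec(taylor_order=5, attention_enabled=True)
    architecture_to_yaml(spec, tmp_path / "arch.yaml")
    assert architecture_from_yaml(tmp_path / "arch.yaml") == spec


def test_network_hdf5_roundtrip(tmp_path, rng):
    net = build_self_resattentionet18(
        ArchitectureSpec(taylor_order=1, attention_enabled=True), seed=5)
    net.input_mean, net.input_scale = 42.0, 17.0
    path = tmp_path / "net.h5"
    save_network_hdf5(net, path)
    back = load_network_hdf5(path)
    assert back.input_mean == 42.0 and back.input_scale == 17.0
    x = Tensor(rng.normal(size=(1, 1, 1024)))
    np.testing.assert_allclose(back.eval()(x).data, net.eval()(x).data, atol=1e-6)
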