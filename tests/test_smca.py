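"""Spatial-multiscale context attention against explicit loop oracles."""

import numpy as np
import pytest

from amsdet.errors import ConfigurationError, InputError
from amsdet.nn import F, Tensor, no_grad
from amsdet.smca import (SMCA, SMCAConfig, adaptive_kernel_size, fuse_attention,
                         local_global_features, make_c2f_smca,
                         spatial_self_attention)
from conftest import seeded


def attention_oracle(x, qkv_w, qkv_b, proj_w, proj_b, heads):
    """Per-query-position double loop: softmax(q.k/sqrt(d)) weighted values."""
    b, c, h, w = x.shape
    d = c // heads
    n = h * w
    flat = x.reshape(b, c, n)
    wq = qkv_w[:, :, 0, 0]
    qkv = np.einsum("oc,bcn->bon", wq, flat) + qkv_b[None, :, None]
    out = np.zeros((b, c, n))
    for bi in range(b):
        for hd in range(heads):
            q = qkv[bi, hd * d:(hd + 1) * d]
            k = qkv[bi, c + hd * d:c + hd * d + d]
            v = qkv[bi, 2 * c + hd * d:2 * c + hd * d + d]
            for qi in range(n):
                logits = np.array([q[:, qi] @ k[:, kj] for kj in range(n)]) / np.sqrt(d)
                logits -= logits.max()
                wgt = np.exp(logits) / np.exp(logits).sum()
                out[bi, hd * d:(hd + 1) * d, qi] = sum(wgt[kj] * v[:, kj] for kj in range(n))
    out = np.einsum("oc,bcn->bon", proj_w[:, :, 0, 0], out) + proj_b[None, :, None]
    return out.reshape(b, c, h, w)


def make_smca(channels, heads=1, seed=0, ks=5):
    cfg = SMCAConfig(channels=channels, num_heads=heads, local_pool_size=ks)
    return SMCA(np.random.default_rng(seed), cfg)


class TestSpatialSelfAttention:
    def test_single_position_returns_value_projection(self):
        """With N=1 the softmax over one key is exactly 1, so the output is
        the projected value of the input."""
        m = make_smca(4, heads=2)
        x = np.array([1.0, -2.0, 0.5, 3.0]).reshape(1, 4, 1, 1).astype(np.float32)
        out = m.attention(Tensor(x)).data
        qkv = (m.qkv_w.data[:, :, 0, 0] @ x[0, :, 0, 0]) + m.qkv_b.data
        v = qkv[8:12]
        expected = m.proj_w.data[:, :, 0, 0] @ v + m.proj_b.data
        np.testing.assert_allclose(out[0, :, 0, 0], expected, atol=1e-5)

    def test_identical_positions_attend_uniformly(self):
        """Two positions with the same feature vector produce the same output
        at both positions."""
        m = make_smca(8, heads=2)
        col = np.random.default_rng(0).standard_normal(8).astype(np.float32)
        x = np.stack([col, col], axis=-1).reshape(1, 8, 1, 2)
        out = m.attention(Tensor(x)).data
        np.testing.assert_allclose(out[0, :, 0, 0], out[0, :, 0, 1], atol=1e-5)

    @pytest.mark.parametrize("i", range(20))
    def test_matches_loop_oracle(self, i):
        rng = seeded(i)
        heads = [1, 2, 4][i % 3]
        c = 4 if heads == 1 else 8
        m = make_smca(c, heads=heads, seed=i)
        x = rng.standard_normal((1, c, 3, 3)).astype(np.float32)
        got = m.attention(Tensor(x)).data
        want = attention_oracle(x.astype(np.float64), m.qkv_w.data, m.qkv_b.data,
                                m.proj_w.data, m.proj_b.data, heads)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_rows_sum_to_one(self):
        """Softmax attention weights over key positions are a distribution."""
        rng = seeded(99)
        x = rng.standard_normal((2, 8, 4, 5)).astype(np.float32)
        scores = rng.standard_normal((2, 2, 20, 20)).astype(np.float32)
        attn = F.softmax(Tensor(scores * 7), axis=-1).data
        assert attn.min() >= 0
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_errors(self):
        m = make_smca(8, heads=2)
        with pytest.raises(ConfigurationError):
            spatial_self_attention(Tensor(np.zeros((1, 6, 2, 2), np.float32)),
                                   m.qkv_w, m.qkv_b, m.proj_w, m.proj_b, 4)
        bad = np.zeros((1, 8, 2, 2), np.float32)
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(InputError):
            m.attention(Tensor(bad))


class TestAdaptiveKernelSize:
    @pytest.mark.parametrize("c,expected", [(2, 1), (64, 3), (256, 5)])
    def test_reference_values(self, c, expected):
        assert adaptive_kernel_size(c) == expected

    def test_formula_over_channel_sweep(self):
        """k = floor((log2 C + 1)/2) raised to the next odd integer, for all
        C in 2..1024."""
        for c in range(2, 1025):
            t = int(np.floor((np.log2(c) + 1) / 2))
            want = t if t % 2 else t + 1
            assert adaptive_kernel_size(c) == max(want, 1)

    def test_always_odd_and_monotone(self):
        ks = [adaptive_kernel_size(c) for c in range(1, 2049)]
        assert all(k % 2 == 1 for k in ks)
        assert all(b >= a for a, b in zip(ks, ks[1:]))

    def test_invalid_channels(self):
        with pytest.raises(InputError):
            adaptive_kernel_size(0)


class TestLocalGlobalFeatures:
    def test_constant_input(self):
        x = Tensor(np.full((1, 3, 7, 9), 2.5, np.float32))
        f_l, f_g = local_global_features(x, 5)
        np.testing.assert_allclose(f_l.data, 2.5, atol=1e-6)
        np.testing.assert_allclose(f_g.data, 2.5, atol=1e-6)

    def test_identity_when_input_matches_bins(self):
        rng = seeded(3)
        x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
        f_l, _ = local_global_features(Tensor(x), 5)
        np.testing.assert_allclose(f_l.data, x, atol=1e-6)

    def test_global_is_mean_of_local(self):
        rng = seeded(4)
        x = rng.standard_normal((2, 6, 11, 8)).astype(np.float32)
        f_l, f_g = local_global_features(Tensor(x), 5)
        np.testing.assert_allclose(f_g.data[..., 0, 0],
                                   f_l.data.mean(axis=(2, 3)), atol=1e-6)

    @pytest.mark.parametrize("i", range(20))
    def test_bin_partition_oracle(self, i):
        """Adaptive pooling equals explicit per-bin averaging with the
        floor/ceil bin boundaries."""
        rng = seeded(100 + i)
        c, h, w = 8, 7, 9
        ks = 5
        x = rng.standard_normal((1, c, h, w)).astype(np.float32)
        f_l, _ = local_global_features(Tensor(x), ks)
        for bi in range(ks):
            for bj in range(ks):
                h0, h1 = int(np.floor(bi * h / ks)), int(np.ceil((bi + 1) * h / ks))
                w0, w1 = int(np.floor(bj * w / ks)), int(np.ceil((bj + 1) * w / ks))
                want = x[0, :, h0:h1, w0:w1].mean(axis=(1, 2))
                np.testing.assert_allclose(f_l.data[0, :, bi, bj], want, atol=1e-5)

    def test_invalid_pool_size(self):
        with pytest.raises(ConfigurationError):
            local_global_features(Tensor(np.zeros((1, 2, 4, 4), np.float32)), 0)


def conv1d_oracle(vec, w):
    """Slide the kernel across channels with zero padding."""
    k = len(w)
    p = k // 2
    c = len(vec)
    padded = np.concatenate([np.zeros(p), vec, np.zeros(p)])
    return np.array([sum(w[t] * padded[i + t] for t in range(k)) for i in range(c)])


class TestFuseAttention:
    def test_omega_zero_uses_global_branch_only(self):
        m = make_smca(16)
        m.omega.data = np.float32(0.0)
        rng = seeded(5)
        xs = Tensor(rng.standard_normal((1, 16, 6, 6)).astype(np.float32))
        f_l, f_g = local_global_features(xs, 5)
        a = fuse_attention(f_l, f_g, m.conv1d_w, m.omega, m.k1d).data[0, :, 0, 0]
        want = 1 / (1 + np.exp(-conv1d_oracle(f_g.data[0, :, 0, 0], m.conv1d_w.data)))
        np.testing.assert_allclose(a, want, atol=1e-6)

    def test_zero_kernel_gives_half(self):
        """sigma(0) = 0.5 for both branches, any omega."""
        m = make_smca(16)
        m.conv1d_w.data[:] = 0.0
        xs = Tensor(seeded(6).standard_normal((1, 16, 6, 6)).astype(np.float32))
        gate = m.gate(xs).data
        np.testing.assert_allclose(gate, 0.5, atol=1e-6)

    @pytest.mark.parametrize("i", range(20))
    def test_conv1d_blend_oracle(self, i):
        """Full fusion against a loop oracle: per-bin cross-channel conv,
        sigmoid, bin average, blended with the global branch."""
        rng = seeded(200 + i)
        m = make_smca(16, seed=i)
        ks = 5
        f_l = rng.standard_normal((1, 16, ks, ks)).astype(np.float32)
        f_g = f_l.mean(axis=(2, 3), keepdims=True)
        a = fuse_attention(Tensor(f_l), Tensor(f_g), m.conv1d_w, m.omega, m.k1d)
        w = m.conv1d_w.data
        sig = lambda z: 1 / (1 + np.exp(-z))
        loc = np.zeros(16)
        for bi in range(ks):
            for bj in range(ks):
                loc += sig(conv1d_oracle(f_l[0, :, bi, bj], w))
        loc /= ks * ks
        glo = sig(conv1d_oracle(f_g[0, :, 0, 0], w))
        omega = float(np.clip(m.omega.data, 0, 1))
        want = omega * loc + (1 - omega) * glo
        np.testing.assert_allclose(a.data[0, :, 0, 0], want, atol=1e-6)

    def test_even_kernel_rejected(self):
        m = make_smca(16)
        xs = Tensor(np.zeros((1, 16, 5, 5), np.float32))
        f_l, f_g = local_global_features(xs, 5)
        with pytest.raises(ConfigurationError):
            fuse_attention(f_l, f_g, m.conv1d_w, m.omega, kernel_size=2)

    def test_gate_bounded_in_unit_interval(self):
        for i in range(5):
            m = make_smca(32, seed=i)
            xs = Tensor(seeded(300 + i).standard_normal((2, 32, 9, 9)).astype(np.float32) * 10)
            gate = m.gate(xs).data
            assert np.all(gate > 0) and np.all(gate < 1)


class TestSMCAForward:
    def test_recomposition(self):
        """Y equals the elementwise product of independently computed X_s and
        A_final."""
        m = make_smca(8, heads=2, seed=7)
        x = Tensor(seeded(8).standard_normal((2, 8, 5, 5)).astype(np.float32))
        y = m(x).data
        xs = m.attention(x)
        gate = m.gate(xs)
        np.testing.assert_allclose(y, xs.data * gate.data, atol=1e-6)

    def test_saturated_gate_limits(self):
        """A saturated positive kernel drives the gate to 1 (Y ~ X_s); a
        saturated negative kernel drives it to 0 (Y ~ 0)."""
        m = make_smca(8, heads=2, seed=9)
        x = Tensor(seeded(9).standard_normal((1, 8, 4, 4)).astype(np.float32))
        xs = m.attention(x).data
        m.conv1d_w.data[:] = 50.0
        y_hi = m(x).data
        # gate -> sigmoid(large * sum of channels) is not uniformly 1 for
        # arbitrary signs, so saturate via omega and a constant-positive input
        xpos = Tensor(np.abs(seeded(10).standard_normal((1, 8, 4, 4))).astype(np.float32) + 1)
        xs_pos = m.attention(xpos).data
        m.conv1d_w.data[:] = 0.0
        m.conv1d_w.data[m.k1d // 2] = 1000.0
        gate = m.gate(m.attention(xpos)).data
        y = m(xpos).data
        pos = xs_pos > 0
        np.testing.assert_allclose(y[pos], xs_pos[pos], rtol=1e-3, atol=1e-4)
        m.conv1d_w.data[m.k1d // 2] = -1000.0
        y0 = m(xpos).data
        np.testing.assert_allclose(y0[pos], 0.0, atol=1e-3)

    @pytest.mark.parametrize("c", [8, 16, 32, 64])
    @pytest.mark.parametrize("hw", [(1, 1), (5, 8), (13, 5)])
    def test_shape_preserved(self, c, hw):
        m = make_smca(c, heads=4, seed=c)
        x = Tensor(seeded(c).standard_normal((1, c, *hw)).astype(np.float32))
        assert m(x).data.shape == x.data.shape

    def test_monotone_gating(self):
        """Scaling the gate toward zero never increases |Y| anywhere."""
        m = make_smca(8, heads=2, seed=11)
        x = Tensor(seeded(11).standard_normal((1, 8, 6, 6)).astype(np.float32))
        xs = m.attention(x)
        gate = m.gate(xs).data
        y_full = np.abs(xs.data * gate)
        for scale in (0.7, 0.3, 0.0):
            y_scaled = np.abs(xs.data * (gate * scale))
            assert np.all(y_scaled <= y_full + 1e-7)
        assert np.all(np.abs(xs.data * gate) <= np.abs(xs.data) + 1e-7)


class TestC2fSMCA:
    def test_shape_and_single_pixel(self):
        rng = np.random.default_rng(0)
        blk = make_c2f_smca(rng, 32, 32, n=1)
        x = Tensor(seeded(12).standard_normal((1, 32, 1, 1)).astype(np.float32))
        assert blk(x).data.shape == (1, 32, 1, 1)

    def test_decomposition_oracle(self):
        """Block output equals the explicit split -> unit chain -> concat ->
        fusion sequence executed step by step."""
        rng = np.random.default_rng(5)
        blk = make_c2f_smca(rng, 32, 32, n=2)
        blk.eval()
        x = Tensor(seeded(13).standard_normal((2, 32, 6, 6)).astype(np.float32))
        with no_grad():
            got = blk(x).data
            y = blk.cv1(x)
            a = F.narrow(y, 1, 0, 16)
            b = F.narrow(y, 1, 16, 16)
            parts = [a, b]
            cur = b
            for unit in blk.m:
                cur = unit(cur)
                parts.append(cur)
            want = blk.cv2(F.concat(parts, axis=1)).data
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_gate_zero_isolates_skip_branch(self):
        """Saturating the SMCA gate negative zeroes the processed branch, so
        only cv1's two split halves reach the fusion convolution."""
        rng = np.random.default_rng(6)
        blk = make_c2f_smca(rng, 32, 32, n=1)
        blk.eval()
        smca = blk.m[0][1]
        smca.conv1d_w.data[:] = 0.0
        smca.qkv_b.data[:] = 0.0
        smca.omega.data = np.float32(1.0)
        # zero qkv/proj weights and drive proj bias very negative so X_s < 0
        # everywhere is not needed; instead zero proj weights and bias so
        # X_s = 0 exactly -> Y = 0 regardless of the gate
        smca.proj_w.data[:] = 0.0
        smca.proj_b.data[:] = 0.0
        x = Tensor(seeded(14).standard_normal((1, 32, 4, 4)).astype(np.float32))
        with no_grad():
            got = blk(x).data
            y = blk.cv1(x)
            a = F.narrow(y, 1, 0, 16)
            b = F.narrow(y, 1, 16, 16)
            zero = Tensor(np.zeros_like(b.data))
            want = blk.cv2(F.concat([a, b, zero], axis=1)).data
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_channel_mismatch_raises(self):
        rng = np.random.default_rng(7)
        blk = make_c2f_smca(rng, 32, 32, n=1)
        with pytest.raises(ValueError):
            blk(Tensor(np.zeros((1, 16, 4, 4), np.float32)))
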