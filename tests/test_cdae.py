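"""Architecture shape calculus, pooling/unpooling operators, convolution
against a nested-loop oracle, encoding and decoder truncation."""

import numpy as np
import pytest

from ishcdae import _ops
from ishcdae.cdae import (ArchitectureSpec, CDAENetwork, LayerSpec,
                          best_auc_architecture, bottleneck_shape,
                          cdae_architecture, max_pool, unpool)


def conv2d_loops(x, weight, bias):
    """Brute-force same-padded stride-1 correlation, (C,H,W) layout."""
    c_out, c_in, k, _ = weight.shape
    _, h, w = x.shape
    p = k // 2
    out = np.zeros((c_out, h, w))
    for o in range(c_out):
        for i in range(h):
            for j in range(w):
                s = 0.0
                for c in range(c_in):
                    for di in range(k):
                        for dj in range(k):
                            ii, jj = i + di - p, j + dj - p
                            if 0 <= ii < h and 0 <= jj < w:
                                s += x[c, ii, jj] * weight[o, c, di, dj]
                out[o, i, j] = s + bias[o]
    return out


class TestShapeCalculus:
    @pytest.mark.parametrize("h,w,n,expected", [
        (960, 480, 4, (60, 30)),
        (200, 200, 2, (50, 50)),
        (480, 240, 3, (60, 30)),
        (96, 48, 4, (6, 3)),
        (7, 9, 0, (7, 9)),
    ])
    def test_bottleneck_shape(self, h, w, n, expected):
        assert bottleneck_shape(h, w, n) == expected

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            bottleneck_shape(100, 48, 4)
        with pytest.raises(ValueError):
            best_auc_architecture(100, 48)

    def test_reference_architecture_representation_lengths(self):
        assert best_auc_architecture().representation_length() == 1800
        assert best_auc_architecture(96, 48).representation_length() == 18

    def test_reference_architecture_structure(self):
        arch = best_auc_architecture()
        enc_kinds = [l.kind for l in arch.encoder]
        assert enc_kinds.count("conv") == 10
        assert enc_kinds.count("maxpool") == 4
        dec_kinds = [l.kind for l in arch.decoder]
        assert dec_kinds.count("deconv") == 9
        assert dec_kinds.count("unpool") == 4
        # bottleneck: single feature map; decoder ends with single-filter tanh
        convs = [l for l in arch.encoder if l.kind == "conv"]
        assert convs[-1].n_filters == 1
        assert arch.decoder[-1].activation == "tanh"
        assert arch.decoder[-1].n_filters == 1
        assert all(l.filter_size == 3 for l in convs)

    def test_asymmetric_pool_unpool_rejected(self):
        enc = (LayerSpec("conv", 2), LayerSpec("maxpool"), LayerSpec("conv", 1))
        dec = (LayerSpec("deconv", 1, activation="tanh"),)
        with pytest.raises(ValueError, match="mirror"):
            ArchitectureSpec(8, 8, enc, dec)

    def test_architecture_json_roundtrip(self):
        arch = best_auc_architecture(96, 48)
        assert ArchitectureSpec.from_json(arch.to_json()) == arch


class TestPoolingOperators:
    def test_single_block_max(self):
        assert max_pool(np.array([[1.0, 2.0], [3.0, 4.0]])) == np.array([[4.0]])

    def test_constant_grid_quarter_area(self):
        out = max_pool(np.full((6, 4), 2.5))
        assert out.shape == (3, 2)
        assert np.all(out == 2.5)

    def test_matches_nested_loop_blockwise_max(self, rng):
        x = rng.standard_normal((8, 8))
        out = max_pool(x)
        for i in range(4):
            for j in range(4):
                assert out[i, j] == x[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max()

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError, match="even"):
            max_pool(np.zeros((5, 4)))

    def test_unpool_duplicates_value(self):
        assert np.array_equal(unpool(np.array([[5.0]])),
                              np.full((2, 2), 5.0))

    def test_unpool_of_pool_gives_constant_blocks_of_blockwise_max(self, rng):
        x = rng.standard_normal((8, 6))
        up = unpool(max_pool(x))
        assert up.shape == x.shape
        for i in range(4):
            for j in range(3):
                block = up[2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                assert np.all(block == x[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max())

    def test_unpool_quadruples_sum_and_area(self, rng):
        m = rng.random((3, 5))
        up = unpool(m)
        assert up.shape == (6, 10)
        assert np.isclose(up.sum(), 4 * m.sum())


class TestConvolution:
    @pytest.mark.parametrize("c_in,c_out,k", [(1, 1, 3), (2, 3, 3), (3, 2, 5)])
    def test_matches_nested_loop_oracle(self, rng, c_in, c_out, k):
        x = rng.standard_normal((1, c_in, 8, 8))
        w = rng.standard_normal((c_out, c_in, k, k))
        b = rng.standard_normal(c_out)
        y, _ = _ops.conv_forward(x, w, b)
        expected = conv2d_loops(x[0], w, b)
        assert np.abs(y[0] - expected).max() <= 1e-5


class TestNetwork:
    @pytest.mark.parametrize("h,w", [(16, 16), (32, 16), (48, 32), (64, 64), (80, 16)])
    def test_shape_conservation_through_full_pass(self, h, w, rng):
        net = CDAENetwork(cdae_architecture(h, w), seed=0)
        out = net.forward_full(rng.random((h, w)))
        assert out.pixels.shape == (h, w)

    def test_output_strictly_inside_tanh_range(self, rng):
        net = CDAENetwork(cdae_architecture(16, 16), seed=1)
        out = net.forward_full(rng.random((16, 16)) * 2 - 1)
        assert np.all(out.pixels > -1) and np.all(out.pixels < 1)

    def test_forward_deterministic(self, rng):
        net = CDAENetwork(cdae_architecture(16, 16), seed=2)
        x = rng.random((16, 16))
        assert np.array_equal(net.forward_full(x).pixels,
                              net.forward_full(x).pixels)

    def test_shape_mismatch_rejected(self, rng):
        net = CDAENetwork(cdae_architecture(16, 16), seed=0)
        with pytest.raises(ValueError, match="match"):
            net.forward_full(rng.random((16, 32)))

    def test_encode_length_and_equality_with_bottleneck_slice(self, rng):
        net = CDAENetwork(cdae_architecture(96, 48), seed=3)
        x = rng.random((96, 48))
        rep = net.encode(x)
        assert rep.values.shape == (18,)
        bottleneck = net.forward_batch(x[None], upto=net.n_encoder_layers)
        assert np.array_equal(rep.values, bottleneck.reshape(-1))

    def test_truncate_decoder_preserves_representations(self, rng):
        net = CDAENetwork(cdae_architecture(32, 16), seed=4)
        x = rng.random((32, 16))
        enc = net.truncate_decoder()
        assert len(enc.layers) == len(net.architecture.encoder)
        assert np.array_equal(enc.encode(x).values, net.encode(x).values)
        # idempotent
        assert enc.truncate_decoder() is enc
        with pytest.raises(ValueError, match="decoder"):
            enc.forward_full(x)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = CDAENetwork(cdae_architecture(16, 16), seed=5)
        x = rng.random((16, 16))
        net.save(tmp_path / "ck.npz")
        back = CDAENetwork.load(tmp_path / "ck.npz")
        assert back.architecture == net.architecture
        assert np.array_equal(back.encode(x).values, net.encode(x).values)


class TestTranslationTolerance:
    def test_small_shift_changes_representation_less_than_motif_removal(self):
        """Pooling should make representations more tolerant to a 2-px motif
        shift than to replacing the motif with background."""
        rng = np.random.default_rng(0)
        net = CDAENetwork(cdae_architecture(64, 32, n_pool_stages=3), seed=7)
        shift_d, remove_d = [], []
        for trial in range(12):
            bg = 0.5 + 0.05 * rng.standard_normal((64, 32))
            r0, c0 = rng.integers(16, 40), rng.integers(8, 20)
            rr, cc = np.meshgrid(np.arange(64), np.arange(32), indexing="ij")
            blob = np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * 4.0 ** 2)))
            blob_shift = np.exp(-((((rr - r0 - 2) ** 2) + (cc - c0) ** 2) / (2 * 4.0 ** 2)))
            img = np.clip(bg + 0.45 * blob, 0, 1) * 2 - 1
            img_shift = np.clip(bg + 0.45 * blob_shift, 0, 1) * 2 - 1
            img_nomotif = np.clip(bg, 0, 1) * 2 - 1
            z = net.encode(img).values
            shift_d.append(np.linalg.norm(net.encode(img_shift).values - z))
            remove_d.append(np.linalg.norm(net.encode(img_nomotif).values - z))
        assert np.mean(shift_d) < np.mean(remove_d)
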