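"""Learning-rate schedule, reconstruction loss, gradient correctness and
training behaviour."""

import numpy as np
import pytest

from ishcdae.cdae import ArchitectureSpec, CDAENetwork, LayerSpec, cdae_architecture
from ishcdae.train import (CDAETransformer, TrainConfig, _backward,
                           _forward_cached, lr_schedule, reconstruction_loss,
                           train_cdae)


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 0.05), (1, 0.045), (10, 0.05 * 0.9 ** 10),
    ])
    def test_geometric_decay(self, epoch, expected):
        assert lr_schedule(epoch) == pytest.approx(expected, abs=1e-12)

    def test_full_sequence_exact(self):
        _, report = train_cdae(
            np.random.default_rng(0).random((4, 16, 16)),
            cdae_architecture(16, 16, n_pool_stages=2, n_filters=2,
                              convs_per_stage=1),
            TrainConfig(n_epochs=6, seed=0),
        )
        assert report.epoch_lrs == [0.05 * 0.9 ** e for e in range(6)]


class TestReconstructionLoss:
    def test_identical_is_zero_and_unit_offset_is_one(self, rng):
        x = rng.random((6, 6))
        assert reconstruction_loss(x, x) == 0.0
        assert reconstruction_loss(np.ones((4, 4)), np.zeros((4, 4))) == 1.0

    def test_matches_loop_oracle(self, rng):
        a, b = rng.random((5, 7)), rng.random((5, 7))
        acc = 0.0
        for i in range(5):
            for j in range(7):
                acc += (a[i, j] - b[i, j]) ** 2
        assert reconstruction_loss(a, b) == pytest.approx(acc / 35, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestGradients:
    def _check(self, arch, bias_shift=0.0, n_per_param=12, eps=1e-6):
        rng = np.random.default_rng(0)
        net = CDAENetwork(arch, seed=3, dtype="float64", init="uniform")
        for p in net.params:
            if p is not None:
                p["bias"] += bias_shift
        x = rng.random((2, 1, arch.input_h, arch.input_w))
        t = rng.random((2, 1, arch.input_h, arch.input_w)) * 2 - 1

        def loss():
            out, _ = _forward_cached(net, x)
            d = out - t
            return float(np.mean(d * d))

        out, caches = _forward_cached(net, x)
        d = out - t
        grads = _backward(net, (2.0 / d.size) * d, caches)
        worst = 0.0
        for p, g in zip(net.params, grads):
            if p is None:
                continue
            for key in ("weight", "bias"):
                flat = p[key].ravel()
                idxs = rng.choice(flat.size, size=min(n_per_param, flat.size),
                                  replace=False)
                for i in idxs:
                    old = flat[i]
                    flat[i] = old + eps
                    lp = loss()
                    flat[i] = old - eps
                    lm = loss()
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    ana = g[key].ravel()[i]
                    worst = max(worst, abs(num - ana) /
                                max(1e-8, abs(num) + abs(ana)))
        return worst

    def test_finite_difference_smooth_network(self):
        """Full-loss gradient vs central differences on an all-tanh CDAE
        (smooth everywhere, so the comparison is exact)."""
        enc = (LayerSpec("conv", 2, activation="tanh"), LayerSpec("maxpool"),
               LayerSpec("conv", 1, activation="tanh"))
        dec = (LayerSpec("unpool"), LayerSpec("deconv", 2, activation="tanh"),
               LayerSpec("deconv", 1, activation="tanh"))
        assert self._check(ArchitectureSpec(8, 8, enc, dec)) < 1e-6

    def test_finite_difference_relu_network(self):
        """ReLU CDAE checked away from its kinks: biases shifted so every
        pre-activation is strictly positive and pooling has no ties."""
        arch = cdae_architecture(8, 8, n_pool_stages=1, n_filters=2,
                                 convs_per_stage=1)
        assert self._check(arch, bias_shift=3.0) < 1e-4


class TestTrainingLoop:
    def test_fixed_seed_reproduces_final_weights(self, small_stack):
        arch = cdae_architecture(64, 32, n_pool_stages=2, n_filters=2,
                                 convs_per_stage=1)
        cfg = TrainConfig(n_epochs=3, seed=11)
        net1, rep1 = train_cdae(small_stack[:20], arch, cfg)
        net2, rep2 = train_cdae(small_stack[:20], arch, cfg)
        assert rep1.epoch_losses == rep2.epoch_losses
        for p1, p2 in zip(net1.params, net2.params):
            if p1 is not None:
                assert np.array_equal(p1["weight"], p2["weight"])

    def test_training_reduces_loss(self, small_stack):
        arch = cdae_architecture(64, 32, n_pool_stages=2, n_filters=2)
        _, report = train_cdae(small_stack[:40], arch,
                               TrainConfig(n_epochs=12, seed=1))
        assert report.epoch_losses[-1] < report.epoch_losses[0]
        assert all(np.isfinite(l) for l in report.epoch_losses)

    def test_loss_minimum_in_last_third(self, small_stack):
        arch = cdae_architecture(64, 32, n_pool_stages=2, n_filters=2)
        for seed in (1, 2, 3):
            _, report = train_cdae(small_stack[:40], arch,
                                   TrainConfig(n_epochs=12, seed=seed))
            assert int(np.argmin(report.epoch_losses)) >= 8

    def test_zero_denoising_rate_is_plain_cae_and_still_learns(self, small_stack):
        arch = cdae_architecture(64, 32, n_pool_stages=2, n_filters=2)
        _, report = train_cdae(small_stack[:20], arch,
                               TrainConfig(n_epochs=8, seed=2,
                                           denoising_rate=0.0))
        assert report.epoch_losses[-1] < report.epoch_losses[0]

    def test_dimension_mismatch_rejected(self, small_stack):
        arch = cdae_architecture(32, 32, n_pool_stages=2)
        with pytest.raises(ValueError, match="dims"):
            train_cdae(small_stack, arch, TrainConfig(n_epochs=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(denoising_rate=0.9)
        with pytest.raises(ValueError):
            TrainConfig(initial_lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(n_epochs=0)


class TestCDAETransformer:
    def test_fit_transform_shapes_and_sklearn_contract(self, small_stack):
        from sklearn.base import clone

        est = CDAETransformer(n_pool_stages=3, n_filters=2, convs_per_stage=1,
                              n_epochs=2, random_state=0)
        clone(est)  # get_params/set_params round trip
        X = est.fit(small_stack[:16]).transform(small_stack[:16])
        assert X.shape == (16, (64 // 8) * (32 // 8))
        assert est.n_features_out_ == X.shape[1]

    def test_transform_before_fit_raises(self, small_stack):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            CDAETransformer().transform(small_stack[:2])

    def test_transform_uses_uncorrupted_input(self, small_stack):
        """Encoding at evaluation time never applies masking noise: two
        transforms of the same data are identical."""
        est = CDAETransformer(n_pool_stages=2, n_filters=2, convs_per_stage=1,
                              n_epochs=1, random_state=0,
                              denoising_rate=0.5).fit(small_stack[:8])
        a = est.transform(small_stack[:8])
        b = est.transform(small_stack[:8])
        assert np.array_equal(a, b)
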