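import numpy as np
import pytest

from caescreen.cae import CAE, CAEConfig, build_cae
from caescreen.errors import ValidationError
from caescreen.nn import Conv2D, ConvTranspose2D, MaxPool2D, Sequential


class TestEngine:
    """Checks of the convolution engine against independent computations."""

    def test_conv_matches_scipy_correlate(self):
        from scipy import ndimage
        rng = np.random.default_rng(0)
        layer = Conv2D(3, 4, 5, rng, relu=False)
        x = rng.standard_normal((2, 10, 10, 3)).astype(np.float32)
        y = layer.forward(x, training=False)
        W = layer.params["W"].astype(float)
        # same-padded correlation, channel by channel, via zero padding
        expected = np.zeros((2, 10, 10, 4))
        xp = np.pad(x.astype(float), ((0, 0), (2, 2), (2, 2), (0, 0)))
        for co in range(4):
            for ci in range(3):
                expected[..., co] += ndimage.correlate(
                    xp[..., ci], W[None, :, :, ci, co], mode="constant")[:, 2:-2, 2:-2]
        assert np.allclose(y, expected, atol=1e-4)

    def test_transposed_conv_matches_scatter_oracle(self):
        rng = np.random.default_rng(1)
        for k, s in [(2, 2), (5, 2), (3, 1)]:
            layer = ConvTranspose2D(2, 3, k, s, rng, relu=False)
            x = rng.standard_normal((1, 4, 4, 2)).astype(np.float32)
            y = layer.forward(x, training=False)
            W = layer.params["W"].astype(float)
            beg = (k - s) // 2
            h = w = 4
            expected = np.zeros((1, h * s, w * s, 3))
            for i in range(h):
                for j in range(w):
                    for a in range(k):
                        for b in range(k):
                            oi, oj = s * i + a - beg, s * j + b - beg
                            if 0 <= oi < h * s and 0 <= oj < w * s:
                                expected[0, oi, oj] += x[0, i, j].astype(float) @ W[a, b]
            assert np.allclose(y, expected, atol=1e-4)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(2)
        layers = [Conv2D(2, 3, 2, rng, relu=False), MaxPool2D(2),
                  ConvTranspose2D(3, 1, 5, 2, rng, relu=False)]
        net = Sequential(layers)
        for l in layers:
            for k in l.params:
                l.params[k] = l.params[k].astype(np.float64)
        x = rng.standard_normal((2, 8, 8, 2))
        t = rng.standard_normal((2, 8, 8, 1))

        def loss():
            y = net.forward(x)
            return float(np.mean((y - t) ** 2))

        y = net.forward(x, training=True)
        net.backward(2.0 / y.size * (y - t))
        eps = 1e-6
        for l in layers:
            for key, p in l.params.items():
                for _ in range(4):
                    idx = tuple(rng.integers(0, s) for s in p.shape)
                    orig = p[idx]
                    p[idx] = orig + eps
                    lp = loss()
                    p[idx] = orig - eps
                    lm = loss()
                    p[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    assert l.grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestArchitecture:
    def test_full_scale_layer_shapes(self):
        model = build_cae(CAEConfig())
        sides = [s[0] for s in model.layer_output_shapes()]
        assert sides == [500, 250, 250, 125, 250, 500, 500]
        assert model.bottleneck_shape == (125, 125, 256)
        assert model.output_shape == (500, 500, 1)

    def test_scaled_config_shapes(self):
        model = build_cae(CAEConfig(input_side=128, filters=(16, 32)))
        assert model.bottleneck_shape == (32, 32, 32)
        assert model.output_shape == (128, 128, 1)

    def test_scale_knob_shrinks_side_and_filters_together(self):
        cfg = CAEConfig(scale=0.2)
        assert cfg.effective_side == 100
        assert cfg.effective_filters == (25, 51)
        model = build_cae(cfg)
        assert model.bottleneck_shape == (25, 25, 51)

    def test_side_not_divisible_by_pool_squared_rejected(self):
        with pytest.raises(ValidationError):
            build_cae(CAEConfig(input_side=126))

    def test_config_roundtrip(self):
        cfg = CAEConfig(input_side=64, filters=(4, 8), epochs=3, seed=9)
        assert CAEConfig.from_dict(cfg.to_dict()) == cfg


class TestTraining:
    def test_all_zero_images_reach_zero_loss(self):
        x = np.zeros((8, 16, 16), dtype=np.float32)
        model = build_cae(CAEConfig(input_side=16, filters=(4, 8), epochs=20,
                                    batch_size=4, seed=0))
        model.train(x)
        # the ReLU output can reach exactly zero, so the MSE goes to ~0
        assert model.history[-1].train_loss < 1e-6
        assert float(model.per_image_mse(x).mean()) < 1e-6

    def test_history_bookkeeping(self, trained_small, small_clean_pre):
        assert len(trained_small.history) == trained_small.config.epochs
        for rec in trained_small.history:
            assert rec.train_loss >= 0
            assert rec.mse_clean is not None and rec.mse_clean >= 0
            assert rec.pct_diff is not None

    def test_training_loss_decreases(self, trained_small):
        hist = trained_small.history
        assert hist[-1].train_loss <= hist[0].train_loss

    def test_model_beats_zero_predictor(self, trained_small, small_clean_pre):
        held_out = small_clean_pre[40:]
        mse = float(trained_small.per_image_mse(held_out).mean())
        zero_mse = float((held_out.astype(np.float64) ** 2).mean())
        assert mse < zero_mse

    def test_anomaly_premise_on_fixtures(self, trained_small, small_clean_pre,
                                         small_artifact_pre):
        """Artifact-laden reconstructions are worse than clean ones."""
        clean_mse = trained_small.per_image_mse(small_clean_pre[40:]).mean()
        art_mse = trained_small.per_image_mse(small_artifact_pre).mean()
        assert art_mse > clean_mse

    def test_empty_training_set_rejected(self):
        model = build_cae(CAEConfig(input_side=16, filters=(2, 2)))
        with pytest.raises(ValidationError):
            model.train(np.zeros((0, 16, 16), dtype=np.float32))

    def test_shape_mismatch_rejected(self):
        model = build_cae(CAEConfig(input_side=16, filters=(2, 2)))
        with pytest.raises(ValidationError):
            model.train(np.zeros((4, 32, 32), dtype=np.float32))


class TestReconstruct:
    def test_deterministic_and_nonnegative(self, trained_small, small_clean_pre):
        a = trained_small.reconstruct(small_clean_pre[0])
        b = trained_small.reconstruct(small_clean_pre[0])
        assert (a == b).all()
        assert a.min() >= 0.0
        assert a.shape == small_clean_pre[0].shape

    def test_batch_matches_single(self, trained_small, small_clean_pre):
        batch = trained_small.reconstruct(small_clean_pre[:3])
        single = trained_small.reconstruct(small_clean_pre[1])
        assert np.allclose(batch[1], single)

    def test_wrong_side_rejected(self, trained_small):
        with pytest.raises(ValidationError):
            trained_small.reconstruct(np.zeros((32, 32), dtype=np.float32))


class TestValidationMetrics:
    def _stub(self, mses):
        model = build_cae(CAEConfig(input_side=16, filters=(2, 2)))
        it = iter(mses)
        model.per_image_mse = lambda imgs: np.asarray(next(it))
        return model

    def test_hand_arithmetic(self):
        model = self._stub([[0.01, 0.03], [0.06, 0.02]])
        vm = model.validation_metrics(np.zeros((2, 16, 16)), np.zeros((2, 16, 16)))
        assert vm.mse_clean == pytest.approx(0.02)
        assert vm.pct_diff == pytest.approx(100.0)

    def test_identical_sets_give_zero_pct_diff(self, trained_small, small_clean_pre):
        vm = trained_small.validation_metrics(small_clean_pre[40:44],
                                              small_clean_pre[40:44])
        assert vm.pct_diff == pytest.approx(0.0, abs=1e-9)

    def test_identity_reconstruction_gives_zero_mse(self):
        model = build_cae(CAEConfig(input_side=16, filters=(2, 2)))
        model.reconstruct = lambda imgs, batch_size=None: np.asarray(imgs)
        x = np.random.default_rng(0).random((3, 16, 16)).astype(np.float32)
        vm = model.validation_metrics(x)
        assert vm.mse_clean == 0.0

    def test_empty_sets_rejected(self, trained_small):
        with pytest.raises(ValidationError):
            trained_small.validation_metrics(np.zeros((0, 64, 64)))


class TestSerialization:
    def test_save_load_roundtrip(self, trained_small, small_clean_pre, tmp_path):
        p = tmp_path / "model.npz"
        trained_small.save(p)
        loaded = CAE.load(p)
        assert loaded.config == trained_small.config
        assert len(loaded.history) == len(trained_small.history)
        a = trained_small.reconstruct(small_clean_pre[0])
        b = loaded.reconstruct(small_clean_pre[0])
        assert (a == b).all()
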