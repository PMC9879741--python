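"""Encoder--decoder reconstruction: layer gradients, build determinism,
training behaviour, checkpointing, and prediction geometry."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from ctcenterline import _nn
from ctcenterline.centerline import measure_centerlines
from ctcenterline.preprocess import TrainingPair
from ctcenterline.reconstructor import (LocalizerToVolumeModel, ModelConfig,
                                        TrainConfig)

TOY = ModelConfig(depth=2, base_channels=4, output_ap_bins=8,
                  input_shape=(16, 16))


class TestLayers:
    def test_conv_forward_matches_scipy(self):
        rng = np.random.default_rng(0)
        conv = _nn.Conv2d(2, 3, k=3, stride=1, rng=rng)
        x = rng.standard_normal((1, 2, 9, 7)).astype(np.float32)
        out = conv.forward(x, training=True)
        W = conv.W.reshape(3, 2, 3, 3)
        for o in range(3):
            ref = sum(
                correlate2d(x[0, c], W[o, c], mode="same", boundary="fill")
                for c in range(2)) + conv.b[o]
            assert np.allclose(out[0, o], ref, atol=1e-4)

    def test_backprop_matches_numerical_gradients(self):
        """Finite-difference check through the full graph (convs, BN, skips,
        global context, shift warp)."""
        rng = np.random.default_rng(4)
        m = LocalizerToVolumeModel(
            ModelConfig(depth=2, base_channels=3, output_ap_bins=5,
                        input_shape=(8, 8)), seed=1)
        for layer in m._layers():
            if isinstance(layer, (_nn.GlobalContext, _nn.ShiftMLP)):
                layer.W2[...] = rng.standard_normal(layer.W2.shape).astype(
                    np.float32) * 0.3
        x = rng.random((1, 1, 8, 8)).astype(np.float32)
        y = rng.random((1, 5, 8, 8)).astype(np.float32)

        def loss():
            return float(np.mean((m._forward(x, True) - y) ** 2))

        pred = m._forward(x, True)
        _, dgrad = _nn.mse_loss(pred, y)
        m._backward(dgrad)
        worst = 0.0
        for layer in m._layers():
            for name, p in layer.params().items():
                g = layer.grads()[name].ravel()
                flat = p.ravel()
                for k in rng.choice(flat.size, min(3, flat.size),
                                    replace=False):
                    eps = 1e-2
                    old = flat[k]
                    flat[k] = old + eps
                    lp = loss()
                    flat[k] = old - eps
                    lm = loss()
                    flat[k] = old
                    num = (lp - lm) / (2 * eps)
                    ana = g[k]
                    if max(abs(num), abs(ana)) > 1e-5:
                        worst = max(worst,
                                    abs(num - ana) / max(abs(num), abs(ana)))
        assert worst < 1e-2

    def test_channel_warp_shifts_content(self):
        v = np.zeros((1, 8, 2, 2), dtype=np.float32)
        v[0, 3] = 1.0
        out, _ = _nn.warp_channels(v, np.array([2.0], dtype=np.float32))
        assert out[0, 5].sum() == pytest.approx(4.0)
        assert out[0, 3].sum() == pytest.approx(0.0)


class TestBuild:
    def test_same_seed_identical_weights(self):
        a = LocalizerToVolumeModel(TOY, seed=5)
        b = LocalizerToVolumeModel(TOY, seed=5)
        for la, lb in zip(a._layers(), b._layers()):
            for name in la.params():
                assert np.array_equal(la.params()[name], lb.params()[name])
        x = np.random.default_rng(0).random((16, 16)).astype(np.float32)
        assert np.array_equal(a.predict_array(x), b.predict_array(x))

    def test_parameter_count_depth1_matches_hand_formula(self):
        cfg = ModelConfig(depth=1, base_channels=4, output_ap_bins=8,
                          input_shape=(8, 8), global_context=False,
                          shift_head=False)
        m = LocalizerToVolumeModel(cfg, seed=0)
        c = 4
        encoder = (1 * 9 * c + c) + 2 * c          # conv + BN
        bneck = 2 * ((c * 9 * c + c) + 2 * c)      # two conv+BN blocks
        dec = ((c + 1) * 9 * c + c) + 2 * c + (c * 9 * c + c) + 2 * c
        head = (c * 9 * 2 * c + 2 * c) + 2 * (2 * c) + (2 * c * 8 + 8)
        assert m.parameter_count() == encoder + bneck + dec + head

    def test_bottleneck_reduction_and_padding(self):
        cfg = ModelConfig(depth=5, base_channels=2, output_ap_bins=8,
                          input_shape=(144, 64))
        assert cfg.padded_shape() == (160, 64)  # 144 padded to 32 | 160
        m = LocalizerToVolumeModel(cfg, seed=0)
        x = np.zeros((1, 1, 160, 64), dtype=np.float32)
        h = x
        for enc in m.encoders:
            h = enc.forward(h, training=False)
        assert h.shape[-2:] == (160 // 32, 64 // 32)

    def test_wrong_input_shape_rejected(self):
        m = LocalizerToVolumeModel(TOY, seed=0)
        with pytest.raises(ValueError, match="input"):
            m.predict_array(np.zeros((10, 10), dtype=np.float32))


class TestTraining:
    def test_single_pair_overfit(self, standard_pair):
        """Memorization oracle: one pair, 200 epochs, reconstruction MSE
        below 1e-3."""
        cfg = ModelConfig(depth=2, base_channels=32, output_ap_bins=32,
                          input_shape=(24, 16))
        m = LocalizerToVolumeModel(cfg, seed=0)
        res = m.fit([standard_pair],
                    TrainConfig(epochs=200, seed=0, learning_rate=1e-2))
        assert res.final_loss < 1e-3
        assert res.loss_history[-1] < res.loss_history[0]

    def test_zero_epochs_leaves_model_unchanged(self, standard_pair):
        m = LocalizerToVolumeModel(TOY.__class__(depth=2, base_channels=4,
                                                 output_ap_bins=32,
                                                 input_shape=(24, 16)),
                                   seed=0)
        before = {id(l): {k: v.copy() for k, v in l.params().items()}
                  for l in m._layers()}
        res = m.fit([standard_pair], TrainConfig(epochs=0, seed=0))
        assert res.loss_history == []
        for l in m._layers():
            for k, v in l.params().items():
                assert np.array_equal(v, before[id(l)][k])

    def test_training_is_deterministic(self, standard_pair):
        cfg = ModelConfig(depth=2, base_channels=4, output_ap_bins=32,
                          input_shape=(24, 16))
        hist = []
        for _ in range(2):
            m = LocalizerToVolumeModel(cfg, seed=3)
            res = m.fit([standard_pair],
                        TrainConfig(epochs=3, seed=1, learning_rate=1e-3))
            hist.append(res.loss_history)
        assert hist[0] == hist[1]

    def test_nan_loss_aborts_with_diagnostics(self, standard_pair):
        bad = TrainingPair(localizer_in=standard_pair.localizer_in,
                           volume_out=np.full_like(standard_pair.volume_out,
                                                   np.nan),
                           crop_record=standard_pair.crop_record,
                           case_id="poisoned")
        cfg = ModelConfig(depth=2, base_channels=4, output_ap_bins=32,
                          input_shape=(24, 16))
        m = LocalizerToVolumeModel(cfg, seed=0)
        with pytest.raises(RuntimeError, match="poisoned"):
            m.fit([bad], TrainConfig(epochs=1, seed=0))

    def test_mixed_shapes_rejected(self, standard_pair):
        other = TrainingPair(
            localizer_in=np.zeros((12, 8), dtype=np.float32),
            volume_out=np.zeros((32, 12, 8), dtype=np.float32),
            crop_record=standard_pair.crop_record)
        m = LocalizerToVolumeModel(ModelConfig(depth=2, base_channels=4,
                                               output_ap_bins=32,
                                               input_shape=(24, 16)), seed=0)
        with pytest.raises(ValueError, match="mixed"):
            m.fit([standard_pair, other], TrainConfig(epochs=1))


class TestPredictionAndCheckpoint:
    @staticmethod
    @pytest.fixture(scope="class")
    def overfit_model(standard_pair):
        cfg = ModelConfig(depth=2, base_channels=32, output_ap_bins=32,
                          input_shape=(24, 16))
        m = LocalizerToVolumeModel(cfg, seed=0)
        m.fit([standard_pair],
              TrainConfig(epochs=200, seed=0, learning_rate=1e-2))
        return m

    def test_overfit_prediction_recovers_body_bbox(self, overfit_model,
                                                   standard_pair,
                                                   standard_case):
        pred = overfit_model.predict_volume(standard_pair.localizer_in,
                                            standard_pair.crop_record)
        rep_dl = measure_centerlines(pred, source="predicted")
        rep_gt = measure_centerlines(standard_case.volume)
        tol = max(pred.grid.spacing)
        assert abs(rep_dl.body_bbox.anterior_limit
                   - rep_gt.body_bbox.anterior_limit) <= tol
        assert abs(rep_dl.body_bbox.posterior_limit
                   - rep_gt.body_bbox.posterior_limit) <= tol

    def test_prediction_grid_mm_frame(self, overfit_model, standard_pair,
                                      standard_case):
        pred = overfit_model.predict_volume(standard_pair.localizer_in,
                                            standard_pair.crop_record)
        src = standard_case.volume.grid
        assert pred.grid.coords(0)[0] == pytest.approx(src.coords(0)[0])
        assert pred.grid.coords(0)[-1] == pytest.approx(src.coords(0)[-1])
        assert pred.voxels.min() >= 0.0 and pred.voxels.max() <= 1.0

    def test_checkpoint_roundtrip(self, overfit_model, standard_pair,
                                  tmp_path):
        path = tmp_path / "model.npz"
        overfit_model.preprocess_hash = "abc123"
        overfit_model.save(path)
        loaded = LocalizerToVolumeModel.load(path)
        a = overfit_model.predict_array(standard_pair.localizer_in)
        b = loaded.predict_array(standard_pair.localizer_in)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError, match="preprocess"):
            LocalizerToVolumeModel.load(path,
                                        expected_preprocess_hash="zzz")


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=-1)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
    with pytest.raises(ValueError):
        TrainConfig(loss="perceptual")
    with pytest.raises(ValueError):
        TrainConfig(augmentation="flips")
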