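"""Classifier architecture and behavior tests."""

import numpy as np
import pytest

from radarcough.config import ModelConfig, TrainConfig
from radarcough.model import (CoughClassifier, ce_loss, load_checkpoint,
                              save_checkpoint)
from radarcough.nn import Adam, BasicBlock, Conv2d, softmax_cross_entropy
from radarcough.simulate import sample_motion_profile, synthesize_cube
from radarcough.pipeline import preprocess, standardize


@pytest.fixture(scope="module")
def tiny():
    cfg = ModelConfig(spatial_backbone="resnet18", base_channels=4,
                      feature_dim=64, ffn_hidden_dim=128)
    return CoughClassifier(cfg, rng=0)


class TestArchitectureInventory:
    def test_default_trunk_is_standard_34_layer_layout(self):
        """Stem + 16 basic blocks (3,4,6,3) with a 1-channel stem and no
        classification head; the 512->256 projection is the only addition."""
        model = CoughClassifier(ModelConfig(), rng=0)
        trunk = model.trunk
        convs = trunk.conv_layers()
        blocks = [m for m in trunk.modules() if isinstance(m, BasicBlock)]
        stem = convs[0]
        assert stem.in_channels == 1 and stem.kernel_size == 7 and stem.stride == 2
        assert len(blocks) == 16
        # 1 stem + 32 block convs + 3 downsample projections
        assert len(convs) == 36
        widths = [b.conv1.out_channels for b in blocks]
        assert widths == [64] * 3 + [128] * 4 + [256] * 6 + [512] * 3
        assert trunk.out_dim == 512
        assert model.proj.in_features == 512 and model.proj.out_features == 256
        assert model.head.in_features == 256 and model.head.out_features == 2

    def test_reduced_backbone_block_count(self, tiny):
        blocks = [m for m in tiny.trunk.modules() if isinstance(m, BasicBlock)]
        assert len(blocks) == 8  # (2, 2, 2, 2)

    def test_feature_dim_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(feature_dim=250, num_heads=4)


class TestSpatialFeatures:
    def test_output_shape_full_and_short_sequences(self, tiny, rng):
        for t in (35, 20):
            x = rng.normal(size=(t, 1, 48, 125)).astype(np.float32)
            f = tiny.spatial_features(x)
            assert f.shape == (t, 64)
            assert np.isfinite(f).all()

    def test_identical_frames_identical_rows(self, tiny, rng):
        frame = rng.normal(size=(1, 1, 48, 125)).astype(np.float32)
        x = np.repeat(frame, 6, axis=0)
        tiny.eval()
        f = tiny.spatial_features(x)
        tiny.train()
        np.testing.assert_allclose(f, f[0][None].repeat(6, axis=0), atol=1e-5)

    def test_wrong_channel_count_rejected(self, tiny, rng):
        with pytest.raises(ValueError):
            tiny.spatial_features(rng.normal(size=(5, 3, 48, 125)))


class TestTemporalFeatures:
    def test_shape_contract(self, tiny, rng):
        f = rng.normal(size=(35, 64)).astype(np.float32)
        h = tiny.temporal_features(f)
        assert h.shape == (35, 64)

    def test_permutation_equivariance_without_positions(self, rng):
        cfg = ModelConfig(spatial_backbone="resnet18", base_channels=4,
                          feature_dim=32, ffn_hidden_dim=64,
                          positional_encoding="none")
        model = CoughClassifier(cfg, rng=1)
        f = rng.normal(size=(10, 32)).astype(np.float64)
        perm = rng.permutation(10)
        h = model.temporal_features(f)
        h_perm = model.temporal_features(f[perm])
        np.testing.assert_allclose(h_perm, h[perm], atol=1e-4)

    def test_positional_encoding_breaks_order_invariance(self, rng):
        cfg = ModelConfig(spatial_backbone="resnet18", base_channels=4,
                          feature_dim=32, ffn_hidden_dim=64,
                          positional_encoding="sinusoidal")
        model = CoughClassifier(cfg, rng=1)
        f = rng.normal(size=(10, 32)).astype(np.float64)
        perm = rng.permutation(10)
        pooled = model.pool(model.temporal_features(f))
        pooled_perm = model.pool(model.temporal_features(f[perm]))
        assert not np.allclose(pooled, pooled_perm, atol=1e-3)

    def test_dimension_mismatch_rejected(self, tiny, rng):
        with pytest.raises(ValueError):
            tiny.temporal_features(rng.normal(size=(35, 32)))


class TestPoolAndClassify:
    def test_pool_of_constant_sequence(self):
        v = np.arange(8.0)
        h = np.tile(v, (5, 1))
        np.testing.assert_allclose(CoughClassifier.pool(h), v)

    def test_pool_arithmetic_and_oracle(self, rng):
        h = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        np.testing.assert_allclose(CoughClassifier.pool(h), [0.5, 0.5, 0.0])
        big = rng.normal(size=(35, 256))
        brute = np.array([big[:, j].sum() / 35 for j in range(256)])
        np.testing.assert_allclose(CoughClassifier.pool(big), brute, atol=1e-12)

    def test_pool_empty_rejected(self):
        with pytest.raises(ValueError):
            CoughClassifier.pool(np.zeros((0, 4)))

    def test_classify_symmetry_and_closed_form(self, tiny):
        tiny.head.w.value[...] = 0.0
        tiny.head.b.value[...] = 0.0
        out = tiny.classify(np.ones(64))
        np.testing.assert_allclose(out["probs"], [0.5, 0.5], atol=1e-12)
        # logits [ln 3, 0] -> probabilities [0.75, 0.25]
        tiny.head.b.value[...] = [np.log(3.0), 0.0]
        out = tiny.classify(np.zeros(64))
        np.testing.assert_allclose(out["probs"], [0.75, 0.25], atol=1e-6)
        tiny.head.b.value[...] = 0.0

    def test_probabilities_normalized_on_random_logits(self, rng):
        from radarcough.nn import softmax

        z = rng.normal(scale=10, size=(100, 2))
        p = softmax(z)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all() and (p <= 1).all()


class TestCeLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert ce_loss(probs, [1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_predictor_ln2(self):
        probs = np.full((10, 2), 0.5)
        assert ce_loss(probs, [0, 1] * 5) == pytest.approx(np.log(2), abs=1e-12)

    def test_single_sample_closed_form(self):
        probs = np.array([[0.2, 0.8]])
        assert ce_loss(probs, [1]) == pytest.approx(-np.log(0.8), abs=1e-12)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            ce_loss(np.array([[1.2, -0.2]]), [0])


class TestForward:
    def test_batch_contract_and_determinism(self, tiny, rng):
        x = rng.normal(size=(1, 12, 1, 48, 125)).astype(np.float32)
        batch = np.repeat(x, 4, axis=0)
        tiny.eval()
        logits = tiny.forward(batch)
        tiny.train()
        assert logits.shape == (4, 2)
        for row in logits[1:]:
            np.testing.assert_allclose(row, logits[0], atol=1e-5)

    def test_heterogeneous_shapes_rejected(self, tiny, rng):
        ragged = [rng.normal(size=(12, 1, 48, 125)),
                  rng.normal(size=(10, 1, 48, 125))]
        with pytest.raises(ValueError):
            tiny.forward(ragged)

    def test_gradient_step_decreases_loss(self, rng):
        cfg = ModelConfig(spatial_backbone="resnet18", base_channels=2,
                          feature_dim=16, ffn_hidden_dim=32)
        model = CoughClassifier(cfg, rng=2)
        x = rng.normal(size=(4, 6, 1, 48, 125)).astype(np.float32)
        y = np.array([0, 1, 0, 1])
        opt = Adam(model.parameters(), lr=1e-3)
        logits = model.forward(x)
        loss0, dlogits, _ = softmax_cross_entropy(logits, y)
        model.zero_grad()
        model.backward(dlogits)
        opt.step()
        model.eval()
        loss1, _, _ = softmax_cross_entropy(model.forward(x), y)
        assert loss1 < loss0

    def test_checkpoint_roundtrip(self, tiny, rng, tmp_path):
        x = rng.normal(size=(2, 8, 1, 48, 125)).astype(np.float32)
        tiny.eval()
        before = tiny.forward(x)
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny, extra={"note": "test"})
        restored, extra = load_checkpoint(path)
        restored.eval()
        np.testing.assert_allclose(restored.forward(x), before, atol=1e-6)
        assert extra == {"note": "test"}
        tiny.train()


class TestOverfitSmoke:
    def test_separable_mini_batch_reaches_full_train_accuracy(self):
        """4 cough + 4 non-cough high-SNR recordings are fit within 50 steps."""
        xs, ys = [], []
        for i in range(8):
            activity = "cough" if i < 4 else "breathing"
            rng = np.random.default_rng(100 + i)
            profile = sample_motion_profile(activity, "sitting", rng)
            cube = synthesize_cube(profile, snr_db=30, rng=rng)
            seq = preprocess(cube)
            xs.append(standardize(seq.data).astype(np.float32))
            ys.append(int(activity == "cough"))
        x = np.stack(xs)
        y = np.array(ys)

        cfg = ModelConfig(spatial_backbone="resnet18", base_channels=4,
                          feature_dim=64, ffn_hidden_dim=128)
        model = CoughClassifier(cfg, rng=3)
        opt = Adam(model.parameters(), lr=1e-3)
        reached = False
        for _ in range(50):
            logits = model.forward(x)
            if (logits.argmax(axis=1) == y).all():
                reached = True
                break
            _, dlogits, _ = softmax_cross_entropy(logits, y)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
        assert reached, "training failed to fit 8 separable samples"
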