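"""Self-attention ops, the training layer, augmentation and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from paplite.fixtures import (ClassMorphology, FixtureSpec,
                              generate_image_array)
from paplite.nn import (AttentionConfig, AttentionWeights,
                        AugmentationRanges, TrainingConfig, augment_image,
                        build_attention_model, cross_entropy, flatten_map,
                        multi_head_attention, project_qkv,
                        scaled_dot_attention, train_model, unflatten_map)
from paplite.nn.layers import MultiHeadSelfAttention


def _weights(c, d, rng, w_o=None):
    return AttentionWeights(
        w_q=rng.normal(size=(c, d)), w_k=rng.normal(size=(c, d)),
        w_v=rng.normal(size=(c, d)),
        w_o=w_o if w_o is not None else rng.normal(size=(d, c)))


class TestFlatten:
    def test_single_position_is_channel_vector(self, rng):
        f = rng.normal(size=(1, 1, 6))
        assert np.array_equal(flatten_map(f), f.reshape(1, 6))

    def test_round_trip_and_loop_oracle(self, rng):
        f = rng.normal(size=(2, 3, 4))
        x = flatten_map(f)
        assert x.shape == (6, 4)
        assert np.array_equal(unflatten_map(x, 2, 3), f)
        for i in range(2):
            for j in range(3):
                assert np.array_equal(x[i * 3 + j], f[i, j])


class TestProjections:
    def test_zero_input(self, rng):
        w = _weights(4, 4, rng)
        q, k, v = project_qkv(np.zeros((3, 4)), w)
        assert not q.any() and not k.any() and not v.any()

    def test_identity_projection(self, rng):
        x = rng.normal(size=(3, 4))
        w = _weights(4, 4, rng)
        w.w_q = np.eye(4)
        q, _, _ = project_qkv(x, w)
        assert np.allclose(q, x)

    def test_matches_triple_loop(self, rng):
        x = rng.normal(size=(3, 4))
        w = _weights(4, 4, rng)
        q, _, _ = project_qkv(x, w)
        manual = np.zeros((3, 4))
        for i in range(3):
            for j in range(4):
                for kk in range(4):
                    manual[i, j] += x[i, kk] * w.w_q[kk, j]
        assert np.allclose(q, manual)

    def test_shape_mismatch(self, rng):
        w = _weights(4, 4, rng)
        with pytest.raises(ValueError):
            project_qkv(np.zeros((3, 5)), w)


class TestScaledDotAttention:
    def test_single_row_returns_value(self, rng):
        q = rng.normal(size=(1, 3))
        v = rng.normal(size=(1, 3))
        assert np.allclose(scaled_dot_attention(q, q, v), v)

    def test_zero_keys_give_uniform_weights(self, rng):
        q = rng.normal(size=(5, 3))
        v = rng.normal(size=(5, 3))
        out, w = scaled_dot_attention(q, np.zeros((5, 3)), v,
                                      return_weights=True)
        assert np.allclose(w, 1 / 5)
        assert np.allclose(out, np.tile(v.mean(axis=0), (5, 1)))

    def test_two_by_two_hand_case(self):
        q = np.array([[1.0, 0.0], [0.0, 1.0]])
        k = np.array([[1.0, 0.0], [0.0, 2.0]])
        v = np.array([[1.0, 2.0], [3.0, 4.0]])
        s = q @ k.T / np.sqrt(2)
        # row-wise scalar softmax then weighted value rows
        expected = np.empty((2, 2))
        for i in range(2):
            e = np.exp(s[i] - s[i].max())
            a = e / e.sum()
            expected[i] = a[0] * v[0] + a[1] * v[1]
        assert np.allclose(scaled_dot_attention(q, k, v), expected)

    @settings(deadline=None, max_examples=25)
    @given(arrays(np.float64, (4, 3), elements=st.floats(-5, 5)))
    def test_rows_sum_to_one(self, x):
        _, w = scaled_dot_attention(x, x, x, return_weights=True)
        assert np.allclose(w.sum(axis=1), 1.0)


class TestMultiHead:
    def test_single_head_identity_wo_reduces(self, rng):
        w = _weights(4, 4, rng, w_o=np.eye(4))
        x = rng.normal(size=(5, 4))
        q, k, v = project_qkv(x, w)
        assert np.allclose(multi_head_attention(x, w, 1),
                           scaled_dot_attention(q, k, v))

    def test_permutation_equivariance(self, rng):
        w = _weights(6, 6, rng)
        x = rng.normal(size=(8, 6))
        perm = rng.permutation(8)
        assert np.allclose(multi_head_attention(x[perm], w, 3),
                           multi_head_attention(x, w, 3)[perm])

    def test_two_heads_match_slice_and_stack(self, rng):
        w = _weights(4, 4, rng)
        x = rng.normal(size=(4, 4))
        q, k, v = project_qkv(x, w)
        heads = [scaled_dot_attention(q[:, s], k[:, s], v[:, s])
                 for s in (slice(0, 2), slice(2, 4))]
        expected = np.concatenate(heads, axis=1) @ w.w_o
        assert np.allclose(multi_head_attention(x, w, 2), expected)

    def test_indivisible_heads_rejected(self, rng):
        w = _weights(4, 4, rng)
        with pytest.raises(ValueError):
            multi_head_attention(rng.normal(size=(3, 4)), w, 3)

    def test_head_reorder_with_wo_rows(self, rng):
        """Swapping head slices while permuting W_O rows leaves SA(X) fixed."""
        w = _weights(4, 4, rng)
        x = rng.normal(size=(5, 4))
        base = multi_head_attention(x, w, 2)
        perm = [2, 3, 0, 1]  # swap the two d_k=2 blocks
        swapped = AttentionWeights(w_q=w.w_q[:, perm], w_k=w.w_k[:, perm],
                                   w_v=w.w_v[:, perm], w_o=w.w_o[perm, :])
        assert np.allclose(multi_head_attention(x, swapped, 2), base)

    def test_constant_rows_give_constant_output(self, rng):
        w = _weights(4, 4, rng)
        x = np.tile(rng.normal(size=4), (6, 1))
        out = multi_head_attention(x, w, 2)
        assert np.allclose(out, out[0])
        assert np.allclose(out.mean(axis=0), out[0])


class TestConfigBookkeeping:
    @pytest.mark.parametrize("channels,head_dim", [(1280, 160), (512, 64)])
    def test_published_widths_split_into_8_heads(self, channels, head_dim):
        cfg = AttentionConfig(n_heads=8, channels=channels)
        assert cfg.embed_dim == cfg.n_heads * cfg.head_dim
        assert cfg.head_dim == head_dim

    def test_indivisible_embed_rejected(self):
        with pytest.raises(ValueError):
            AttentionConfig(n_heads=5, channels=16)


class TestTrainingLayer:
    def test_layer_matches_pure_op(self, rng):
        cfg = AttentionConfig(n_heads=2, channels=6)
        layer = MultiHeadSelfAttention(cfg, rng=rng)
        w = AttentionWeights(layer.params["w_q"], layer.params["w_k"],
                             layer.params["w_v"], layer.params["w_o"])
        x = rng.normal(size=(2, 2, 3, 6))
        y = layer.forward(x)
        for b in range(2):
            expected = multi_head_attention(x[b].reshape(6, 6), w, 2)
            assert np.allclose(y[b].reshape(6, 6), expected)


class TestCrossEntropy:
    def test_exact_prediction_zero_loss(self):
        y = np.array([0.0, 1.0, 0.0])
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_is_log_k(self):
        y = np.array([1.0, 0, 0, 0])
        yhat = np.full(4, 0.25)
        assert cross_entropy(y, yhat) == pytest.approx(np.log(4))

    def test_three_class_numeric(self):
        y = np.array([0.0, 0.0, 1.0])
        yhat = np.array([0.2, 0.3, 0.5])
        assert cross_entropy(y, yhat) == pytest.approx(-np.log(0.5))

    def test_bad_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([1.0, 0.0]), np.array([0.9, 0.3]))


class TestModelConstruction:
    def test_unknown_backbone(self):
        with pytest.raises(ValueError):
            build_attention_model("vgg16", 3)

    def test_head_divisibility(self):
        build_attention_model("toy_cnn", 3, n_heads=8)  # 16 / 8 = 2, fine
        with pytest.raises(ValueError):
            build_attention_model("toy_cnn", 3, n_heads=5)

    def test_resnet18_channel_width(self):
        model = build_attention_model("resnet18", 4)
        assert model.channels == 512

    def test_softmax_output_normalised(self, rng):
        model = build_attention_model("toy_cnn", 4, seed=0)
        probs = model.predict_proba(rng.random((2, 32, 32, 3)))
        assert probs.shape == (2, 4)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_save_load_round_trip(self, tmp_path, rng):
        from paplite.nn.models import AttentionCNN

        model = build_attention_model("toy_cnn", 3, seed=1)
        x = rng.random((2, 24, 24, 3))
        model.save(tmp_path / "m.npz")
        clone = AttentionCNN.load(tmp_path / "m.npz")
        assert np.allclose(clone.forward(x), model.forward(x))


class TestAugmentation:
    def identity_ranges(self):
        return AugmentationRanges(scale=(1.0, 1.0), shear_deg=(0.0, 0.0),
                                  reflect_xy=(0.0, 0.0),
                                  rotation_deg=(0.0, 0.0), flip=False)

    def test_identity_ranges_no_change(self, rng):
        img = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
        out = augment_image(img, self.identity_ranges(), rng)
        assert np.array_equal(out, img)

    def test_fixed_seed_reproducible(self, rng):
        img = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
        ranges = AugmentationRanges(scale=(1.0, 1.0), shear_deg=(0.0, 0.0),
                                    reflect_xy=(0.0, 0.0),
                                    rotation_deg=(-90.0, 90.0), flip=False)
        a = augment_image(img, ranges, np.random.default_rng(5))
        b = augment_image(img, ranges, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_pure_reflection_conserves_intensity(self, rng):
        img = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
        ranges = AugmentationRanges(scale=(1.0, 1.0), shear_deg=(0.0, 0.0),
                                    reflect_xy=(0.0, 0.0),
                                    rotation_deg=(0.0, 0.0), flip=True)
        out = augment_image(img, ranges, np.random.default_rng(2))
        assert out.mean() == pytest.approx(img.mean())
        assert np.array_equal(np.sort(out, axis=None),
                              np.sort(img, axis=None))

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            AugmentationRanges(scale=(2.0, 1.0))


class TestTrainingLoop:
    def test_colour_separable_fixture_learns(self):
        morphs = [ClassMorphology(nucleus_radius_mean=40.0,
                                  nucleus_radius_sd=3.0, nc_area_ratio=0.4,
                                  texture_noise=0.02, stain_hue=h)
                  for h in (0.0, 0.5)]  # opposite stain hues
        spec = FixtureSpec(n_classes=2, per_class_counts=[50, 50],
                           image_size=(32, 32), class_morphology=morphs,
                           seed=0)
        images, labels = generate_image_array(spec)
        model = build_attention_model("toy_cnn", 2, seed=0)
        cfg = TrainingConfig(epochs=5, learning_rate=0.01, seed=0)
        history = train_model(model, images, labels, cfg)
        acc = np.mean(model.predict(images) == labels)
        assert acc > 0.9
        assert np.all(np.isfinite(history["loss"]))
        assert np.all(np.isfinite(history["epoch_loss"]))

    def test_same_seed_same_first_epoch_loss(self, small_image_set):
        images, labels = small_image_set
        losses = []
        for _ in range(2):
            model = build_attention_model("toy_cnn", 3, seed=2)
            h = train_model(model, images, labels,
                            TrainingConfig(epochs=1, seed=2))
            losses.append(h["epoch_loss"][0])
        assert losses[0] == losses[1]

    def test_empty_class_rejected(self, small_image_set):
        images, labels = small_image_set
        model = build_attention_model("toy_cnn", 3, seed=0)
        keep = labels != 2
        with pytest.raises(ValueError):
            train_model(model, images[keep], labels[keep],
                        TrainingConfig(epochs=1, seed=0))
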