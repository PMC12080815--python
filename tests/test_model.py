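"""Structural and numerical properties of the vision-transformer model."""

import numpy as np
import pytest

from orchardvit import autodiff as ad
from orchardvit.autodiff import Tensor
from orchardvit.model import (
    OAOMClassifier,
    OAOMConfig,
    OAOMNetwork,
    extract_patches,
    reassemble_patches,
)

TINY = dict(image_size=(12, 12), patch_size=(6, 6), hidden_size=16, num_layers=2,
            num_heads=2, mlp_size=32, head_widths=(16,), num_classes=3, dropout_rate=0.0)


class TestPatchGeometry:
    @pytest.mark.parametrize(
        "size,policy,expected_n",
        [
            ((72, 72), "resize", 144),  # divisible: N = H*W / (Ph*Pw)
            ((70, 70), "crop", 121),  # floor(70/6)^2
            ((70, 70), "resize", 144),  # 70 -> 72 (nearest multiple)
            ((6, 6), "crop", 1),
        ],
    )
    def test_patch_counts(self, size, policy, expected_n):
        cfg = OAOMConfig(image_size=size, patch_size=(6, 6), boundary_policy=policy,
                         num_classes=2)
        assert cfg.num_patches == expected_n

    def test_single_patch_equals_image(self, rng):
        img = rng.random((6, 6, 3))
        cfg = OAOMConfig(image_size=(6, 6), patch_size=(6, 6), num_classes=2)
        seq = extract_patches(img, cfg)
        assert seq.patches.shape == (1, 6, 6, 3)
        np.testing.assert_array_equal(seq.patches[0], img)

    def test_tiling_lossless_under_crop(self, rng):
        img = rng.random((70, 70, 3))
        cfg = OAOMConfig(image_size=(70, 70), patch_size=(6, 6), boundary_policy="crop",
                         num_classes=2)
        seq = extract_patches(img, cfg)
        np.testing.assert_array_equal(reassemble_patches(seq), img[:66, :66])

    def test_image_smaller_than_patch_rejected(self, rng):
        cfg = OAOMConfig(image_size=(12, 12), patch_size=(6, 6), num_classes=2)
        with pytest.raises(ValueError):
            extract_patches(rng.random((4, 4, 3)), cfg)

    def test_row_major_positions(self, rng):
        cfg = OAOMConfig(image_size=(12, 18), patch_size=(6, 6), num_classes=2)
        seq = extract_patches(rng.random((12, 18, 3)), cfg)
        assert seq.grid_shape == (2, 3)
        np.testing.assert_array_equal(seq.positions, np.arange(1, 7))


class TestEmbedding:
    def test_zero_weights_make_all_tokens_equal_bias(self, rng):
        net = OAOMNetwork(OAOMConfig(**TINY), seed=0)
        net.params["proj_w"].data[:] = 0.0
        net.params["pos"].data[:] = 0.0
        net.params["proj_b"].data[:] = 3.0
        out = net.embed(rng.random((1, 12, 12, 3)))
        np.testing.assert_allclose(out.data[0, 1:], 3.0)

    def test_identical_patches_differ_only_by_positional_encoding(self):
        net = OAOMNetwork(OAOMConfig(**TINY), seed=0)
        img = np.tile(np.full((6, 6, 3), 0.5), (2, 2, 1))  # 4 identical patches
        out = net.embed(img[None])
        pos = net.params["pos"].data
        diff = out.data[0, 1] - out.data[0, 2]
        np.testing.assert_allclose(diff, pos[0] - pos[1], atol=1e-12)

    def test_output_length_and_width(self, rng):
        cfg = OAOMConfig(**{**TINY, "image_size": (24, 24)})
        net = OAOMNetwork(cfg, seed=0)
        out = net.embed(rng.random((2, 24, 24, 3)))
        assert out.shape == (2, cfg.num_patches + 1, cfg.hidden_size)


class TestAttention:
    def test_single_token_attention_weight_is_one(self):
        """softmax of one logit == [[1.0]]; output equals the value projection."""
        cfg = OAOMConfig(**TINY)
        net = OAOMNetwork(cfg, seed=0)
        x = Tensor(np.random.default_rng(0).standard_normal((1, 1, cfg.hidden_size)))
        out = net.attention(x, 0)
        v = x.data @ net.params["v_w0"].data + net.params["v_b0"].data
        expected = v @ net.params["o_w0"].data + net.params["o_b0"].data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_matches_brute_force_single_head(self, rng):
        """Loop-based scaled dot-product attention oracle on 3 tokens."""
        cfg = OAOMConfig(**{**TINY, "num_heads": 1, "head_dim": 5})
        net = OAOMNetwork(cfg, seed=3)
        x = rng.standard_normal((1, 3, cfg.hidden_size))
        out = net.attention(Tensor(x), 0).data[0]

        q = x[0] @ net.params["q_w0"].data + net.params["q_b0"].data
        k = x[0] @ net.params["k_w0"].data + net.params["k_b0"].data
        v = x[0] @ net.params["v_w0"].data + net.params["v_b0"].data
        expected = np.zeros((3, cfg.hidden_size))
        for i in range(3):
            logits = np.array([q[i] @ k[j] / np.sqrt(5) for j in range(3)])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            ctx = sum(w[j] * v[j] for j in range(3))
            expected[i] = ctx @ net.params["o_w0"].data + net.params["o_b0"].data
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_constant_queries_keys_give_uniform_weights(self, rng):
        """With q/k projections zeroed all logits tie, so the context is the
        token-mean of values."""
        cfg = OAOMConfig(**TINY)
        net = OAOMNetwork(cfg, seed=1)
        for nm in ("q_w0", "q_b0", "k_w0", "k_b0"):
            net.params[nm].data[:] = 0.0
        x = rng.standard_normal((1, 4, cfg.hidden_size))
        out = net.attention(Tensor(x), 0).data
        v = x[0] @ net.params["v_w0"].data + net.params["v_b0"].data
        mean_ctx = v.mean(axis=0) @ net.params["o_w0"].data + net.params["o_b0"].data
        np.testing.assert_allclose(out[0], np.tile(mean_ctx, (4, 1)), atol=1e-10)


class TestEncoderAndForward:
    def test_zero_weight_block_is_identity(self, rng):
        net = OAOMNetwork(OAOMConfig(**TINY), seed=0)
        for nm, t in net.params.items():
            if nm.startswith(("q_", "k_", "v_", "o_", "ff")):
                t.data[:] = 0.0
        x = rng.standard_normal((2, 5, 16))
        out = net.encoder_block(Tensor(x), 0)
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_shape_conserved_through_blocks(self, rng):
        net = OAOMNetwork(OAOMConfig(**TINY), seed=0)
        x = Tensor(rng.standard_normal((2, 5, 16)))
        for l in range(2):
            x = net.encoder_block(x, l)
            assert x.shape == (2, 5, 16)

    def test_reference_size_constructs_and_conserves_shape(self):
        """12 layers, hidden 790, 12 heads, mlp 3092 — construction only."""
        cfg = OAOMConfig(image_size=(70, 70), patch_size=(6, 6), hidden_size=790,
                         num_layers=12, num_heads=12, mlp_size=3092, num_classes=85)
        assert cfg.head_dim == 65  # floor(790/12): width not divisible by heads
        net = OAOMNetwork(cfg, seed=0)
        x = Tensor(np.zeros((1, 3, 790)))
        out = net.encoder_block(x, 11)
        assert out.shape == (1, 3, 790)

    def test_softmax_normalization_random_configs(self, rng):
        for _ in range(10):
            cfg = OAOMConfig(
                image_size=(12, 12), patch_size=(6, 6),
                hidden_size=int(rng.integers(8, 24)), num_layers=int(rng.integers(1, 3)),
                num_heads=int(rng.integers(1, 3)), mlp_size=int(rng.integers(8, 32)),
                num_classes=int(rng.integers(2, 6)), dropout_rate=0.0,
            )
            net = OAOMNetwork(cfg, seed=int(rng.integers(1000)))
            proba = net.predict_proba(rng.random((3, 12, 12, 3)))
            assert np.all(proba > 0) and np.all(proba < 1)
            np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_cls_output_invariant_to_patch_permutation_without_positions(self, rng):
        net = OAOMNetwork(OAOMConfig(**TINY), seed=2)
        net.params["pos"].data[:] = 0.0
        img = rng.random((12, 12, 3))
        base = net.predict_proba(img[None])[0]
        cfg = net.config
        seq = extract_patches(img, cfg)
        for perm in ([1, 0, 3, 2], [3, 2, 1, 0], [2, 0, 3, 1]):
            seq_p = type(seq)(seq.patches[perm], seq.positions, seq.grid_shape)
            img_p = reassemble_patches(seq_p)
            np.testing.assert_allclose(net.predict_proba(img_p[None])[0], base, atol=1e-5)

    def test_learned_positions_break_permutation_invariance(self, rng):
        net = OAOMNetwork(OAOMConfig(**TINY), seed=2)
        net.params["pos"].data *= 50.0  # make the positional signal dominate
        img = rng.random((12, 12, 3))
        seq = extract_patches(img, net.config)
        seq_p = type(seq)(seq.patches[[3, 2, 1, 0]], seq.positions, seq.grid_shape)
        a = net.predict_proba(img[None])[0]
        b = net.predict_proba(reassemble_patches(seq_p)[None])[0]
        assert np.abs(a - b).max() > 1e-8

    def test_inference_deterministic(self, rng):
        net = OAOMNetwork(OAOMConfig(**{**TINY, "dropout_rate": 0.3}), seed=0)
        X = rng.random((2, 12, 12, 3))
        np.testing.assert_array_equal(net.predict_proba(X), net.predict_proba(X))


class TestClassifierEstimator:
    def test_sklearn_params_roundtrip(self):
        est = OAOMClassifier(hidden_size=24, gamma=1.5)
        params = est.get_params()
        assert params["hidden_size"] == 24 and params["gamma"] == 1.5
        est.set_params(dv=3.0)
        assert est.dv == 3.0

    def test_fit_predict_shapes_and_labels(self, tiny_arrays):
        X, y, Xt, yt, names = tiny_arrays
        est = OAOMClassifier(image_size=(12, 12), hidden_size=16, num_layers=1,
                             num_heads=2, mlp_size=32, head_widths=(16,),
                             epochs=2, seed=0)
        est.fit(X, np.array(names)[y])  # string labels
        pred = est.predict(Xt)
        assert set(pred) <= set(names)
        proba = est.predict_proba(Xt)
        assert proba.shape == (len(Xt), 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_checkpoint_roundtrip(self, tiny_arrays, tmp_path):
        X, y, Xt, _, _ = tiny_arrays
        est = OAOMClassifier(image_size=(12, 12), hidden_size=16, num_layers=1,
                             num_heads=2, mlp_size=32, head_widths=(16,),
                             epochs=1, seed=0)
        est.fit(X, y)
        path = tmp_path / "ckpt.npz"
        est.save(path)
        loaded = OAOMClassifier.load(path)
        np.testing.assert_array_equal(loaded.predict_proba(Xt), est.predict_proba(Xt))
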