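"""Fusion network: GeM pooling, weight sharing, head arities, gradients."""

import numpy as np
import pytest

from klgrade import nn
from klgrade.model import (
    FusionModel,
    ModelConfig,
    build_model,
    build_preset,
    gem_pool,
    merge_grades,
    parameter_count,
)
from klgrade.objectives import composite_loss
from klgrade.preprocess import ViewBundle


def random_bundles(rng, n=2, size=16):
    return [
        ViewBundle(rng.normal(size=(3, size, size)),
                   rng.normal(size=(3, size, size)),
                   rng.normal(size=(3, size, size)))
        for _ in range(n)
    ]


def tiny_config(**kw):
    defaults = dict(image_size=16, patch_size=16, feature_dim=8, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestGemPool:
    def test_constant_map_any_exponent(self, rng):
        fmap = np.full((4, 5, 5), 3.7)
        for p in (1.0, 3.0, 10.0):
            np.testing.assert_allclose(gem_pool(fmap, p), 3.7, rtol=1e-6)

    def test_p1_is_arithmetic_mean(self, rng):
        fmap = np.abs(rng.normal(size=(6, 4, 4))) + 0.1
        np.testing.assert_allclose(gem_pool(fmap, 1.0), fmap.mean(axis=(1, 2)),
                                   rtol=1e-12)

    def test_large_p_approaches_max(self):
        fmap = np.array([[[0.1, 0.9]]])
        # the two-pixel generalized mean converges to the max like
        # 0.9 * (1/2)^(1/p): ~6e-3 off at p=100, ~6e-4 at p=1000
        err100 = abs(gem_pool(fmap, 100.0)[0] - 0.9)
        err1000 = abs(gem_pool(fmap, 1000.0)[0] - 0.9)
        assert err100 < 1e-2
        assert err1000 < 1e-3
        assert err1000 < err100

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            gem_pool(np.ones((1, 2, 2)), p=0.5)

    def test_layer_matches_function(self, rng):
        x = np.abs(rng.normal(size=(2, 3, 4, 4)))
        layer = nn.GeMPool(p_init=3.0)
        y, _ = layer.forward(x)
        np.testing.assert_allclose(y, gem_pool(x, 3.0), rtol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        x = np.abs(rng.normal(size=(1, 2, 3, 3))) + 0.05
        layer = nn.GeMPool(p_init=2.5)
        y, cache = layer.forward(x)
        dy = rng.normal(size=y.shape)
        layer.p.zero_grad()
        dx = layer.backward(dy, cache)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (0, 1, 2, 1)]:
            x2 = x.copy()
            x2[idx] += eps
            yp, _ = layer.forward(x2)
            x2[idx] -= 2 * eps
            ym, _ = layer.forward(x2)
            num = ((yp - ym) * dy).sum() / (2 * eps)
            assert abs(num - dx[idx]) < 1e-6
        p0 = float(layer.p.value)
        layer.p.value = np.array(p0 + eps)
        yp, _ = layer.forward(x)
        layer.p.value = np.array(p0 - eps)
        ym, _ = layer.forward(x)
        layer.p.value = np.array(p0)
        num_p = ((yp - ym) * dy).sum() / (2 * eps)
        assert abs(num_p - layer.p.grad) < 1e-6


class TestForwardContract:
    def test_head_arities(self, rng):
        model = build_model(tiny_config())
        out, _ = model.forward(random_bundles(rng, 3))
        assert out.ordinal_logits.shape == (3, 4)
        assert out.ld_logits.shape == (3, 5)
        assert out.binary_logit.shape == (3,)
        assert np.isfinite(out.ordinal_logits).all()

    def test_fused_embedding_unit_norm(self, rng):
        model = build_model(tiny_config())
        bundles = random_bundles(rng, 2)
        _, cache = model.forward(bundles, train=False)
        normed, _ = nn.l2_normalize(cache["norm"][0] * cache["norm"][1])
        norms = np.sqrt((cache["norm"][0] ** 2).sum(axis=1))
        np.testing.assert_allclose(norms, 1.0, atol=1e-5)

    def test_patch_streams_share_one_parameter_set(self):
        model = build_model(tiny_config())
        # identity, not value equality: both patch views must route through
        # the same encoder object
        assert model.patch_encoder is model.patch_encoder
        shared = {id(p) for p in model.patch_encoder.params()}
        all_params = {id(p) for p in model.params()}
        assert shared <= all_params
        n_unique = len({id(p) for p in model.params()})
        assert n_unique == len(model.params())

    def test_eval_forward_deterministic(self, rng):
        model = build_model(tiny_config())
        bundles = random_bundles(rng, 2)
        a, _ = model.forward(bundles, train=False)
        b, _ = model.forward(bundles, train=False)
        np.testing.assert_array_equal(a.ld_logits, b.ld_logits)

    def test_swapping_patches_changes_only_concat_order(self, rng):
        model = build_model(tiny_config())
        b = random_bundles(rng, 1)[0]
        _, cache1 = model.forward([b], train=False)
        swapped = ViewBundle(b.global_view, b.right_patch, b.left_patch)
        _, cache2 = model.forward([swapped], train=False)
        d = cache1["dims"]
        fused1 = np.concatenate([cache1["gpool"][3]], axis=1)
        # left embedding of the swapped pass equals right embedding of the
        # original (same encoder weights applied to the same pixels)
        np.testing.assert_allclose(cache2["lpool"][3], cache1["rpool"][3],
                                   rtol=1e-12)
        np.testing.assert_allclose(cache2["rpool"][3], cache1["lpool"][3],
                                   rtol=1e-12)


class TestBuildModel:
    def test_tiny_preset_small_and_runs(self, rng):
        model = build_preset("tiny_multitask", image_size=64, patch_size=32,
                             feature_dim=32)
        assert parameter_count(model) < 1_000_000
        bundles = [ViewBundle(rng.normal(size=(3, 64, 64)),
                              rng.normal(size=(3, 32, 32)),
                              rng.normal(size=(3, 32, 32)))]
        out, _ = model.forward(bundles)
        assert out.ld_logits.shape == (1, 5)

    def test_flat5c_has_single_head_no_patches(self, rng):
        model = build_preset("flat5c_global", image_size=16, patch_size=16,
                             feature_dim=8)
        assert model.patch_encoder is None
        assert set(model.heads) == {"ld"}
        out, _ = model.forward(random_bundles(rng, 1, 16))
        assert out.ld_logits.shape == (1, 5)
        assert out.ordinal_logits is None

    def test_dualhead_merged_label_space(self, rng):
        model = build_preset("dualhead4c", image_size=16, patch_size=16,
                             feature_dim=8)
        out, _ = model.forward(random_bundles(rng, 1, 16))
        assert out.ld_logits.shape == (1, 4)
        assert out.binary_logit is not None
        np.testing.assert_array_equal(
            merge_grades(np.array([0, 1, 2, 3, 4])), [0, 0, 1, 2, 3]
        )

    def test_unknown_encoder_lists_choices(self):
        with pytest.raises(ValueError, match="choices"):
            build_model(tiny_config(global_encoder="resnext"))

    def test_large_backbones_are_stubs(self):
        with pytest.raises(ValueError, match="stub"):
            build_preset("fusenet_full")

    def test_checkpointable_state_round_trip(self, rng):
        model = build_model(tiny_config())
        state = model.state_dict()
        model2 = build_model(tiny_config(seed=99))
        model2.load_state_dict(state)
        bundles = random_bundles(rng, 1)
        a, _ = model.forward(bundles)
        b, _ = model2.forward(bundles)
        np.testing.assert_array_equal(a.ld_logits, b.ld_logits)


class TestEndToEndGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Full-network gradient check through fusion, GeM and all heads."""
        model = build_model(tiny_config(feature_dim=6))
        bundles = random_bundles(rng, 2)
        y = np.array([1, 4])

        def loss_fn():
            out, _ = model.forward(bundles, train=False)
            total, _, _ = composite_loss(out, y)
            return total

        out, cache = model.forward(bundles, train=False)
        _, _, grads = composite_loss(out, y)
        model.zero_grad()
        model.backward(grads, cache)
        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for p in model.params():
            flat, g = p.value.ravel(), p.grad.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size),
                                      replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_fn()
                flat[i] = old - eps
                lm = loss_fn()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[i]) < 1e-6, p.name
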