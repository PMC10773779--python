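"""Image branch: patch embedding, global/local attention blocks, GLAM
fusion, and the multi-scale forward pass."""

import numpy as np
import pytest

from strokefusion.alam import (FeatureMap, Glam, GlobalAttentionBlock,
                               ImageBranchConfig, LocalAttentionBlock,
                               MultiScaleImageBranch, PatchEmbed, patchify,
                               unpatchify)
from strokefusion.nn import Tensor


def small_config(image_size=32, **kw):
    defaults = dict(image_size=image_size, stage_widths=(4, 8, 8, 8, 8),
                    convs_per_stage=1, embed_dim=8, heads=2)
    defaults.update(kw)
    return ImageBranchConfig(**defaults)


class TestPatchify:
    def test_token_count_224_over_16(self, rng):
        fm = FeatureMap(rng.normal(size=(1, 224, 224)))
        seq = patchify(fm, patch_size=16, embed_dim=8, rng=rng)
        assert seq.tokens.shape == (8, 196)      # L = HW / P^2

    def test_single_patch(self, rng):
        fm = FeatureMap(rng.normal(size=(2, 8, 8)))
        seq = patchify(fm, patch_size=8, embed_dim=4, rng=rng)
        assert seq.tokens.shape[1] == 1

    def test_identity_embedding_token_is_flattened_patch(self, rng):
        patch = rng.normal(size=(1, 2, 2))
        embed = PatchEmbed(1, 2, 4, 1, rng)
        embed.proj.weight.data[:] = np.eye(4)
        embed.proj.bias.data[:] = 0.0
        embed.pos.data[:] = 0.0
        seq = patchify(FeatureMap(patch), 2, 4, embed=embed)
        expected = np.array([patch[0, 0, 0], patch[0, 0, 1],
                             patch[0, 1, 0], patch[0, 1, 1]])
        np.testing.assert_allclose(seq.tokens[:, 0], expected)

    @pytest.mark.parametrize("shape,word", [((1, 5, 4), "height"),
                                            ((1, 4, 5), "width")])
    def test_nondivisible_dimension_named(self, rng, shape, word):
        with pytest.raises(ValueError, match=word):
            patchify(FeatureMap(rng.normal(size=shape)), 2, 4, rng=rng)

    def test_roundtrip_with_identity_embedding(self, rng):
        fm = rng.normal(size=(2, 4, 4))
        embed = PatchEmbed(2, 2, 8, 4, rng)
        embed.proj.weight.data[:] = np.eye(8)
        embed.proj.bias.data[:] = 0.0
        embed.pos.data[:] = 0.0
        seq = patchify(FeatureMap(fm), 2, 8, embed=embed)
        back = unpatchify(seq.tokens, patch_size=2, channels=2,
                          source_hw=(4, 4))
        np.testing.assert_allclose(back, fm)


class TestGlobalAttentionBlock:
    def test_zeroed_sublayers_is_exact_identity(self, rng):
        gab = GlobalAttentionBlock(8, 2, rng, zero_sublayers=True)
        x = rng.normal(size=(2, 5, 8))
        np.testing.assert_array_equal(gab(Tensor(x)).data, x)

    def test_shape_preserved(self, rng):
        gab = GlobalAttentionBlock(8, 2, rng)
        x = rng.normal(size=(3, 6, 8))
        assert gab(Tensor(x)).shape == x.shape

    def test_matches_manual_attention_arithmetic(self):
        # single head, D = 2, L = 2, hand-set weights; oracle below uses
        # explicit loops only
        rng = np.random.default_rng(0)
        gab = GlobalAttentionBlock(2, 1, rng, mlp_ratio=2)
        wqkv = np.array([[0.3, -0.2, 0.5, 0.1, 0.4, -0.3],
                         [0.1, 0.6, -0.4, 0.2, -0.1, 0.2]])
        gab.attn.qkv.weight.data[:] = wqkv
        gab.attn.qkv.bias.data[:] = 0.0
        gab.attn.proj.weight.data[:] = np.array([[1.0, -0.5], [0.25, 0.75]])
        gab.attn.proj.bias.data[:] = np.array([0.05, -0.05])
        gab.fc1.weight.data[:] = np.array([[0.2, -0.3, 0.1, 0.4],
                                           [0.5, 0.2, -0.2, 0.3]])
        gab.fc1.bias.data[:] = 0.1
        gab.fc2.weight.data[:] = np.array([[0.3, -0.1], [0.2, 0.4],
                                           [-0.3, 0.2], [0.1, 0.1]])
        gab.fc2.bias.data[:] = 0.0
        x = np.array([[[0.5, -1.0], [1.5, 0.25]]])       # (1, L=2, D=2)

        def ln(v, gamma, beta, eps=1e-5):
            mu = v.mean()
            var = ((v - mu) ** 2).mean()
            return (v - mu) / np.sqrt(var + eps) * gamma + beta

        xn = np.stack([ln(x[0, l], gab.ln1.gamma.data, gab.ln1.beta.data)
                       for l in range(2)])
        q = np.stack([xn[l] @ wqkv[:, 0:2] for l in range(2)])
        k = np.stack([xn[l] @ wqkv[:, 2:4] for l in range(2)])
        v = np.stack([xn[l] @ wqkv[:, 4:6] for l in range(2)])
        att = np.zeros((2, 2))
        for i in range(2):
            scores = np.array([q[i] @ k[j] / np.sqrt(2) for j in range(2)])
            e = np.exp(scores - scores.max())
            att[i] = e / e.sum()
        attended = np.stack([sum(att[i, j] * v[j] for j in range(2))
                             for i in range(2)])
        proj = np.stack(
            [attended[l] @ gab.attn.proj.weight.data
             + gab.attn.proj.bias.data for l in range(2)])
        x1 = x[0] + proj
        x1n = np.stack([ln(x1[l], gab.ln2.gamma.data, gab.ln2.beta.data)
                        for l in range(2)])
        mlp = np.stack(
            [np.maximum(x1n[l] @ gab.fc1.weight.data + gab.fc1.bias.data, 0)
             @ gab.fc2.weight.data + gab.fc2.bias.data for l in range(2)])
        expected = x1 + mlp

        np.testing.assert_allclose(gab(Tensor(x)).data[0], expected,
                                   atol=1e-10)


class TestLocalAttentionBlock:
    def test_saturated_masks_pass_input_through(self, rng):
        lab = LocalAttentionBlock(4, rng)
        for p in lab.parameters():
            p.data[:] = 0.0
        lab.channel.fc2.bias.data[:] = 30.0      # sigmoid(30) ~ 1
        lab.spatial.conv.bias.data[:] = 30.0
        x = rng.normal(size=(1, 4, 6, 6))
        fl, _, _ = lab(Tensor(x))
        np.testing.assert_allclose(fl.data, x, atol=1e-3)

    def test_masks_strictly_in_unit_interval(self, rng):
        lab = LocalAttentionBlock(4, rng)
        for _ in range(100):
            x = Tensor(rng.normal(size=(1, 4, 8, 8)) * 3)
            _, att_c, att_s = lab(x)
            for m in (att_c.data, att_s.data):
                assert np.all(m > 0) and np.all(m < 1)
        assert att_c.shape == (1, 4, 1, 1)       # constant across space
        assert att_s.shape == (1, 1, 8, 8)       # constant across channels

    def test_triple_loop_oracle(self, rng):
        lab = LocalAttentionBlock(3, rng)
        x = rng.normal(size=(1, 3, 4, 4))
        fl, att_c, att_s = lab(Tensor(x))
        for c in range(3):
            for h in range(4):
                for w in range(4):
                    expected = (att_s.data[0, 0, h, w]
                                * att_c.data[0, c, 0, 0] * x[0, c, h, w])
                    assert abs(fl.data[0, c, h, w] - expected) < 1e-12


class TestGlam:
    def _glam(self, rng, channels=2, hw=(4, 4)):
        return Glam(channels, hw, patch_size=2, embed_dim=8, heads=2,
                    rng=rng)

    def test_zeroed_global_pathway_leaves_local_contribution(self, rng):
        glam = self._glam(rng)
        glam.to_map.weight.data[:] = 0.0
        glam.to_map.bias.data[:] = 0.0
        x = rng.normal(size=(1, 2, 4, 4))
        joint = glam(Tensor(x))
        fl = glam._last["fl"].data
        expected = np.einsum("oc,nchw->nohw", glam.fuse.weight.data[:, :, 0, 0],
                             fl) + glam.fuse.bias.data[None, :, None, None]
        np.testing.assert_allclose(joint.data, expected, atol=1e-12)

    def test_joint_shape_matches_input(self, rng):
        glam = self._glam(rng, channels=3, hw=(8, 8))
        x = rng.normal(size=(2, 3, 8, 8))
        assert glam(Tensor(x)).shape == x.shape

    def test_fusion_rule_manual_arithmetic(self, rng):
        glam = self._glam(rng)
        x = rng.normal(size=(1, 2, 4, 4))
        joint = glam(Tensor(x))
        fg = glam._last["fg_map"].data
        fl = glam._last["fl"].data
        w = glam.fuse.weight.data[:, :, 0, 0]
        b = glam.fuse.bias.data
        expected = np.zeros_like(joint.data)
        for o in range(2):
            for c in range(2):
                expected[0, o] += w[o, c] * (fg[0, c] + fl[0, c])
            expected[0, o] += b[o]
        np.testing.assert_allclose(joint.data, expected, atol=1e-10)


class TestMultiScaleForward:
    def test_inference_determinism(self, rng):
        branch = MultiScaleImageBranch(small_config(), np.random.default_rng(2))
        branch.eval()
        x = rng.normal(size=(1, 3, 32, 32))
        np.testing.assert_array_equal(branch(Tensor(x)).data,
                                      branch(Tensor(x)).data)

    def test_f1_length_is_sum_of_tap_widths(self, rng):
        cfg = small_config(stage_widths=(4, 8, 16, 24, 32))
        branch = MultiScaleImageBranch(cfg, np.random.default_rng(2))
        x = rng.normal(size=(2, 3, 32, 32))
        assert branch(Tensor(x)).shape == (2, 16 + 24 + 32)
        assert cfg.feature_dim == 72

    def test_single_scale_no_glam_equals_manual_pooling(self, rng):
        cfg = small_config(multiscale=False, glam=False)
        branch = MultiScaleImageBranch(cfg, np.random.default_rng(2))
        branch.eval()
        x = rng.normal(size=(1, 3, 32, 32))
        f1 = branch(Tensor(x))
        tap = branch.activations["stage4"].data
        np.testing.assert_allclose(f1.data[0], tap[0].mean(axis=(1, 2)),
                                   atol=1e-12)

    def test_incompatible_resolution_raises_at_construction(self):
        cfg = small_config(image_size=48)      # 48 / 16 = 3, odd vs P = 2
        with pytest.raises(ValueError, match="patch"):
            MultiScaleImageBranch(cfg, np.random.default_rng(0))

    @pytest.mark.parametrize("size,n_seeds", [(32, 5), (64, 3), (224, 1)])
    def test_output_finite_across_seeds(self, size, n_seeds):
        # reduced seed count vs the nominal 100-seed sweep (CPU budget)
        cfg = small_config(image_size=size)
        for seed in range(n_seeds):
            branch = MultiScaleImageBranch(cfg, np.random.default_rng(seed))
            branch.eval()
            x = np.random.default_rng(seed + 50).normal(size=(1, 3, size, size))
            assert np.all(np.isfinite(branch(Tensor(x)).data))
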