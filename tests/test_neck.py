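"""Pyramid necks: CEM padding/path contracts, attention-affinity
oracles, FPN/AC-FPN toggle identity, shape audit and gradient health."""

import numpy as np
import pytest

from chickseg import nn
from chickseg.neck import (CEM, CEMConfig, CnAM, CxAM, NeckConfig, Pyramid,
                           build_pyramid, cnam, cxam)
from chickseg.nn import Tensor


class TestCEM:
    @pytest.mark.parametrize("hw", [(8, 8), (25, 25), (16, 32)])
    def test_output_spatial_size_preserved(self, rng, hw):
        cfg = CEMConfig(dilations=(3, 6, 12), inner_channels=8)
        mod = CEM(4, cfg, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 4, *hw)).astype(np.float32))
        with nn.no_grad():
            out = mod(x)
        assert out.shape == (1, 8, *hw)

    def test_coarse_path_isolation(self, rng):
        """With the dilated path zeroed and the 1x1 fusion wired to pass
        only the coarse channels, CEM reduces to its coarse projection."""
        cfg = CEMConfig(dilations=(1, 2), inner_channels=4)
        mod = CEM(3, cfg, np.random.default_rng(1))
        for blk in mod.blocks:
            blk.conv.weight.data[:] = 0
        n_cat = 2 * 4 + 4
        fuse = np.zeros((4, n_cat, 1, 1), np.float32)
        # coarse output occupies the last 4 concatenated channels
        for i in range(4):
            fuse[i, n_cat - 4 + i, 0, 0] = 1.0
        mod.fuse.weight.data = fuse
        mod.fuse.bias.data[:] = 0
        x = Tensor(rng.normal(size=(1, 3, 6, 6)).astype(np.float32))
        with nn.no_grad():
            out = mod(x)
            coarse = mod.coarse(x)
        assert np.allclose(out.data, coarse.data, atol=1e-6)

    def test_identity_kernel_preserves_impulse(self):
        """Single dilation [1] with identity-initialised kernels keeps a
        centred impulse at the centre (explicit convolution check)."""
        cfg = CEMConfig(dilations=(1,), inner_channels=1,
                        dense_connections=False)
        mod = CEM(1, cfg, np.random.default_rng(2))
        w = np.zeros((1, 1, 3, 3), np.float32)
        w[0, 0, 1, 1] = 1.0
        mod.blocks[0].conv.weight.data = w
        mod.blocks[0].norm.gamma.data[:] = 1
        mod.blocks[0].norm.beta.data[:] = 0
        x = np.zeros((1, 1, 7, 7), np.float32)
        x[0, 0, 3, 3] = 1.0
        with nn.no_grad():
            block_out = nn.relu(mod.blocks[0].norm(
                mod.blocks[0].conv(Tensor(x))))
        # the dilated conv itself is an identity on the impulse
        with nn.no_grad():
            raw = mod.blocks[0].conv(Tensor(x))
        assert np.allclose(raw.data, x, atol=1e-6)
        assert block_out.data[0, 0].argmax() == 3 * 7 + 3

    def test_empty_dilations_rejected(self):
        with pytest.raises(ValueError):
            CEMConfig(dilations=())


def affinity_oracle(q, k, v, latent):
    """Straight-line attention arithmetic on flattened (C, HW) arrays."""
    scale = 1.0 / np.sqrt(latent)
    logits = q.T @ k * scale
    logits -= logits.max(axis=1, keepdims=True)
    aff = np.exp(logits)
    aff /= aff.sum(axis=1, keepdims=True)
    return v @ aff.T, aff


class TestCxAM:
    def test_affinity_rows_sum_to_one(self, rng):
        mod = CxAM(4, 3, np.random.default_rng(5))
        F = rng.normal(size=(4, 3, 3)).astype(np.float32)
        with nn.no_grad():
            q = mod.wq(Tensor(F[None])).data[0].reshape(3, -1)
            k = mod.wk(Tensor(F[None])).data[0].reshape(3, -1)
        _, aff = affinity_oracle(q, k, np.zeros((4, 9)), 3)
        assert np.allclose(aff.sum(axis=1), 1.0, atol=1e-6)

    def test_constant_input_uniform_affinity(self):
        F = np.full((2, 2, 2), 3.0, np.float32)
        wq = np.random.default_rng(1).normal(size=(2, 2)).astype(np.float32)
        wk = np.random.default_rng(2).normal(size=(2, 2)).astype(np.float32)
        wv = np.random.default_rng(3).normal(size=(2, 2)).astype(np.float32)
        out = cxam(F, wq, wk, wv)
        # spatially constant output: attention of a constant map is the
        # uniform average, and the residual is constant too
        assert np.allclose(out, out[:, :1, :1], atol=1e-5)

    def test_hand_oracle_2x2(self, rng):
        F = rng.normal(size=(2, 2, 2)).astype(np.float32)
        wq = rng.normal(size=(3, 2)).astype(np.float32)
        wk = rng.normal(size=(3, 2)).astype(np.float32)
        wv = rng.normal(size=(2, 2)).astype(np.float32)
        got = cxam(F, wq, wk, wv)
        flat = F.reshape(2, 4)
        q = wq @ flat
        k = wk @ flat
        v = wv @ flat
        att, _ = affinity_oracle(q, k, v, 3)
        expected = flat + att
        assert np.allclose(got.reshape(2, 4), expected, atol=1e-5)


class TestCnAM:
    def test_rows_sum_to_one_and_shape(self, rng):
        F = rng.normal(size=(3, 4, 4)).astype(np.float32)
        F5 = rng.normal(size=(5, 4, 4)).astype(np.float32)
        wp = rng.normal(size=(2, 5)).astype(np.float32)
        wz = rng.normal(size=(2, 5)).astype(np.float32)
        out = cnam(F, F5, wp, wz)
        assert out.shape == F.shape

    def test_hand_oracle_2x2(self, rng):
        F = rng.normal(size=(2, 2, 2)).astype(np.float32)
        F5 = rng.normal(size=(3, 2, 2)).astype(np.float32)
        wp = rng.normal(size=(2, 3)).astype(np.float32)
        wz = rng.normal(size=(2, 3)).astype(np.float32)
        got = cnam(F, F5, wp, wz)
        f5_flat = F5.reshape(3, 4)
        p = wp @ f5_flat
        z = wz @ f5_flat
        f_flat = F.reshape(2, 4)
        att, _ = affinity_oracle(p, z, f_flat, 2)
        expected = f_flat + att
        assert np.allclose(got.reshape(2, 4), expected, atol=1e-5)

    def test_misaligned_inputs_rejected(self, rng):
        mod = CnAM(3, 2, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            with nn.no_grad():
                mod(Tensor(rng.normal(size=(1, 2, 4, 4))),
                    Tensor(rng.normal(size=(1, 3, 2, 2))))


class TestPyramid:
    def _feats(self, rng, base=32):
        chans = [16, 32, 64, 128]
        return {f"C{i+2}": rng.normal(size=(c, base >> i, base >> i)
                                      ).astype(np.float32)
                for i, c in enumerate(chans)}

    def test_stride_ladder_and_uniform_width(self, rng):
        feats = self._feats(rng)
        cfg = NeckConfig(type="acfpn", out_channels=24, latent_channels=8)
        p = build_pyramid(feats, cfg)
        assert [p[f"P{i}"].shape for i in range(2, 6)] == \
            [(24, 32, 32), (24, 16, 16), (24, 8, 8), (24, 4, 4)]
        assert p["P6"].shape == (24, 2, 2)

    @pytest.mark.parametrize("chans", [[256, 512, 1024, 2048],
                                       [64, 128, 256, 512]])
    def test_width_256_regardless_of_backbone(self, rng, chans):
        feats = {f"C{i+2}": rng.normal(size=(c, 16 >> i, 16 >> i)
                                       ).astype(np.float32)
                 for i, c in enumerate(chans)}
        p = build_pyramid(feats, NeckConfig(type="fpn"))
        assert all(v.shape[0] == 256 for v in p.values())

    def test_disabled_modules_reduce_to_plain_fpn(self, rng):
        feats = self._feats(rng, base=16)
        cfg_ac = NeckConfig(type="acfpn", out_channels=16,
                            latent_channels=4, seed=7)
        cfg_fpn = NeckConfig(type="fpn", out_channels=16, seed=7)
        ac = Pyramid([16, 32, 64, 128], cfg_ac)
        plain = Pyramid([16, 32, 64, 128], cfg_fpn)
        # identical lateral/smoothing weights by construction (same seed,
        # drawn before the attention modules)
        ac.cem = None
        out_ac = build_pyramid(feats, model=ac)
        out_fpn = build_pyramid(feats, model=plain)
        for k in out_fpn:
            assert np.allclose(out_ac[k], out_fpn[k], atol=1e-6)

    def test_inconsistent_levels_rejected(self, rng):
        feats = self._feats(rng)
        feats["C3"] = feats["C3"][:, :5, :5]
        with pytest.raises(ValueError):
            build_pyramid(feats, NeckConfig(type="fpn", out_channels=8))

    def test_one_step_keeps_parameters_finite(self, rng):
        cfg = NeckConfig(type="acfpn", out_channels=16, latent_channels=4)
        model = Pyramid([16, 32, 64, 128], cfg)
        feats = {k: Tensor(v[None]) for k, v in self._feats(rng,
                                                            16).items()}
        opt = nn.SGD(model.parameters(), lr=0.01)
        loss = sum((v * v).mean() for v in model(feats).values())
        loss.backward()
        opt.step()
        for p in model.parameters():
            assert np.isfinite(p.data).all()
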