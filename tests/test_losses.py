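"""Loss terms: hand-computed values, SSIM against the independent skimage
reference, composite identity and differentiability."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from fsnet import nn
from fsnet.losses import (LossComponents, SsimConfig, bce_loss, composite_loss,
                          gaussian_window, mse_loss, ssim, ssim_loss)


def _skimage_ssim(a, b):
    return structural_similarity(a, b, win_size=11, gaussian_weights=True,
                                 sigma=1.5, use_sample_covariance=False,
                                 data_range=1.0)


class TestMse:
    def test_values(self, rng):
        x = rng.random((2, 1, 4, 4))
        assert float(mse_loss(x, x).data) == 0.0
        assert float(mse_loss(x + 0.1, x).data) == pytest.approx(0.01)
        a = np.array([[0.0, 1.0], [1.0, 0.0]]).reshape(1, 1, 2, 2)
        b = np.array([[1.0, 1.0], [0.0, 0.0]]).reshape(1, 1, 2, 2)
        assert float(mse_loss(a, b).data) == pytest.approx(0.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 4, 5)))


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        a = rng.random((2, 1, 16, 16))
        assert float(ssim(a, a).data) == pytest.approx(1.0, abs=1e-12)
        assert float(ssim_loss(a, a).data) == pytest.approx(0.0, abs=1e-12)

    def test_matches_skimage_reference(self, rng):
        worst = 0.0
        for _ in range(5):
            a, b = rng.random((1, 1, 32, 32)), rng.random((1, 1, 32, 32))
            mine = float(ssim(a, b).data)
            ref = _skimage_ssim(a[0, 0], b[0, 0])
            worst = max(worst, abs(mine - ref))
        assert worst <= 1e-6

    def test_constant_images_closed_form(self):
        a = np.full((1, 1, 32, 32), 0.3)
        b = np.full((1, 1, 32, 32), 0.7)
        c1 = 1e-4
        expected = (2 * 0.3 * 0.7 + c1) / (0.3 ** 2 + 0.7 ** 2 + c1)
        assert float(ssim(a, b).data) == pytest.approx(expected, abs=1e-12)
        assert float(ssim_loss(a, b).data) == pytest.approx(1 - expected, abs=1e-12)

    def test_anticorrelated_structure_exceeds_loss_one(self, rng):
        a = 0.5 + 0.4 * np.sin(np.linspace(0, 8 * np.pi, 32 * 32)).reshape(1, 1, 32, 32)
        b = 1.0 - a
        assert float(ssim(a, b).data) < 0
        assert float(ssim_loss(a, b).data) > 1

    def test_multichannel_reference_averages_modalities(self, rng):
        ref = rng.random((1, 2, 32, 32))
        fused = rng.random((1, 1, 32, 32))
        per = [_skimage_ssim(ref[0, k], fused[0, 0]) for k in range(2)]
        got = float(ssim_loss(ref, fused).data)
        assert got == pytest.approx(1 - np.mean(per), abs=1e-9)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((1, 1, 8, 8)), np.zeros((1, 1, 8, 8)))

    def test_gaussian_window_normalized(self):
        k = gaussian_window(11, 1.5)
        assert k.shape == (11, 11)
        assert k.sum() == pytest.approx(1.0)


class TestBce:
    def test_symmetric_point_is_log_two(self, rng):
        t = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        p = np.full_like(t, 0.5)
        assert float(bce_loss(p, t).data) == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_prediction_hits_clamp_floor(self, rng):
        t = (rng.random((1, 1, 8, 8)) > 0.5).astype(float)
        assert float(bce_loss(t.copy(), t).data) <= 1.001e-7

    def test_single_pixel_value(self):
        got = float(bce_loss(np.array([[[[0.8]]]]), np.array([[[[1.0]]]])).data)
        assert got == pytest.approx(-np.log(0.8))

    def test_non_binary_target_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.full((1, 1, 2, 2), 0.5), np.full((1, 1, 2, 2), 0.3))


class TestComposite:
    def _components(self, mse, ssim_l, bce, eta=0.02, gamma=1.0):
        z = lambda v: nn.Tensor(np.asarray(float(v)))
        total = eta * (z(mse) + z(ssim_l)) + gamma * z(bce)
        return LossComponents(z(mse), z(ssim_l), z(bce), total, eta, gamma)

    def test_weighted_identity(self):
        assert float(self._components(0, 0, 0.5).total.data) == pytest.approx(0.5)
        assert float(self._components(1, 1, 0).total.data) == pytest.approx(0.04)
        assert float(self._components(0.3, 0.2, 0.1, eta=1).total.data) == pytest.approx(0.6)

    def test_eta_scaling_is_linear(self, rng):
        ct = rng.random((1, 1, 16, 16))
        mri = rng.random((1, 1, 16, 16))
        stacked = np.concatenate([ct, mri], axis=1)
        fused = rng.random((1, 1, 16, 16))
        recon = rng.random((1, 2, 16, 16))
        prob = np.clip(rng.random((1, 1, 16, 16)), 0.01, 0.99)
        mask = (rng.random((1, 1, 16, 16)) > 0.5).astype(float)
        c1 = composite_loss(recon, stacked, fused, prob, mask, eta=0.02)
        c2 = composite_loss(recon, stacked, fused, prob, mask, eta=0.04)
        lhs = float(c2.total.data) - float(c2.bce.data)
        rhs = 2 * (float(c1.total.data) - float(c1.bce.data))
        assert lhs == pytest.approx(rhs, rel=1e-12)
        # exact recomposition
        assert float(c1.total.data) == pytest.approx(
            0.02 * (float(c1.mse.data) + float(c1.ssim_loss.data))
            + float(c1.bce.data), rel=1e-12)

    def test_gradient_matches_finite_difference(self, rng, fd):
        stacked = rng.random((1, 2, 16, 16))
        fused_arr = rng.random((1, 1, 16, 16))
        recon_arr = rng.random((1, 2, 16, 16))
        prob_arr = np.clip(rng.random((1, 1, 16, 16)), 0.05, 0.95)
        mask = (rng.random((1, 1, 16, 16)) > 0.5).astype(float)
        fused = nn.Tensor(fused_arr, requires_grad=True)
        recon = nn.Tensor(recon_arr, requires_grad=True)
        prob = nn.Tensor(prob_arr, requires_grad=True)
        comps = composite_loss(recon, stacked, fused, prob, mask)
        comps.total.backward()

        def total_at(kind):
            c = composite_loss(recon_arr, stacked, fused_arr, prob_arr, mask)
            return float(c.total.data)

        for t, arr, idx in ((prob, prob_arr, (0, 0, 3, 4)),
                            (fused, fused_arr, (0, 0, 8, 8)),
                            (recon, recon_arr, (0, 1, 2, 2))):
            approx = fd(lambda: total_at(None), arr, idx)
            assert t.grad[idx] == pytest.approx(approx, abs=1e-4)

    def test_fusion_terms_absent_without_fusion(self, rng):
        prob = np.clip(rng.random((1, 1, 16, 16)), 0.05, 0.95)
        mask = (rng.random((1, 1, 16, 16)) > 0.5).astype(float)
        stacked = rng.random((1, 2, 16, 16))
        comps = composite_loss(None, stacked, None, prob, mask)
        assert float(comps.mse.data) == 0.0
        assert float(comps.ssim_loss.data) == 0.0
        assert float(comps.total.data) == pytest.approx(float(comps.bce.data))
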