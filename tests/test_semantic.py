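"""MS-SSIM and semantic-loss checks against independent oracles.

The windowed statistics are verified against an explicit per-window loop;
the single-scale mean is verified against scikit-image's SSIM, an
implementation developed independently of this package.
"""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as sk_ssim

from constructs.autodiff import Tensor
from constructs.images import Image
from constructs.semantic import (CANONICAL_WEIGHTS, MsSsimConfig,
                                 effective_scales, gaussian_window, ms_ssim,
                                 ms_ssim_tensor, semantic_loss,
                                 semantic_loss_tensor, ssim_maps)

SINGLE = MsSsimConfig(K=1, weights=(1.0,))


def brute_force_maps(x, y, cfg, L=1.0):
    """Per-window loop computing mu, sigma^2, sigma_xy by explicit summation."""
    win = gaussian_window(cfg.window_size, cfg.window_sigma)
    k = cfg.window_size
    C1, C2 = (cfg.K1 * L) ** 2, (cfg.K2 * L) ** 2
    h, w, c = x.shape
    cs = np.zeros((h - k + 1, w - k + 1, c))
    ss = np.zeros_like(cs)
    for ch in range(c):
        for i in range(h - k + 1):
            for j in range(w - k + 1):
                px = x[i:i + k, j:j + k, ch]
                py = y[i:i + k, j:j + k, ch]
                mx, my = (win * px).sum(), (win * py).sum()
                vx = (win * px * px).sum() - mx * mx
                vy = (win * py * py).sum() - my * my
                cxy = (win * px * py).sum() - mx * my
                v1, v2 = 2 * cxy + C2, vx + vy + C2
                cs[i, j, ch] = v1 / v2
                ss[i, j, ch] = ((2 * mx * my + C1) * v1) / ((mx * mx + my * my + C1) * v2)
    return cs, ss


def test_identical_images_give_unit_maps(rng):
    x = rng.random((20, 20, 3))
    cs, ss = ssim_maps(x, x.copy(), SINGLE)
    assert np.allclose(cs, 1.0, atol=1e-6)
    assert np.allclose(ss, 1.0, atol=1e-6)


def test_constant_images_match_symbolic_value():
    """x=0, y=1 with zero variance: cs = 1, ss = C1/(1 + C1)."""
    x = np.zeros((16, 16, 1))
    y = np.ones((16, 16, 1))
    cs, ss = ssim_maps(x, y, SINGLE)
    expected = 1e-4 / (1 + 1e-4)  # (K1*L)^2 = 1e-4
    assert np.allclose(cs, 1.0, atol=1e-12)
    assert np.allclose(ss, expected, atol=1e-8)
    assert abs(ms_ssim(x, y, SINGLE) - expected) < 1e-8


def test_maps_match_brute_force_window_loop(rng):
    x = rng.random((18, 17, 2))
    y = rng.random((18, 17, 2))
    cs, ss = ssim_maps(x, y, SINGLE)
    bcs, bss = brute_force_maps(x, y, SINGLE)
    assert np.abs(cs - bcs).max() < 1e-5
    assert np.abs(ss - bss).max() < 1e-5


def test_single_scale_mean_matches_scikit_image(rng):
    x = rng.random((40, 40))
    y = np.clip(x + 0.15 * rng.standard_normal((40, 40)), 0, 1)
    ours = ms_ssim(x[:, :, None], y[:, :, None], SINGLE)
    ref = sk_ssim(x, y, win_size=11, gaussian_weights=True, sigma=1.5,
                  use_sample_covariance=False, data_range=1.0)
    assert abs(ours - ref) < 1e-9


def test_multiscale_matches_independent_recomputation(rng):
    """Full K-scale value vs. a second, independently coded evaluation built
    on the brute-force maps and plain numpy pyramid."""
    cfg = MsSsimConfig(K=2, weights=(0.3, 0.7))
    x = rng.random((32, 32, 1))
    y = np.clip(x + 0.2 * rng.standard_normal((32, 32, 1)), 0, 1)

    def down(a):
        return a.reshape(a.shape[0] // 2, 2, a.shape[1] // 2, 2, a.shape[2]).mean(axis=(1, 3))

    cs1, _ = brute_force_maps(x, y, cfg)
    _, ss2 = brute_force_maps(down(x), down(y), cfg)
    expected = (max(cs1.mean(), 1e-6) ** 0.3) * (max(ss2.mean(), 1e-6) ** 0.7)
    assert abs(ms_ssim(x, y, cfg) - expected) < 1e-4


def test_identity_and_symmetry_and_bound(rng):
    for _ in range(3):
        x = rng.random((48, 48, 3))
        y = rng.random((48, 48, 3))
        assert abs(ms_ssim(x, x.copy()) - 1.0) < 1e-6
        assert abs(ms_ssim(x, y) - ms_ssim(y, x)) < 1e-6
        assert ms_ssim(x, y) <= 1.0 + 1e-9
        assert ms_ssim(x, y) < 1.0 - 1e-3  # distinct images stay below the bound


def test_monotone_degradation_under_noise(rng):
    x = rng.random((64, 64, 3)) * 0.6 + 0.2
    n = rng.standard_normal(x.shape)
    vals = [ms_ssim(x, np.clip(x + eps * n, 0, 1)) for eps in (0.0, 0.05, 0.1, 0.2)]
    assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
    assert vals[0] == pytest.approx(1.0, abs=1e-6)


def test_semantic_loss_identities(rng):
    x = rng.random((32, 32, 3))
    y = rng.random((32, 32, 3))
    assert semantic_loss(x, x.copy()) < 1e-6
    assert semantic_loss(x, y) == pytest.approx(1.0 - ms_ssim(x, y), abs=0)


def test_semantic_loss_gradient_vanishes_at_match(rng):
    """y = x is a maximum of MS-SSIM, so the loss gradient there is ~0."""
    x = rng.random((1, 1, 24, 24))
    yt = Tensor(x.copy(), requires_grad=True)
    semantic_loss_tensor(Tensor(x), yt, MsSsimConfig(K=1, weights=(1.0,))).backward()
    assert np.abs(yt.grad).max() < 1e-6


def test_scale_reduction_on_small_images():
    cfg = MsSsimConfig()
    k, w = effective_scales(64, 64, cfg)
    assert k == 3 and abs(sum(w) - 1.0) < 1e-12
    k1, w1 = effective_scales(256, 256, cfg)
    assert k1 == 5 and w1 == pytest.approx(CANONICAL_WEIGHTS)


def test_k1_scale_consistency(rng):
    """With K = 1 and unit weight the metric is the spatial mean of the
    luminance-bearing single-scale map."""
    x = rng.random((30, 30, 2))
    y = np.clip(x + 0.2 * rng.standard_normal(x.shape), 0, 1)
    _, ss = ssim_maps(x, y, SINGLE)
    assert ss.mean() > 0  # positively correlated pair keeps the mean off the floor
    assert abs(ms_ssim(x, y, SINGLE) - ss.mean()) < 1e-6


def test_composition_toggle_changes_value(rng):
    x = rng.random((32, 32, 1))
    y = np.clip(x + 0.3 * rng.standard_normal(x.shape), 0, 1)
    canon = ms_ssim(x, y, MsSsimConfig(K=2, weights=(0.5, 0.5)))
    literal = ms_ssim(x, y, MsSsimConfig(K=2, weights=(0.5, 0.5), composition="product"))
    assert canon != pytest.approx(literal, abs=1e-6)


def test_contract_violations():
    x = np.zeros((16, 16, 1))
    with pytest.raises(ValueError, match="shapes differ"):
        ms_ssim(x, np.zeros((16, 17, 1)))
    with pytest.raises(ValueError, match="dynamic ranges"):
        ms_ssim(Image(x, 1.0), Image(np.zeros((16, 16, 1)), 2.0))
    with pytest.raises(ValueError, match="window"):
        ms_ssim(np.zeros((8, 8, 1)), np.zeros((8, 8, 1)))
    with pytest.raises(ValueError, match="outside"):
        ms_ssim(np.full((16, 16, 1), 1.5), np.zeros((16, 16, 1)))


def test_config_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        MsSsimConfig(K=2, weights=(0.5, 0.6))
    with pytest.raises(ValueError, match="odd"):
        MsSsimConfig(window_size=10)
    with pytest.raises(ValueError, match="composition"):
        MsSsimConfig(composition="mystery")


def test_dynamic_range_enters_through_stability_constants():
    """C1 = (K1 L)^2 scales with L: the 0-vs-255 case on an 8-bit range
    reproduces the [0, 1] constant-image value."""
    x = np.zeros((16, 16, 1))
    y = np.full((16, 16, 1), 255.0)
    v255 = ms_ssim(Image(x, 255.0), Image(y, 255.0), SINGLE)
    v1 = ms_ssim(np.zeros((16, 16, 1)), np.ones((16, 16, 1)), SINGLE)
    assert abs(v255 - v1) < 1e-9
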