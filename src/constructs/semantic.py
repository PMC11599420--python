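"""Multi-scale structural similarity (MS-SSIM) and the semantic loss 1 - MS-SSIM.

Local luminance, contrast and structure statistics are taken under a
Gaussian window; the contrast-structure term cs = v1/v2 with
v1 = 2*sigma_xy + C2, v2 = sigma_x^2 + sigma_y^2 + C2 is evaluated at every
scale of a dyadic pyramid, and the luminance-bearing term

    ss = ((2*mu_x*mu_y + C1) * v1) / ((mu_x^2 + mu_y^2 + C1) * v2)

only at the coarsest scale.  The per-scale spatial means, clamped to a small
positive floor, are combined as a weighted geometric product

    MS-SSIM = prod_{i<K} mean(cs_i)^{W_i} * mean(ss_K)^{W_K}

computed per channel and averaged over channels.  C1 = (K1*L)^2 and
C2 = (K2*L)^2 derive from the dynamic range L (canonically 1 for pixels in
[0, 1]).  A literal reading that applies the full cs*ss product at every
scale is available via ``composition="product"`` for comparison.

All arithmetic runs through the autodiff engine, so the loss is
differentiable with respect to either image and can train a generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, avg_pool2d
from .images import Image, as_pixels

#: Canonical per-scale weights for the 5-scale metric, normalised to sum
#: exactly to one (the published constants sum to 1.0001).
_RAW_W = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
CANONICAL_WEIGHTS = tuple(w / sum(_RAW_W) for w in _RAW_W)

_FLOOR = 1e-6  # positive floor for means entering the geometric product


@dataclass
class MsSsimConfig:
    K: int = 5
    weights: tuple = CANONICAL_WEIGHTS
    window_size: int = 11
    window_sigma: float = 1.5
    K1: float = 0.01
    K2: float = 0.03
    composition: str = "canonical"  # or "product" (literal reading)

    def __post_init__(self):
        self.weights = tuple(float(w) for w in self.weights)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.weights) != self.K:
            raise ValueError(f"need {self.K} weights, got {len(self.weights)}")
        if any(w <= 0 for w in self.weights):
            raise ValueError("all scale weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("scale weights must sum to 1")
        if self.window_size % 2 != 1:
            raise ValueError("window_size must be odd")
        if self.window_sigma <= 0:
            raise ValueError("window_sigma must be positive")
        if self.composition not in ("canonical", "product"):
            raise ValueError(f"unknown composition {self.composition!r}")


def gaussian_window1d(size: int, sigma: float) -> np.ndarray:
    """Normalised 1-D Gaussian window of odd length ``size``."""
    r = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(r * r) / (2.0 * sigma * sigma))
    return g / g.sum()


def gaussian_window(size: int, sigma: float) -> np.ndarray:
    """Normalised 2-D Gaussian window (size x size); separable by design."""
    g = gaussian_window1d(size, sigma)
    return np.outer(g, g)


def _band_matrix(n: int, taps: np.ndarray, dtype) -> np.ndarray:
    """(n, n-k+1) banded matrix so x @ B is a valid 1-D correlation."""
    k = taps.size
    m = np.zeros((n, n - k + 1), dtype=dtype)
    for i in range(k):
        m[np.arange(n - k + 1) + i, np.arange(n - k + 1)] = taps[i]
    return m


def _blur(x: Tensor, win1d: np.ndarray) -> Tensor:
    """Separable depthwise valid Gaussian filtering of an NCHW tensor.

    Implemented as two banded matrix products (rows then columns), which the
    autodiff engine differentiates as ordinary matmuls.
    """
    n, c, h, w = x.shape
    k = win1d.size
    bw = Tensor(_band_matrix(w, win1d, x.dtype))
    bh = Tensor(_band_matrix(h, win1d, x.dtype))
    out = x.reshape(n * c * h, w) @ bw                      # filter along W
    out = out.reshape(n * c, h, w - k + 1).transpose(0, 2, 1)
    out = out.reshape(n * c * (w - k + 1), h) @ bh          # filter along H
    out = out.reshape(n * c, w - k + 1, h - k + 1).transpose(0, 2, 1)
    return out.reshape(n, c, h - k + 1, w - k + 1)


def _check_pair(xp: np.ndarray, yp: np.ndarray, Lx: float, Ly: float, window: int):
    if xp.shape != yp.shape:
        raise ValueError(f"image shapes differ: {xp.shape} vs {yp.shape}")
    if abs(Lx - Ly) > 1e-12:
        raise ValueError(f"dynamic ranges differ: {Lx} vs {Ly}")
    if min(xp.shape[0], xp.shape[1]) < window:
        raise ValueError(
            f"image {xp.shape[0]}x{xp.shape[1]} smaller than the {window}-tap window"
        )


def _ssim_tensors(xt: Tensor, yt: Tensor, L: float, cfg: MsSsimConfig):
    """(cs, ss) map Tensors, NCHW with the valid-convolution extent."""
    win = gaussian_window1d(cfg.window_size, cfg.window_sigma)
    C1 = (cfg.K1 * L) ** 2
    C2 = (cfg.K2 * L) ** 2
    mu_x, mu_y = _blur(xt, win), _blur(yt, win)
    mu_xx, mu_yy, mu_xy = mu_x * mu_x, mu_y * mu_y, mu_x * mu_y
    var_x = _blur(xt * xt, win) - mu_xx
    var_y = _blur(yt * yt, win) - mu_yy
    cov = _blur(xt * yt, win) - mu_xy
    v1 = 2.0 * cov + C2
    v2 = var_x + var_y + C2
    cs = v1 / v2
    ss = ((2.0 * mu_xy + C1) * v1) / ((mu_xx + mu_yy + C1) * v2)
    return cs, ss


def ssim_maps(x, y, cfg: MsSsimConfig | None = None, dynamic_range: float = 1.0):
    """Single-scale contrast-sensitivity and structural-similarity maps.

    Parameters
    ----------
    x, y
        :class:`~constructs.images.Image` or H x W (x C) arrays in
        [0, dynamic_range].
    cfg
        Metric configuration; defaults to the canonical constants.

    Returns
    -------
    (cs_map, ss_map)
        H' x W' x C float arrays over the valid window extent,
        H' = H - window_size + 1.
    """
    cfg = cfg or MsSsimConfig()
    Lx = x.dynamic_range if isinstance(x, Image) else dynamic_range
    Ly = y.dynamic_range if isinstance(y, Image) else dynamic_range
    xp, yp = as_pixels(x, Lx), as_pixels(y, Ly)
    _check_pair(xp, yp, Lx, Ly, cfg.window_size)
    xt = Tensor(np.moveaxis(xp.astype(np.float64), -1, 0)[None])
    yt = Tensor(np.moveaxis(yp.astype(np.float64), -1, 0)[None])
    cs, ss = _ssim_tensors(xt, yt, Lx, cfg)
    return (np.moveaxis(cs.data[0], 0, -1), np.moveaxis(ss.data[0], 0, -1))


def effective_scales(h: int, w: int, cfg: MsSsimConfig) -> tuple[int, tuple]:
    """Largest usable scale count for an h x w image, with renormalised weights.

    Scale i (1-based) sees the image halved i-1 times; it is usable while the
    halved side still covers the window.
    """
    k = 1
    while (
        k < cfg.K
        and (min(h, w) // (2 ** k)) >= cfg.window_size
    ):
        k += 1
    wts = np.asarray(cfg.weights[:k], dtype=np.float64)
    return k, tuple(wts / wts.sum())


def _crop_even(t: Tensor) -> Tensor:
    n, c, h, w = t.shape
    if h % 2 == 0 and w % 2 == 0:
        return t
    he, we = h - h % 2, w - w % 2
    arr = t.data[:, :, :he, :we]
    out = Tensor(arr)
    if t.requires_grad:
        # route gradient through a take-style view
        out = t.take(np.arange(he), axis=2).take(np.arange(we), axis=3)
    return out


def ms_ssim_tensor(xt: Tensor, yt: Tensor, cfg: MsSsimConfig, L: float = 1.0) -> Tensor:
    """Differentiable MS-SSIM on NCHW tensors in [0, L]; returns a scalar Tensor."""
    n, c, h, w = xt.shape
    k_eff, weights = effective_scales(h, w, cfg)
    per_channel = None
    for i in range(1, k_eff + 1):
        cs, ss = _ssim_tensors(xt, yt, L, cfg)
        if cfg.composition == "product":
            term = (cs * ss).mean(axis=(0, 2, 3))
        elif i < k_eff:
            term = cs.mean(axis=(0, 2, 3))
        else:
            term = ss.mean(axis=(0, 2, 3))
        factor = term.clamp_min(_FLOOR).pow(weights[i - 1])
        per_channel = factor if per_channel is None else per_channel * factor
        if i < k_eff:
            xt, yt = _crop_even(xt), _crop_even(yt)
            xt, yt = avg_pool2d(xt, 2), avg_pool2d(yt, 2)
    return per_channel.mean()


def ms_ssim(x, y, cfg: MsSsimConfig | None = None, dynamic_range: float = 1.0) -> float:
    """MS-SSIM between two images; 1.0 for identical inputs."""
    cfg = cfg or MsSsimConfig()
    Lx = x.dynamic_range if isinstance(x, Image) else dynamic_range
    Ly = y.dynamic_range if isinstance(y, Image) else dynamic_range
    xp, yp = as_pixels(x, Lx), as_pixels(y, Ly)
    _check_pair(xp, yp, Lx, Ly, cfg.window_size)
    xt = Tensor(np.moveaxis(xp.astype(np.float64), -1, 0)[None])
    yt = Tensor(np.moveaxis(yp.astype(np.float64), -1, 0)[None])
    return float(ms_ssim_tensor(xt, yt, cfg, Lx).item())


def semantic_loss_tensor(xt: Tensor, yt: Tensor, cfg: MsSsimConfig, L: float = 1.0) -> Tensor:
    """1 - MS-SSIM as a differentiable scalar Tensor (inputs in [0, L])."""
    return 1.0 - ms_ssim_tensor(xt, yt, cfg, L)


def semantic_loss(x, y, cfg: MsSsimConfig | None = None, dynamic_range: float = 1.0) -> float:
    """Semantic loss 1 - MS-SSIM(x, y); zero iff the images agree."""
    return 1.0 - ms_ssim(x, y, cfg, dynamic_range=dynamic_range)
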