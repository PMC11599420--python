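"""One-sided X -> Y translation: ResNet generator, patch discriminator and
the adversarial objective.

There is deliberately no Y -> X generator and no cycle-reconstruction term
anywhere in this package — content preservation comes from the contrastive
and structural-similarity losses instead.  The generator exposes encoder
feature taps (layer 0 is the input image itself, then the stem and the two
downsampling stages and the middle of the residual stack) which feed the
patch-contrastive loss.

By default the adversarial objective is trained in its least-squares form
(labels 1 = real, 0 = fake); the saturating log form is available with
``mode="vanilla"``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, no_grad, upsample_nearest2d
from .contrastive import FeatureStack
from .nn import Conv2d, InstanceNorm2d, LeakyReLU, Module, ReLU, Sequential, Tanh

#: encoder tap identifiers: 0=input image, 1=stem, 2=down1, 3=down2, 4=mid-residual
ENCODER_TAPS = (0, 1, 2, 3, 4)


class ResBlock(Module):
    def __init__(self, ch: int):
        self.body = Sequential(
            Conv2d(ch, ch, 3, pad=1, pad_mode="reflect"), InstanceNorm2d(ch), ReLU(),
            Conv2d(ch, ch, 3, pad=1, pad_mode="reflect"), InstanceNorm2d(ch),
        )

    def forward(self, x):
        return x + self.body(x)


class ResnetGenerator(Module):
    """c7s1 stem, two stride-2 downsampling stages, residual trunk, two
    nearest-neighbour upsampling stages, c7s1 output head with tanh."""

    DOWN_FACTOR = 4

    def __init__(self, in_ch: int = 3, out_ch: int = 3, ngf: int = 64, n_blocks: int = 6):
        self.ngf, self.n_blocks = ngf, n_blocks
        self.stem = Sequential(Conv2d(in_ch, ngf, 7, pad=3, pad_mode="reflect"),
                               InstanceNorm2d(ngf), ReLU())
        self.down1 = Sequential(Conv2d(ngf, 2 * ngf, 3, stride=2, pad=1),
                                InstanceNorm2d(2 * ngf), ReLU())
        self.down2 = Sequential(Conv2d(2 * ngf, 4 * ngf, 3, stride=2, pad=1),
                                InstanceNorm2d(4 * ngf), ReLU())
        self.blocks = [ResBlock(4 * ngf) for _ in range(n_blocks)]
        self.up1 = Sequential(Conv2d(4 * ngf, 2 * ngf, 3, pad=1),
                              InstanceNorm2d(2 * ngf), ReLU())
        self.up2 = Sequential(Conv2d(2 * ngf, ngf, 3, pad=1),
                              InstanceNorm2d(ngf), ReLU())
        self.head = Sequential(Conv2d(ngf, out_ch, 7, pad=3, pad_mode="reflect"), Tanh())
        self._mid = max(1, n_blocks // 2)

    def _check_size(self, x):
        h, w = x.shape[2], x.shape[3]
        f = self.DOWN_FACTOR
        if h % f or w % f:
            raise ValueError(
                f"input {h}x{w} not divisible by the network's downsampling factor {f}; "
                f"resize to {h - h % f}x{w - w % f} or pad to a multiple of {f}"
            )

    def encode(self, x: Tensor, tag: str = "") -> FeatureStack:
        """Run the encoder half only and collect the feature taps."""
        self._check_size(x)
        taps = [x]
        h = self.stem(x)
        taps.append(h)
        h = self.down1(h)
        taps.append(h)
        h = self.down2(h)
        taps.append(h)
        for blk in self.blocks[: self._mid]:
            h = blk(h)
        taps.append(h)
        return FeatureStack(taps, source_tag=tag)

    def forward(self, x: Tensor, with_feats: bool = False):
        self._check_size(x)
        taps = [x]
        h = self.stem(x)
        taps.append(h)
        h = self.down1(h)
        taps.append(h)
        h = self.down2(h)
        taps.append(h)
        mid = None
        for i, blk in enumerate(self.blocks):
            h = blk(h)
            if i + 1 == self._mid:
                mid = h
        taps.append(mid if mid is not None else h)
        h = self.up1(upsample_nearest2d(h, 2))
        h = self.up2(upsample_nearest2d(h, 2))
        out = self.head(h)
        if with_feats:
            return out, FeatureStack(taps, source_tag="input")
        return out


class PatchDiscriminator(Module):
    """3-layer PatchGAN emitting a spatial realism score map (logits)."""

    def __init__(self, in_ch: int = 3, ndf: int = 64):
        self.ndf = ndf
        self.net = Sequential(
            Conv2d(in_ch, ndf, 4, stride=2, pad=1, pad_mode="zeros"), LeakyReLU(0.2),
            Conv2d(ndf, 2 * ndf, 4, stride=2, pad=1, pad_mode="zeros"),
            InstanceNorm2d(2 * ndf), LeakyReLU(0.2),
            Conv2d(2 * ndf, 4 * ndf, 4, stride=1, pad=1, pad_mode="zeros"),
            InstanceNorm2d(4 * ndf), LeakyReLU(0.2),
            Conv2d(4 * ndf, 1, 4, stride=1, pad=1, pad_mode="zeros"),
        )
        #: effective receptive field of one output logit, for config logging
        self.receptive_field = 34

    def forward(self, x):
        return self.net(x)


class TranslatorModel(Module):
    """Generator + discriminator pair for one-sided X -> Y translation."""

    def __init__(self, ngf: int = 64, ndf: int = 64, n_blocks: int = 6,
                 rng: np.random.Generator | None = None):
        self.G = ResnetGenerator(ngf=ngf, n_blocks=n_blocks)
        self.D = PatchDiscriminator(ndf=ndf)
        if rng is not None:
            self.G.init_gaussian(rng, 0.02)
            self.D.init_gaussian(rng, 0.02)

    def parameter_counts(self) -> dict:
        return {
            "generator": int(sum(p.data.size for p in self.G.parameters())),
            "discriminator": int(sum(p.data.size for p in self.D.parameters())),
            "discriminator_receptive_field": self.D.receptive_field,
        }


def translate(model: TranslatorModel, x) -> np.ndarray:
    """Map one image (1 x 3 x H x W Tensor/array in [-1, 1]) through G, no grad."""
    arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    with no_grad():
        out = model.G(Tensor(arr))
    return out.data


def _mse(t: Tensor, target: float) -> Tensor:
    d = t - target
    return (d * d).mean()


def gan_losses(model: TranslatorModel, x: Tensor, y: Tensor, mode: str = "lsgan",
               fake: Tensor | None = None):
    """Generator-adversarial and discriminator losses.

    ``fake`` may carry a precomputed G(x) (with tape) to avoid a second
    generator pass; the discriminator loss always sees it detached.
    Returns (loss_G_adv, loss_D) scalar Tensors.
    """
    if mode not in ("lsgan", "vanilla"):
        raise ValueError(f"unknown gan mode {mode!r}")
    if fake is None:
        fake = model.G(x)
    d_real = model.D(y)
    d_fake_det = model.D(fake.detach())
    d_fake = model.D(fake)
    if mode == "lsgan":
        loss_d = _mse(d_real, 1.0) + _mse(d_fake_det, 0.0)
        loss_g = _mse(d_fake, 1.0)
    else:  # log form: D maximises log D(y) + log(1 - D(G(x))) on sigmoid logits
        loss_d = (-d_real).softplus().mean() + d_fake_det.softplus().mean()
        loss_g = (-d_fake).softplus().mean()
    return loss_g, loss_d
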