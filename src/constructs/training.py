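"""Total objective assembly, ablation configurations and the training loop.

The objective is

    L_total = L_GAN + lambda_x * L_Patch(X) + lambda_y * L_Patch(Y)
            + lambda_ss * L_semantic

where L_Patch(X) contrasts patches of G(x) against the co-located patches of
x, L_Patch(Y) applies the same construction to domain-Y images and their own
translations (an identity-style guard against degenerate generators), and
L_semantic = 1 - MS-SSIM between the input and its translation after
rescaling both to [0, 1].  Setting lambda_ss = 0 reverts to the plain
contrastive (CUT-style) objective; lambda_x = lambda_y = 0 removes the patch
terms.

Training alternates a discriminator step on (y, G(x) detached) with a
generator step on the full objective, using Adam with linear LR decay over
the second half of the run.  Every random stream (weight init, data order,
patch sampling) derives from the run seed, and the optimiser and RNG states
ride along in checkpoints so a resumed run reproduces an unbroken one
bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .adversarial import TranslatorModel, _mse
from .autodiff import Tensor
from .contrastive import NceConfig, PatchSampler, patchnce_loss
from .nn import Adam
from .semantic import MsSsimConfig, semantic_loss_tensor

ABLATION_VARIANTS = ("full", "no_semantic", "no_patchnce", "cut")


@dataclass
class LossConfig:
    lambda_x: float = 1.0
    lambda_y: float = 1.0
    lambda_ss: float = 1.0
    gan_mode: str = "lsgan"
    semantic_pair: str = "input_translation"  # or "identity_translation"
    msssim: MsSsimConfig = field(default_factory=MsSsimConfig)
    nce: NceConfig = field(default_factory=NceConfig)

    def __post_init__(self):
        if min(self.lambda_x, self.lambda_y, self.lambda_ss) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.semantic_pair not in ("input_translation", "identity_translation"):
            raise ValueError(f"unknown semantic_pair {self.semantic_pair!r}")


def make_ablation(cfg: LossConfig, variant: str) -> LossConfig:
    """Ablation configurations: drop the semantic term (= the plain CUT
    objective) or the patch terms."""
    if variant == "full":
        return replace(cfg)
    if variant in ("no_semantic", "cut"):
        return replace(cfg, lambda_ss=0.0)
    if variant == "no_patchnce":
        return replace(cfg, lambda_x=0.0, lambda_y=0.0)
    raise ValueError(f"unknown ablation variant {variant!r}; choose from {ABLATION_VARIANTS}")


def total_loss(model: TranslatorModel, sampler: PatchSampler, x: Tensor, y: Tensor,
               cfg: LossConfig, rng: np.random.Generator,
               fake: Tensor | None = None, feats_x=None):
    """Generator-side objective and its unweighted per-term breakdown.

    Returns (total, breakdown, fake) where breakdown holds the unweighted
    scalar terms {gan, patch_x, patch_y, semantic}; disabled terms are 0 and
    their modules are never invoked.  ``fake``/``feats_x`` may carry a
    precomputed G(x) pass (the encoder taps of x are a by-product of the
    generator forward, so recomputing them is pure waste).
    """
    if fake is None:
        fake, feats_x = model.G(x, with_feats=True)
    d_fake = model.D(fake)
    if cfg.gan_mode == "lsgan":
        loss_gan = _mse(d_fake, 1.0)
    elif cfg.gan_mode == "vanilla":
        loss_gan = (-d_fake).softplus().mean()
    else:
        raise ValueError(f"unknown gan mode {cfg.gan_mode!r}")
    total = loss_gan
    breakdown = {"gan": float(loss_gan.item()), "patch_x": 0.0,
                 "patch_y": 0.0, "semantic": 0.0}

    if cfg.lambda_x > 0:
        fx = feats_x if feats_x is not None else model.G.encode(x, tag="input")
        ffake = model.G.encode(fake, tag="translation")
        q, k = sampler.sample_patches(fx, ffake, rng)
        lx = patchnce_loss(q, k, cfg.nce)
        breakdown["patch_x"] = float(lx.item())
        total = total + cfg.lambda_x * lx
    if cfg.lambda_y > 0:
        idt, fy = model.G(y, with_feats=True)
        fidt = model.G.encode(idt, tag="identity")
        q, k = sampler.sample_patches(fy, fidt, rng)
        ly = patchnce_loss(q, k, cfg.nce)
        breakdown["patch_y"] = float(ly.item())
        total = total + cfg.lambda_y * ly
    if cfg.lambda_ss > 0:
        if cfg.semantic_pair == "input_translation":
            a, b = x, fake
        else:
            a, b = y, model.G(y)
        sem = semantic_loss_tensor((a + 1.0) * 0.5, (b + 1.0) * 0.5, cfg.msssim, L=1.0)
        breakdown["semantic"] = float(sem.item())
        total = total + cfg.lambda_ss * sem
    breakdown["total"] = float(total.item())
    return total, breakdown, fake


@dataclass
class TrainState:
    """Serializable bookkeeping for a run: step counter, RNG streams and
    optimizer hyperparameters."""

    step: int = 0
    seed: int = 0
    lr: float = 2e-4
    betas: tuple = (0.5, 0.999)
    total_steps: int = 0


def _epoch_means(records: list, steps_per_epoch: int) -> dict:
    """Mean of each logged term over the first and last full epoch."""
    if not records:
        return {}
    first = records[:steps_per_epoch]
    last = records[-steps_per_epoch:]
    keys = ("gan", "patch_x", "patch_y", "semantic", "total")
    return {
        "first_epoch": {k: float(np.mean([r[k] for r in first])) for k in keys},
        "final_epoch": {k: float(np.mean([r[k] for r in last])) for k in keys},
    }


def train(images_x: list, images_y: list, cfg: LossConfig, out_dir,
          steps: int = 500, total_steps: int | None = None,
          seed: int = 0, ngf: int = 8, ndf: int = 8,
          n_blocks: int = 3, lr: float = 2e-4, betas=(0.5, 0.999),
          log_every: int = 1, ckpt_every: int | None = None,
          resume: str | Path | None = None, resolved_config: dict | None = None,
          progress: bool = False):
    """Train the translator on two unpaired image lists.

    Parameters
    ----------
    images_x, images_y
        Lists of H x W x 3 float arrays in [0, 1] (unpaired domains).
    cfg
        Loss configuration (possibly an ablation).
    out_dir
        Receives ``log.jsonl`` and ``checkpoint.npz``.
    total_steps
        Horizon for the linear LR decay (defaults to ``steps``); pass the
        final target when training in stages so the schedule is unchanged.

    Returns
    -------
    (model, sampler, records)
        The trained model, its projection heads and the per-step loss log.
    """
    from .io_utils import load_checkpoint_into, save_checkpoint  # cycle guard

    if not images_x or not images_y:
        raise ValueError("both training domains must contain at least one image")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng_init = np.random.default_rng((seed, 1))
    model = TranslatorModel(ngf=ngf, ndf=ndf, n_blocks=n_blocks, rng=rng_init)
    sampler = PatchSampler(cfg.nce, init_seed=seed)

    xs = [_to_nchw_pm1(im) for im in images_x]
    ys = [_to_nchw_pm1(im) for im in images_y]

    # dry pass binds the lazy projection-head shapes before optimizers exist
    _bind_heads(model, sampler, xs[0], cfg)

    opt_g = Adam(list(model.G.parameters()) + list(sampler.parameters()), lr=lr, betas=betas)
    opt_d = Adam(list(model.D.parameters()), lr=lr, betas=betas)

    state = TrainState(step=0, seed=seed, lr=lr, betas=tuple(betas),
                       total_steps=total_steps or steps)
    records: list = []
    if resume is not None:
        state = load_checkpoint_into(resume, model, sampler, opt_g, opt_d)
        state.total_steps = max(state.total_steps, total_steps or steps)

    log_path = out_dir / "log.jsonl"
    log_f = open(log_path, "a" if resume is not None else "w")
    t0 = time.time()
    try:
        while state.step < steps:
            # stateless per-step randomness: a resumed run draws exactly the
            # same data order and patch locations as an unbroken one
            epoch, pos = divmod(state.step, len(xs))
            order = np.random.default_rng((seed, 3, epoch)).permutation(len(xs))
            xi = int(order[pos])
            yi = int(np.random.default_rng((seed, 4, state.step)).integers(len(ys)))
            rng_patch = np.random.default_rng((seed, 5, state.step))
            x, y = Tensor(xs[xi]), Tensor(ys[yi])

            opt_g.set_lr_linear_decay(state.step, state.total_steps)
            opt_d.set_lr_linear_decay(state.step, state.total_steps)

            # --- discriminator step on (y, G(x) detached)
            fake, feats_x = model.G(x, with_feats=True)
            d_real = model.D(y)
            d_fake = model.D(fake.detach())
            if cfg.gan_mode == "lsgan":
                loss_d = _mse(d_real, 1.0) + _mse(d_fake, 0.0)
            else:
                loss_d = (-d_real).softplus().mean() + d_fake.softplus().mean()
            model.D.zero_grad()
            loss_d.backward()
            opt_d.step()

            # --- generator step on the full objective (reuses the G(x) tape)
            total, breakdown, _ = total_loss(model, sampler, x, y, cfg, rng_patch,
                                             fake=fake, feats_x=feats_x)
            model.G.zero_grad()
            sampler.zero_grad()
            model.D.zero_grad()
            total.backward()
            opt_g.step()
            model.D.zero_grad()

            state.step += 1
            rec = {"step": state.step, **breakdown, "loss_d": float(loss_d.item())}
            records.append(rec)
            if state.step % log_every == 0:
                log_f.write(json.dumps(rec) + "\n")
            if progress and state.step % 50 == 0:
                el = time.time() - t0
                print(f"step {state.step}/{steps} total={rec['total']:.4f} ({el:.0f}s)")
            if ckpt_every and state.step % ckpt_every == 0:
                save_checkpoint(out_dir / "checkpoint.npz", model, sampler,
                                opt_g, opt_d, state, resolved_config)
    finally:
        log_f.close()
    save_checkpoint(out_dir / "checkpoint.npz", model, sampler, opt_g, opt_d,
                    state, resolved_config)
    summary = _epoch_means(records, steps_per_epoch=max(1, len(xs)))
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return model, sampler, records


def _to_nchw_pm1(im: np.ndarray) -> np.ndarray:
    im = np.asarray(im, dtype=np.float32)
    if im.ndim != 3 or im.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got {im.shape}")
    return np.moveaxis(im * 2.0 - 1.0, -1, 0)[None]


def _bind_heads(model, sampler, x0: np.ndarray, cfg: LossConfig):
    if cfg.lambda_x == 0 and cfg.lambda_y == 0:
        return
    from .autodiff import no_grad

    with no_grad():
        fs = model.G.encode(Tensor(x0))
    for lid, f in zip(cfg.nce.layer_ids, fs.layers):
        sampler._head(lid, f.shape[1])
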