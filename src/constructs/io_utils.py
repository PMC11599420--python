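"""Configuration resolution, dataset readers/writers and checkpoints.

Images are 8-bit RGB PNG; label masks are single-channel 8-bit PNG with the
pixel value equal to the class ID (0 = background).  Masks for a directory
of images live in a sibling ``masks/`` directory and are matched by
filename stem.  Every artifact written by the package embeds the resolved
configuration fingerprint so provenance is checkable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .contrastive import NceConfig
from .semantic import CANONICAL_WEIGHTS, MsSsimConfig
from .training import LossConfig

# ------------------------------------------------------------------- config
DEFAULT_CONFIG: dict = {
    "model": {"ngf": 64, "ndf": 64, "n_blocks": None},  # None -> 6 below 256 px, 9 above
    "gan": {"mode": "lsgan"},
    "nce": {"tau": 0.07, "num_patches": 256, "layer_ids": [0, 1, 2, 3, 4],
            "embed_dim": 256},
    "msssim": {"K": 5, "weights": list(CANONICAL_WEIGHTS), "window_size": 11,
               "window_sigma": 1.5, "K1": 0.01, "K2": 0.03,
               "composition": "canonical"},
    "semantic": {"pair": "input_translation"},
    "loss": {"lambda_x": 1.0, "lambda_y": 1.0, "lambda_ss": 1.0},
    "train": {"steps": 500, "lr": 2.0e-4, "beta1": 0.5, "beta2": 0.999,
              "log_every": 1, "ckpt_every": None, "seed": 0},
    "seg": {"num_classes": 4, "base_ch": 8, "steps": 300, "lr": 2.0e-3,
            "batch_size": 2},
    "data": {"image_size": 64, "resize": False},
}

#: desk-scale overrides used by the bundled fixtures and examples
FIXTURE_OVERRIDES: dict = {
    "model": {"ngf": 8, "ndf": 8, "n_blocks": 3},
    "nce": {"num_patches": 64, "embed_dim": 64},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        here = f"{path}.{k}" if path else k
        if k not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[k], dict) and isinstance(v, dict):
            out[k] = _merge(base[k], v, here)
        else:
            out[k] = v
    return out


def resolve_config(config_file=None, overrides: dict | None = None,
                   fixture_scale: bool = False) -> dict:
    """Defaults <- optional YAML file <- programmatic overrides.

    Unknown keys at any level are rejected rather than ignored.
    """
    cfg = DEFAULT_CONFIG
    if fixture_scale:
        cfg = _merge(cfg, FIXTURE_OVERRIDES)
    if config_file is not None:
        loaded = yaml.safe_load(Path(config_file).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {config_file} must hold a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_fingerprint(cfg: dict) -> str:
    """Stable short hash of a resolved configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def loss_config_from(cfg: dict) -> LossConfig:
    ms = cfg["msssim"]
    nc = cfg["nce"]
    return LossConfig(
        lambda_x=float(cfg["loss"]["lambda_x"]),
        lambda_y=float(cfg["loss"]["lambda_y"]),
        lambda_ss=float(cfg["loss"]["lambda_ss"]),
        gan_mode=cfg["gan"]["mode"],
        semantic_pair=cfg["semantic"]["pair"],
        msssim=MsSsimConfig(K=int(ms["K"]), weights=tuple(ms["weights"]),
                            window_size=int(ms["window_size"]),
                            window_sigma=float(ms["window_sigma"]),
                            K1=float(ms["K1"]), K2=float(ms["K2"]),
                            composition=ms["composition"]),
        nce=NceConfig(tau=float(nc["tau"]), num_patches=int(nc["num_patches"]),
                      layer_ids=tuple(nc["layer_ids"]),
                      embed_dim=int(nc["embed_dim"])),
    )


def model_kwargs_from(cfg: dict) -> dict:
    m = cfg["model"]
    n_blocks = m["n_blocks"]
    if n_blocks is None:
        n_blocks = 9 if int(cfg["data"]["image_size"]) >= 256 else 6
    return {"ngf": int(m["ngf"]), "ndf": int(m["ndf"]), "n_blocks": int(n_blocks)}


# ----------------------------------------------------------------- raster IO
def save_image(path, pixels01: np.ndarray):
    """Write an H x W x 3 [0, 1] float image as 8-bit RGB PNG."""
    arr = np.clip(np.asarray(pixels01), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def load_image(path) -> np.ndarray:
    """Read a PNG into an H x W x 3 float array in [0, 1]."""
    try:
        arr = iio.imread(Path(path))
    except Exception as e:  # pragma: no cover - delegated decoding
        raise ValueError(f"cannot read image file {path}: {e}") from e
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.float64) / 255.0


def save_mask(path, mask):
    from .images import LabelMask

    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if labels.max(initial=0) > 255:
        raise ValueError("class IDs beyond 255 do not fit 8-bit masks")
    iio.imwrite(Path(path), labels.astype(np.uint8))


def load_mask(path, num_classes: int):
    from .images import LabelMask

    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.max(initial=0) >= num_classes:
        raise ValueError(
            f"mask {path} holds class ID {int(arr.max())} but num_classes={num_classes}"
        )
    return LabelMask(arr.astype(np.int64), num_classes)


def _resize01(img: np.ndarray, hw: tuple) -> np.ndarray:
    from scipy.ndimage import zoom

    h, w = hw
    fac = (h / img.shape[0], w / img.shape[1], 1)
    return np.clip(zoom(img, fac, order=1), 0.0, 1.0)


def load_image_dir(path, expect_masks: bool = False, num_classes: int = 4,
                   resize: tuple | None = None):
    """Load a directory of PNGs (sorted by name) as [0, 1] float images.

    With ``expect_masks`` the sibling ``masks/`` directory must hold a mask
    for every image stem.  ``resize`` = (H, W) rescales images (bilinear) —
    without it, inconsistent sizes are an error.  Returns a list of images
    or (image, mask) pairs.
    """
    d = Path(path)
    files = sorted(p for p in d.glob("*.png") if p.is_file())
    if not files:
        raise FileNotFoundError(f"no images found in {d}")
    out = []
    shape = None
    for f in files:
        img = load_image(f)
        if resize is not None and img.shape[:2] != tuple(resize):
            img = _resize01(img, tuple(resize))
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"inconsistent image size: {f} is {img.shape[:2]}, "
                             f"expected {shape[:2]} (configure resize to allow)")
        if expect_masks:
            mf = d.parent / "masks" / f.name
            if not mf.exists():
                raise FileNotFoundError(f"missing mask for {f.name}: expected {mf}")
            out.append((img, load_mask(mf, num_classes)))
        else:
            out.append(img)
    return out


# --------------------------------------------------------------- checkpoints
def save_checkpoint(path, model, sampler, opt_g, opt_d, state, resolved_config=None):
    """Single-archive checkpoint: all weights, optimizer states, step counter,
    lazy-head shapes and the resolved config."""
    arrays = {}
    for prefix, mod in (("g", model.G), ("d", model.D), ("h", sampler)):
        for k, v in mod.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    for prefix, opt in (("og", opt_g), ("od", opt_d)):
        s = opt.state_dict()
        for i, a in enumerate(s["m"]):
            arrays[f"{prefix}/m/{i}"] = a
        for i, a in enumerate(s["v"]):
            arrays[f"{prefix}/v/{i}"] = a
        arrays[f"{prefix}/t"] = np.array([s["t"], s["lr"]], dtype=np.float64)
    from dataclasses import asdict

    meta = {
        "step": state.step, "seed": state.seed, "lr": state.lr,
        "betas": list(state.betas), "total_steps": state.total_steps,
        "head_spec": sampler.head_spec(),
        "model": {"ngf": model.G.ngf, "ndf": model.D.ndf,
                  "n_blocks": model.G.n_blocks},
        "nce": asdict(sampler.cfg),
        "config": resolved_config,
        "fingerprint": config_fingerprint(resolved_config or {}),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def read_checkpoint(path) -> tuple[dict, dict]:
    z = np.load(Path(path))
    meta = json.loads(bytes(z["meta"]).decode())
    return {k: z[k] for k in z.files if k != "meta"}, meta


def load_translator(path):
    """Rebuild the generator/discriminator/head stack from a checkpoint."""
    from .adversarial import TranslatorModel
    from .contrastive import NceConfig, PatchSampler

    arrays, meta = read_checkpoint(path)
    ncfg = meta["nce"]
    model = TranslatorModel(ngf=meta["model"]["ngf"], ndf=meta["model"]["ndf"],
                            n_blocks=meta["model"]["n_blocks"])
    sampler = PatchSampler(NceConfig(
        tau=float(ncfg["tau"]), num_patches=int(ncfg["num_patches"]),
        layer_ids=tuple(ncfg["layer_ids"]), embed_dim=int(ncfg["embed_dim"])),
        init_seed=int(meta.get("seed", 0)))
    sampler.build_from_spec(meta["head_spec"])
    model.G.load_state_dict({k[2:]: v for k, v in arrays.items() if k.startswith("g/")})
    model.D.load_state_dict({k[2:]: v for k, v in arrays.items() if k.startswith("d/")})
    if meta["head_spec"]:
        sampler.load_state_dict({k[2:]: v for k, v in arrays.items() if k.startswith("h/")})
    return model, sampler, meta


def load_checkpoint_into(path, model, sampler, opt_g, opt_d):
    """Restore a full training state for resumption; returns a TrainState."""
    from .training import TrainState

    arrays, meta = read_checkpoint(path)
    model.G.load_state_dict({k[2:]: v for k, v in arrays.items() if k.startswith("g/")})
    model.D.load_state_dict({k[2:]: v for k, v in arrays.items() if k.startswith("d/")})
    sampler.build_from_spec(meta["head_spec"])
    if meta["head_spec"]:
        sampler.load_state_dict({k[2:]: v for k, v in arrays.items() if k.startswith("h/")})
        # rebind optimizer parameter lists to the restored tensors
        opt_g.params = list(model.G.parameters()) + list(sampler.parameters())
        opt_g.m = [np.zeros_like(p.data) for p in opt_g.params]
        opt_g.v = [np.zeros_like(p.data) for p in opt_g.params]
    for prefix, opt in (("og", opt_g), ("od", opt_d)):
        t_lr = arrays[f"{prefix}/t"]
        opt.load_state_dict({
            "t": int(t_lr[0]), "lr": float(t_lr[1]),
            "m": [arrays[f"{prefix}/m/{i}"] for i in range(len(opt.params))],
            "v": [arrays[f"{prefix}/v/{i}"] for i in range(len(opt.params))],
        })
    return TrainState(step=int(meta["step"]), seed=int(meta["seed"]),
                      lr=float(meta["lr"]), betas=tuple(meta["betas"]),
                      total_steps=int(meta["total_steps"]))
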