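"""Procedural two-domain surgical-like scene fixtures.

Each scene is a multi-class label field with smooth, organ-like curved
boundaries (level sets of a band-limited Gaussian random field) plus an
elongated tool-like rectangle, rendered twice from the same mask:

* **X style** ("simulated"): flat per-class colors with a mild vertical
  shading gradient — the look of an untextured render.
* **Y style** ("realistic"): a different per-class palette modulated by
  per-class correlated noise texture, a spatially varying illumination
  gradient, additive specular highlights and a radial vignette — the
  lighting variability that makes the translation problem non-trivial.

Both renderings share a pixel-perfect ground-truth mask.  Training splits
draw X and Y scenes from disjoint seed sets (the domains are unpaired, as
one-sided translation assumes); the evaluation split reuses one structure
seed for both styles so a hypothetical perfect translator has a known
target.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import LabelMask

# The simulated palette is deliberately non-tissue-like: hues are rotated
# far from the realistic palette (so the class -> appearance mapping must be
# learned and a segmentation model fit on the realistic domain fails on raw
# X-style images), while per-class luminance ordering matches the realistic
# domain — as in actual anatomy renders, where organ brightness is roughly
# faithful even when color and texture are not.
X_PALETTE = ((0.45, 0.58, 0.75), (0.30, 0.15, 0.35), (0.55, 0.85, 0.85), (0.38, 0.44, 0.30))
Y_PALETTE = ((0.82, 0.46, 0.40), (0.42, 0.07, 0.09), (0.93, 0.80, 0.45), (0.35, 0.38, 0.44))


@dataclass
class SceneSpec:
    """Parameters of the procedural scene distribution."""

    image_size: tuple = (64, 64)
    num_classes: int = 4  # 0 wall-like background, 1 organ A, 2 organ B, 3 tool
    class_fractions: tuple = (0.45, 0.30, 0.21, 0.04)
    blob_smoothness: float = 9.0  # low-pass sigma (px) of the boundary field
    min_class_fraction: float = 0.02
    max_retries: int = 25
    # X-style (flat-shaded render)
    x_colors: tuple = X_PALETTE
    x_shading: float = 0.15
    # Y-style (textured, lit render)
    y_colors: tuple = Y_PALETTE
    y_texture_amp: tuple = (0.05, 0.09, 0.07, 0.03)
    y_texture_corr: float = 2.5  # texture correlation length (px)
    y_illum_strength: float = 0.30
    y_specular_count: int = 2
    y_specular_intensity: float = 0.35
    y_specular_sigma: float = 5.0
    y_vignette: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 3:
            raise ValueError("need at least 3 classes")
        for name in ("class_fractions", "x_colors", "y_colors", "y_texture_amp"):
            if len(getattr(self, name)) < self.num_classes:
                raise ValueError(f"{name} must cover {self.num_classes} classes")
        if abs(sum(self.class_fractions[: self.num_classes]) - 1.0) > 1e-6:
            raise ValueError("class_fractions must sum to 1")


def _smooth_field(rng, h, w, sigma):
    f = gaussian_filter(rng.standard_normal((h, w)), sigma, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def _make_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    for _ in range(spec.max_retries):
        u = _smooth_field(rng, h, w, spec.blob_smoothness)
        # nested level sets of one smooth field -> curved organ-like regions
        organ_classes = spec.num_classes - 1
        fr = np.asarray(spec.class_fractions[:organ_classes], dtype=np.float64)
        fr = fr / fr.sum()
        cuts = np.quantile(u, np.cumsum(fr)[:-1])
        mask = np.searchsorted(cuts, u.ravel()).reshape(h, w).astype(np.int64)
        # elongated tool-like rectangle as the last class
        tool_frac = spec.class_fractions[spec.num_classes - 1]
        tw = max(2, int(round(np.sqrt(tool_frac * h * w / 4.0))))
        tl = min(w, 4 * tw)
        r0 = int(rng.integers(0, h - tw))
        c0 = int(rng.integers(0, w - tl))
        if rng.random() < 0.5:
            mask[r0:r0 + tw, c0:c0 + tl] = spec.num_classes - 1
        else:
            r0, c0 = int(rng.integers(0, h - tl)), int(rng.integers(0, w - tw))
            mask[r0:r0 + tl, c0:c0 + tw] = spec.num_classes - 1
        frac = np.bincount(mask.ravel(), minlength=spec.num_classes) / mask.size
        if frac[: spec.num_classes].min() >= spec.min_class_fraction:
            return mask
    raise RuntimeError(
        f"could not place all {spec.num_classes} classes with >= "
        f"{spec.min_class_fraction:.0%} coverage in {spec.max_retries} tries; "
        "relax class_fractions or min_class_fraction"
    )


def _render_x(mask: np.ndarray, spec: SceneSpec) -> np.ndarray:
    h, w = mask.shape
    colors = np.asarray(spec.x_colors[: spec.num_classes], dtype=np.float64)
    img = colors[mask]
    a = spec.x_shading
    shade = 1.0 - a / 2.0 + a * (np.arange(h) / max(1, h - 1))[:, None, None]
    return np.clip(img * shade, 0.0, 1.0)


def _render_y(mask: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    colors = np.asarray(spec.y_colors[: spec.num_classes], dtype=np.float64)
    img = colors[mask]
    # per-class correlated texture, unit-variance before scaling so the
    # per-class pixel variance equals amp^2
    for c in range(spec.num_classes):
        amp = spec.y_texture_amp[c]
        tex = _smooth_field(rng, h, w, spec.y_texture_corr) * amp
        img[mask == c] += tex[mask == c, None]
    if spec.y_illum_strength > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.meshgrid(np.linspace(-0.5, 0.5, h), np.linspace(-0.5, 0.5, w),
                             indexing="ij")
        plane = np.cos(theta) * yy + np.sin(theta) * xx
        img *= (1.0 + spec.y_illum_strength * 2.0 * plane)[:, :, None]
    for _ in range(spec.y_specular_count):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img += (spec.y_specular_intensity *
                np.exp(-d2 / (2 * spec.y_specular_sigma ** 2)))[:, :, None]
    if spec.y_vignette > 0:
        yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
        img *= (1.0 - spec.y_vignette * (yy ** 2 + xx ** 2) / 2.0)[:, :, None]
    return np.clip(img, 0.0, 1.0)


def generate_scene(spec: SceneSpec):
    """One paired scene: (x_img, y_img, mask), all from ``spec.seed``.

    x_img and y_img are H x W x 3 floats in [0, 1] rendered from the same
    mask; identical specs yield bit-identical output.
    """
    rng_mask = np.random.default_rng((spec.seed, 101))
    mask = _make_mask(spec, rng_mask)
    x_img = _render_x(mask, spec)
    y_img = _render_y(mask, spec, np.random.default_rng((spec.seed, 202)))
    return x_img, y_img, LabelMask(mask, spec.num_classes)


def scene_batch(spec: SceneSpec, seeds) -> list:
    """Scenes for an explicit seed list (helper for split construction)."""
    from dataclasses import replace

    return [generate_scene(replace(spec, seed=int(s))) for s in seeds]


def generate_dataset(spec: SceneSpec, n_train_x: int, n_train_y: int, n_eval: int,
                     out_dir) -> dict:
    """Write unpaired training splits and a paired eval split as PNG trees.

    Layout::

        out_dir/train_x/img_####.png          X-style, unpaired
        out_dir/train_y/img_####.png          Y-style, disjoint seeds
        out_dir/eval/x/img_####.png           paired eval split
        out_dir/eval/y/img_####.png
        out_dir/eval/masks/img_####.png       shared ground truth
        out_dir/manifest.json

    Returns the manifest dict; regenerating from it reproduces the tree
    byte-for-byte.
    """
    from .io_utils import save_image, save_mask

    if min(n_train_x, n_train_y, n_eval) < 1:
        raise ValueError("all split sizes must be >= 1")
    out = Path(out_dir)
    base = spec.seed
    seeds = {
        "train_x": [base + i for i in range(n_train_x)],
        "train_y": [base + 10_000 + i for i in range(n_train_y)],
        "eval": [base + 20_000 + i for i in range(n_eval)],
    }
    from dataclasses import replace

    for sub in ("train_x", "train_y", "eval/x", "eval/y", "eval/masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(seeds["train_x"]):
        x, _, _ = generate_scene(replace(spec, seed=s))
        save_image(out / "train_x" / f"img_{i:04d}.png", x)
    for i, s in enumerate(seeds["train_y"]):
        _, y, _ = generate_scene(replace(spec, seed=s))
        save_image(out / "train_y" / f"img_{i:04d}.png", y)
    for i, s in enumerate(seeds["eval"]):
        x, y, m = generate_scene(replace(spec, seed=s))
        save_image(out / "eval" / "x" / f"img_{i:04d}.png", x)
        save_image(out / "eval" / "y" / f"img_{i:04d}.png", y)
        save_mask(out / "eval" / "masks" / f"img_{i:04d}.png", m)
    from .io_utils import config_fingerprint

    manifest = {"spec": asdict(spec), "seeds": seeds,
                "counts": {"train_x": n_train_x, "train_y": n_train_y, "eval": n_eval},
                "fingerprint": config_fingerprint(asdict(spec))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def regenerate_from_manifest(manifest: dict, out_dir) -> dict:
    """Rebuild a dataset tree from its manifest (byte-identical)."""
    spec_d = dict(manifest["spec"])
    spec_d["image_size"] = tuple(spec_d["image_size"])
    for key in ("class_fractions", "x_colors", "y_colors", "y_texture_amp"):
        spec_d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in spec_d[key])
    spec = SceneSpec(**spec_d)
    c = manifest["counts"]
    return generate_dataset(spec, c["train_x"], c["train_y"], c["eval"], out_dir)
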