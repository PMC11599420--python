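"""Segmentation-based evaluation of translation quality.

Two schemes are provided:

* **Consistency evaluation** ("train on real, evaluate on translated
  synthetic"): a segmentation model trained on domain-Y images is frozen
  and applied to the translated domain-X images; predictions are scored
  against the X ground-truth masks.  A translator that closes the domain
  gap while preserving semantics scores high.
* **Downstream evaluation**: translated images serve as (pre)training data
  for segmentation; performance is measured as Dice on a held-out labelled
  real test set, with modes for translated-only training, translated
  pretraining plus real fine-tuning, and a real-only baseline.

Metrics per image: pixel accuracy, mean class accuracy (mean per-class
recall over classes present in the truth), mean IoU and mean Dice over
classes present in prediction or truth; classes absent from both are
excluded from the means.  Aggregates over images are reported as
mean +/- sd, so per-image values are kept rather than a pooled confusion
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .images import LabelMask, from_model_range, to_model_range
from .nn import (Adam, Conv2d, Module, ReLU, Sequential, avg_pool2d, concat,
                 upsample_nearest2d)


@dataclass
class EvalReport:
    """Per-class and aggregate segmentation metrics.

    For single-image reports the ``*_sd`` fields are zero; aggregates over
    n_images > 1 carry the per-image standard deviation.
    """

    pixel_acc: float
    mean_class_acc: float
    mean_iou: float
    mean_dice: float
    per_class_iou: dict = field(default_factory=dict)
    per_class_recall: dict = field(default_factory=dict)
    per_class_dice: dict = field(default_factory=dict)
    pixel_acc_sd: float = 0.0
    mean_class_acc_sd: float = 0.0
    mean_iou_sd: float = 0.0
    mean_dice_sd: float = 0.0
    n_images: int = 1
    fingerprint: str = ""

    def to_dict(self) -> dict:
        return {
            "pixel_acc": self.pixel_acc, "mean_class_acc": self.mean_class_acc,
            "mean_iou": self.mean_iou, "mean_dice": self.mean_dice,
            "pixel_acc_sd": self.pixel_acc_sd, "mean_class_acc_sd": self.mean_class_acc_sd,
            "mean_iou_sd": self.mean_iou_sd, "mean_dice_sd": self.mean_dice_sd,
            "per_class_iou": {str(k): v for k, v in self.per_class_iou.items()},
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
            "per_class_dice": {str(k): v for k, v in self.per_class_dice.items()},
            "n_images": self.n_images, "fingerprint": self.fingerprint,
        }


def _as_labels(m, num_classes: int) -> np.ndarray:
    if isinstance(m, LabelMask):
        if m.num_classes > num_classes:
            raise ValueError("mask declares more classes than the evaluation")
        return m.labels
    return LabelMask(np.asarray(m), num_classes).labels


def seg_metrics(pred, truth, num_classes: int) -> EvalReport:
    """Score one predicted mask against ground truth.

    pxAcc = correct/total; clsAcc = mean per-class recall over classes
    present in the truth; IoU_c = TP/(TP+FP+FN) and Dice_c =
    2TP/(2TP+FP+FN) averaged over classes present in either mask.
    """
    p = _as_labels(pred, num_classes)
    t = _as_labels(truth, num_classes)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    conf = np.bincount(
        (t.ravel() * num_classes + p.ravel()).astype(np.int64),
        minlength=num_classes * num_classes,
    ).reshape(num_classes, num_classes)
    tp = np.diag(conf).astype(np.float64)
    fn = conf.sum(axis=1) - tp  # truth counts minus hits
    fp = conf.sum(axis=0) - tp
    present_truth = conf.sum(axis=1) > 0
    present_any = (conf.sum(axis=1) + conf.sum(axis=0)) > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        recall = tp / (tp + fn)
        iou = tp / (tp + fp + fn)
        dice = 2 * tp / (2 * tp + fp + fn)

    per_iou = {c: float(iou[c]) for c in range(num_classes) if present_any[c]}
    per_rec = {c: float(recall[c]) for c in range(num_classes) if present_truth[c]}
    per_dice = {c: float(dice[c]) for c in range(num_classes) if present_any[c]}
    return EvalReport(
        pixel_acc=float(tp.sum() / conf.sum()),
        mean_class_acc=float(np.mean(list(per_rec.values()))),
        mean_iou=float(np.mean(list(per_iou.values()))),
        mean_dice=float(np.mean(list(per_dice.values()))),
        per_class_iou=per_iou, per_class_recall=per_rec, per_class_dice=per_dice,
    )


def aggregate_reports(reports: list, fingerprint: str = "") -> EvalReport:
    """Mean +/- sd of the scalar metrics over per-image reports."""
    if not reports:
        raise ValueError("no reports to aggregate")

    def stat(attr):
        v = np.array([getattr(r, attr) for r in reports], dtype=np.float64)
        return float(v.mean()), float(v.std())

    pa, pa_sd = stat("pixel_acc")
    ca, ca_sd = stat("mean_class_acc")
    iu, iu_sd = stat("mean_iou")
    di, di_sd = stat("mean_dice")
    classes = sorted({c for r in reports for c in r.per_class_dice})
    mean_cls = {
        name: {c: float(np.mean([getattr(r, name)[c] for r in reports
                                 if c in getattr(r, name)])) for c in classes}
        for name in ("per_class_iou", "per_class_dice")
    }
    return EvalReport(
        pixel_acc=pa, mean_class_acc=ca, mean_iou=iu, mean_dice=di,
        pixel_acc_sd=pa_sd, mean_class_acc_sd=ca_sd, mean_iou_sd=iu_sd,
        mean_dice_sd=di_sd, per_class_iou=mean_cls["per_class_iou"],
        per_class_dice=mean_cls["per_class_dice"],
        n_images=len(reports), fingerprint=fingerprint,
    )


# --------------------------------------------------------------- seg network
class _ConvBlock(Module):
    """Two plain conv+ReLU layers.  Deliberately normalisation-free: feature
    normalisation would discount global colour statistics, which are exactly
    the domain cue the consistency evaluation relies on."""

    def __init__(self, in_ch, out_ch):
        self.net = Sequential(
            Conv2d(in_ch, out_ch, 3, pad=1), ReLU(),
            Conv2d(out_ch, out_ch, 3, pad=1), ReLU(),
        )

    def forward(self, x):
        return self.net(x)


class SegNet(Module):
    """Compact two-level U-Net for pixel-wise classification."""

    def __init__(self, num_classes: int, base_ch: int = 8, in_ch: int = 3,
                 rng: np.random.Generator | None = None):
        b = base_ch
        self.num_classes = num_classes
        self.enc1 = _ConvBlock(in_ch, b)
        self.enc2 = _ConvBlock(b, 2 * b)
        self.bott = _ConvBlock(2 * b, 4 * b)
        self.dec2 = _ConvBlock(4 * b + 2 * b, 2 * b)
        self.dec1 = _ConvBlock(2 * b + b, b)
        self.out = Conv2d(b, num_classes, 1)
        if rng is not None:
            self.init_gaussian(rng, 0.05)

    def forward(self, x):
        e1 = self.enc1(x)
        e2 = self.enc2(avg_pool2d(e1, 2))
        h = self.bott(avg_pool2d(e2, 2))
        h = self.dec2(concat([upsample_nearest2d(h, 2), e2], axis=1))
        h = self.dec1(concat([upsample_nearest2d(h, 2), e1], axis=1))
        return self.out(h)

    def predict(self, images01: np.ndarray) -> np.ndarray:
        """Argmax class map for a batch of H x W x 3 images in [0, 1]."""
        batch = np.stack([np.moveaxis(to_model_range(im), -1, 0) for im in images01])
        with no_grad():
            logits = self.forward(Tensor(batch.astype(np.float32)))
        return logits.data.argmax(axis=1)


def cross_entropy(logits: Tensor, target: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Pixel-wise CE; logits N x K x H x W, target N x H x W int.

    With ``class_weights`` (length K) each pixel's loss is scaled by the
    weight of its true class and the mean is weight-normalised — the usual
    remedy for strongly imbalanced masks (a thin tool versus large organs).
    """
    n, k, h, w = logits.shape
    onehot = np.zeros((n, k, h, w), dtype=logits.dtype)
    nn_idx = np.arange(n)[:, None, None]
    hh, ww = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    onehot[nn_idx, target, hh[None], ww[None]] = 1.0
    lse = logits.logsumexp(axis=1)
    true_logit = (logits * Tensor(onehot)).sum(axis=1)
    pix = lse - true_logit
    if class_weights is None:
        return pix.mean()
    wmap = np.asarray(class_weights, dtype=logits.dtype)[target]
    return (pix * Tensor(wmap)).sum() * (1.0 / float(wmap.sum()))


def train_seg_model(images01: list, masks: list, num_classes: int,
                    steps: int = 300, base_ch: int = 8, lr: float = 2e-3,
                    batch_size: int = 2, seed: int = 0,
                    init_from: SegNet | None = None,
                    class_weighting: bool = True) -> SegNet:
    """Train the compact U-Net with pixel-wise cross-entropy (seeded).

    ``init_from`` warm-starts from an existing model (fine-tuning mode).
    ``class_weighting`` applies inverse-frequency class weights computed
    from the training masks, so rare classes (surgical tools) are not
    drowned out by large organ regions.
    """
    if not images01:
        raise ValueError("empty training set")
    for i, m in enumerate(masks):
        mm = _as_labels(m, num_classes)
        if mm.max(initial=0) >= num_classes:
            raise ValueError(f"mask {i} exceeds num_classes={num_classes}")
    rng = np.random.default_rng((seed, 11))
    net = SegNet(num_classes, base_ch=base_ch, rng=rng)
    if init_from is not None:
        net.load_state_dict(init_from.state_dict())
    opt = Adam(list(net.parameters()), lr=lr, betas=(0.9, 0.999))
    data = [np.moveaxis(to_model_range(np.asarray(im, dtype=np.float32)), -1, 0)
            for im in images01]
    labels = [_as_labels(m, num_classes) for m in masks]
    cw = None
    if class_weighting:
        freq = np.bincount(np.concatenate([l.ravel() for l in labels]),
                           minlength=num_classes).astype(np.float64)
        cw = np.where(freq > 0, freq.sum() / (num_classes * np.maximum(freq, 1)), 0.0)
    for step in range(steps):
        idx = np.random.default_rng((seed, 12, step)).choice(
            len(data), size=min(batch_size, len(data)), replace=False)
        xb = Tensor(np.stack([data[i] for i in idx]))
        tb = np.stack([labels[i] for i in idx])
        loss = cross_entropy(net(xb), tb, class_weights=cw)
        net.zero_grad()
        loss.backward()
        opt.step()
    return net


# ------------------------------------------------------------------ schemes
def consistency_eval(translator, seg_model: SegNet, images_x: list, masks_x: list,
                     num_classes: int, images_y: list | None = None,
                     masks_y: list | None = None, fingerprint: str = "") -> dict:
    """Translate every X image, segment with the frozen model, score against
    the X ground truth.  Returns {"translated": EvalReport,
    "reference": EvalReport or None} where the reference is the segmentation
    model's own score on true Y-style images (an upper bound indicator).

    ``translator`` is a callable mapping an H x W x 3 [0, 1] image to the
    same (e.g. a trained generator wrapper, or identity for the passthrough
    control).
    """
    if len(images_x) != len(masks_x) or not images_x:
        raise ValueError("need equally many X images and masks")
    reports = []
    for im, mk in zip(images_x, masks_x):
        tr = translator(im)
        pred = seg_model.predict(np.asarray(tr)[None])[0]
        reports.append(seg_metrics(pred, _as_labels(mk, num_classes), num_classes))
    out = {"translated": aggregate_reports(reports, fingerprint), "reference": None}
    if images_y:
        ref = [seg_metrics(seg_model.predict(np.asarray(im)[None])[0],
                           _as_labels(mk, num_classes), num_classes)
               for im, mk in zip(images_y, masks_y)]
        out["reference"] = aggregate_reports(ref, fingerprint)
    return out


def downstream_eval(translated: tuple, real_train: tuple, real_test: tuple,
                    mode: str, num_classes: int, seed: int = 0,
                    steps: int = 200, finetune_steps: int | None = None,
                    base_ch: int = 8, foreground_class: int = 1) -> dict:
    """Train a segmentation model per ``mode`` and report Dice on real test data.

    Modes: ``syn`` (translated images only), ``syn_plus_real`` (pretrain on
    translated, fine-tune on real) and ``real_baseline`` (real only).  Each
    argument is a (images, masks) pair of lists.  Returns the aggregate
    report plus the Dice of the designated foreground class.
    """
    if mode not in ("syn", "syn_plus_real", "real_baseline"):
        raise ValueError(f"unknown downstream mode {mode!r}")
    for name, (ims, mks) in (("translated", translated), ("real_train", real_train),
                             ("real_test", real_test)):
        if len(ims) != len(mks):
            raise ValueError(f"{name}: image/mask counts differ")
        if mode != "real_baseline" or name != "translated":
            if not ims:
                raise ValueError(f"{name} split is empty")
    ft = finetune_steps if finetune_steps is not None else steps // 2
    if mode == "syn":
        net = train_seg_model(*translated, num_classes, steps=steps,
                              base_ch=base_ch, seed=seed)
    elif mode == "real_baseline":
        net = train_seg_model(*real_train, num_classes, steps=steps,
                              base_ch=base_ch, seed=seed)
    else:
        pre = train_seg_model(*translated, num_classes, steps=steps,
                              base_ch=base_ch, seed=seed)
        net = train_seg_model(*real_train, num_classes, steps=ft,
                              base_ch=base_ch, seed=seed + 1, init_from=pre)
    reports = [seg_metrics(net.predict(np.asarray(im)[None])[0],
                           _as_labels(mk, num_classes), num_classes)
               for im, mk in zip(*real_test)]
    agg = aggregate_reports(reports)
    fg = [r.per_class_dice.get(foreground_class, 0.0) for r in reports]
    return {"report": agg, "mean_dice": agg.mean_dice,
            "foreground_dice": float(np.mean(fg)), "mode": mode}


def identity_translator(im):
    """Passthrough control for the consistency evaluation."""
    return im


def checkpoint_translator(model) -> callable:
    """Wrap a TranslatorModel as an H x W x 3 [0,1] -> same callable."""

    def _run(im):
        from .adversarial import translate

        arr = np.moveaxis(to_model_range(np.asarray(im, dtype=np.float32)), -1, 0)
        out = translate(model, arr)
        return np.moveaxis(from_model_range(out[0]), 0, -1)

    return _run
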