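"""Patch-based contrastive learning: InfoNCE, multilayer patch sampling and
the PatchNCE loss.

A query patch embedding drawn from the translated image must classify its
co-located patch in the input image (the positive) against the other
sampled locations of the same input (internal negatives) — an (N+1)-way
classification with temperature tau.  Features are tapped from L encoder
layers at S spatial locations each, pushed through a two-layer projection
head per layer, and unit-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module, ReLU, Sequential


@dataclass
class NceConfig:
    """Contrastive-loss hyperparameters (CUT-lineage defaults)."""

    tau: float = 0.07
    num_patches: int = 256
    layer_ids: tuple = (0, 1, 2, 3, 4)
    embed_dim: int = 256

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")
        if self.num_patches < 2:
            raise ValueError("need num_patches >= 2 (at least one negative)")
        self.layer_ids = tuple(int(i) for i in self.layer_ids)


@dataclass
class FeatureStack:
    """Ordered per-layer feature grids (each a 1 x C x H x W Tensor)."""

    layers: list
    source_tag: str = ""

    def __post_init__(self):
        for f in self.layers:
            if f.ndim != 4 or f.shape[0] != 1:
                raise ValueError("each feature layer must be 1 x C x H x W")
        dims = [f.shape[2] * f.shape[3] for f in self.layers]
        if any(b > a for a, b in zip(dims, dims[1:])):
            raise ValueError("spatial extent must be non-increasing with depth")


@dataclass
class PatchEmbeddings:
    """Per layer: S unit-norm embedding rows plus the indices they came from."""

    embeddings: list  # list of (S, d) Tensors
    indices: list = field(default_factory=list)  # list of (S,) int arrays


def info_nce(s, s_plus, s_neg, tau: float) -> float:
    """(N+1)-way classification loss for one query.

    ``-log[ exp(s.s+ / tau) / (exp(s.s+ / tau) + sum_n exp(s.s-_n / tau)) ]``
    evaluated with a stable log-sum-exp.
    """
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    s = np.asarray(s, dtype=np.float64)
    s_plus = np.asarray(s_plus, dtype=np.float64)
    s_neg = np.atleast_2d(np.asarray(s_neg, dtype=np.float64))
    if s.shape != s_plus.shape or s_neg.shape[1] != s.shape[0]:
        raise ValueError(
            f"dimension mismatch: s{s.shape}, s+{s_plus.shape}, s-{s_neg.shape}"
        )
    if s_neg.shape[0] < 1:
        raise ValueError("need at least one negative vector")
    logits = np.concatenate(([s @ s_plus], s_neg @ s)) / tau
    m = logits.max()
    return float(m + np.log(np.exp(logits - m).sum()) - logits[0])


def _nce_from_logits(logits: Tensor) -> Tensor:
    """Mean InfoNCE over rows of an S x S logit matrix (diagonal = positives)."""
    s = logits.shape[0]
    lse = logits.logsumexp(axis=1)
    diag = logits.reshape(s * s).take(np.arange(s) * (s + 1), axis=0)
    return (lse - diag).mean()


class PatchSampler(Module):
    """Samples aligned patch locations from two feature stacks and projects them.

    One two-layer MLP head per tapped layer, created lazily at the first
    forward pass so the head input width binds to the encoder's channel
    count.  Both stacks of a pair go through the same heads.
    """

    def __init__(self, cfg: NceConfig, init_seed: int = 0):
        self.cfg = cfg
        self.init_seed = init_seed
        self.heads: dict[int, Sequential] = {}

    def _head(self, layer_id: int, in_ch: int) -> Sequential:
        if layer_id not in self.heads:
            d = self.cfg.embed_dim
            head = Sequential(Linear(in_ch, d), ReLU(), Linear(d, d))
            # dedicated init stream: head creation must never perturb the
            # patch-sampling randomness
            head.init_gaussian(np.random.default_rng((self.init_seed, 31, layer_id)),
                               std=float(np.sqrt(1.0 / max(in_ch, d))))
            self.heads[layer_id] = head
        return self.heads[layer_id]

    def head_spec(self) -> dict:
        return {str(k): int(v.mods[0].w.shape[0]) for k, v in self.heads.items()}

    def build_from_spec(self, spec: dict):
        for k, in_ch in spec.items():
            self._head(int(k), int(in_ch))

    def sample_patches(self, fx: FeatureStack, fy: FeatureStack, rng: np.random.Generator):
        """Draw S aligned locations per layer; return (query, key) embeddings.

        Queries come from ``fy`` (the translation side), positives/negatives
        from ``fx`` at the same index set.
        """
        if len(fx.layers) != len(fy.layers):
            raise ValueError("feature stacks tap different layer counts")
        q_emb, k_emb, idx_list = [], [], []
        for lid, (flx, fly) in zip(self.cfg.layer_ids, zip(fx.layers, fy.layers)):
            if flx.shape != fly.shape:
                raise ValueError("paired feature layers must share shapes")
            _, c, h, w = flx.shape
            n_loc = h * w
            s = self.cfg.num_patches
            if s > n_loc:
                raise ValueError(f"num_patches={s} exceeds {n_loc} locations in layer {lid}")
            idx = np.sort(rng.choice(n_loc, size=s, replace=False))
            head = self._head(lid, c)
            q_emb.append(self._project(fly, idx, head))
            k_emb.append(self._project(flx, idx, head))
            idx_list.append(idx)
        return (
            PatchEmbeddings(q_emb, [i.copy() for i in idx_list]),
            PatchEmbeddings(k_emb, [i.copy() for i in idx_list]),
        )

    @staticmethod
    def _project(feat: Tensor, idx: np.ndarray, head: Sequential) -> Tensor:
        _, c, h, w = feat.shape
        rows = feat.reshape(c, h * w).take(idx, axis=1).transpose(1, 0)  # (S, C)
        e = head(rows)
        norm = (e * e).sum(axis=1, keepdims=True).clamp_min(1e-12).sqrt()
        return e / norm


def patchnce_loss(query: PatchEmbeddings, key: PatchEmbeddings, cfg: NceConfig) -> Tensor:
    """Mean InfoNCE over layers and locations with internal negatives.

    For every layer an S x S logit matrix query @ key.T / tau is formed; the
    diagonal entries are the positives, off-diagonal entries the negatives.
    """
    if len(query.embeddings) != len(key.embeddings):
        raise ValueError("query/key layer counts differ")
    total = None
    for q, k in zip(query.embeddings, key.embeddings):
        logits = (q @ k.transpose(1, 0)) * (1.0 / cfg.tau)
        term = _nce_from_logits(logits)
        total = term if total is None else total + term
    return total * (1.0 / len(query.embeddings))
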