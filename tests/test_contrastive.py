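"""InfoNCE / PatchNCE checks against brute-force oracles.

The loss is verified against an extended-precision softmax cross-entropy
loop, and the multilayer loss against an explicit double loop over layers
and locations calling the scalar oracle.
"""

import numpy as np
import pytest

from constructs.autodiff import Tensor
from constructs.contrastive import (FeatureStack, NceConfig, PatchEmbeddings,
                                    PatchSampler, info_nce, patchnce_loss)


def oracle_info_nce(s, s_plus, s_neg, tau):
    """Softmax cross-entropy in extended precision, no log-sum-exp tricks."""
    ld = np.longdouble
    logits = np.array([ld(np.dot(s, s_plus))] +
                      [ld(np.dot(s, n)) for n in s_neg]) / ld(tau)
    p = np.exp(logits)
    return float(-np.log(p[0] / p.sum()))


def unit(v):
    return v / np.linalg.norm(v)


@pytest.mark.parametrize("n", [1, 7, 255])
def test_uniform_logits_give_log_n_plus_1(n):
    """All dot products equal -> probability 1/(N+1) -> loss ln(N+1)."""
    v = unit(np.ones(8))
    assert info_nce(v, v, [v] * n, tau=0.07) == pytest.approx(np.log(n + 1), abs=1e-6)


def test_dominant_positive_drives_loss_to_zero():
    s = np.zeros(4)
    s[0] = 1e4  # s.s+ / tau huge, negatives orthogonal
    assert info_nce(s, s / np.linalg.norm(s) * 1e4, [np.array([0, 1, 0, 0.0])] * 5,
                    tau=1.0) < 1e-12


def test_matches_extended_precision_oracle(rng):
    for _ in range(20):
        d = 16
        s = unit(rng.standard_normal(d))
        sp = unit(rng.standard_normal(d))
        neg = [unit(rng.standard_normal(d)) for _ in range(7)]
        ours = info_nce(s, sp, neg, tau=0.07)
        assert ours == pytest.approx(oracle_info_nce(s, sp, neg, 0.07), abs=1e-6)


def test_logit_shift_invariance(rng):
    """A common additive shift of all logits cancels (log-sum-exp stability).

    Realised by scaling: dot products shift equally when a constant vector
    component is added to the query along a direction shared by all keys.
    """
    d = 8
    s = rng.standard_normal(d)
    sp = rng.standard_normal(d)
    neg = [rng.standard_normal(d) for _ in range(5)]
    base = info_nce(s, sp, neg, tau=0.5)
    shift = rng.standard_normal(d)
    shifted = info_nce(s, sp + shift, [n + shift for n in neg], tau=0.5)
    # adding the same vector to every key shifts every logit by s.shift
    assert shifted == pytest.approx(base, abs=1e-9)


def test_huge_logits_stay_finite():
    s = np.full(4, 1e3)
    val = info_nce(s, s, [s] * 3, tau=1e-3)
    assert np.isfinite(val)


def test_monotone_in_positive_logit(rng):
    """Increasing s.s+ with negatives fixed strictly decreases the loss."""
    for k in range(100):
        r = np.random.default_rng(k)
        d = 8
        s = unit(r.standard_normal(d))
        sp = unit(r.standard_normal(d))
        neg = [unit(r.standard_normal(d)) for _ in range(6)]
        lo = info_nce(s, sp, neg, tau=0.07)
        hi = info_nce(s, sp + 0.05 * s, neg, tau=0.07)  # raises s.s+ only
        assert hi < lo


def test_negative_permutation_invariance(rng):
    s = unit(rng.standard_normal(8))
    sp = unit(rng.standard_normal(8))
    neg = [unit(rng.standard_normal(8)) for _ in range(9)]
    a = info_nce(s, sp, neg, tau=0.2)
    b = info_nce(s, sp, neg[::-1], tau=0.2)
    assert a == pytest.approx(b, abs=1e-9)


def test_contract_violations():
    v = np.ones(4)
    with pytest.raises(ValueError, match="tau"):
        info_nce(v, v, [v], tau=0.0)
    with pytest.raises(ValueError, match="mismatch"):
        info_nce(v, np.ones(5), [v], tau=0.1)
    with pytest.raises(ValueError, match="tau"):
        NceConfig(tau=-1.0)
    with pytest.raises(ValueError, match="num_patches"):
        NceConfig(num_patches=1)


# ----------------------------------------------------------------- sampler
def make_stacks(rng, shapes):
    fx = FeatureStack([Tensor(rng.standard_normal((1, c, h, w)).astype(np.float32))
                       for c, h, w in shapes], source_tag="input")
    fy = FeatureStack([Tensor(rng.standard_normal((1, c, h, w)).astype(np.float32))
                       for c, h, w in shapes], source_tag="translation")
    return fx, fy


def test_sampler_alignment_determinism_and_norms(rng):
    cfg = NceConfig(tau=0.07, num_patches=6, layer_ids=(0, 1), embed_dim=8)
    sampler = PatchSampler(cfg)
    fx, fy = make_stacks(rng, [(3, 6, 6), (4, 3, 3)])
    q1, k1 = sampler.sample_patches(fx, fy, np.random.default_rng(5))
    q2, k2 = sampler.sample_patches(fx, fy, np.random.default_rng(5))
    for a, b in zip(q1.indices, q2.indices):
        assert np.array_equal(a, b)  # same seed, same locations
    for qi, ki in zip(q1.indices, k1.indices):
        assert np.array_equal(qi, ki)  # queries and positives co-located
    for e in q1.embeddings + k1.embeddings:
        norms = np.linalg.norm(e.data, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)
    for idx in q1.indices:
        assert len(np.unique(idx)) == len(idx)  # without replacement


def test_sampler_full_grid_when_s_equals_locations(rng):
    cfg = NceConfig(num_patches=9, layer_ids=(0,), embed_dim=4)
    sampler = PatchSampler(cfg)
    fx, fy = make_stacks(rng, [(2, 3, 3)])
    q, _ = sampler.sample_patches(fx, fy, np.random.default_rng(0))
    assert sorted(q.indices[0].tolist()) == list(range(9))


def test_sampler_rejects_oversampling(rng):
    cfg = NceConfig(num_patches=10, layer_ids=(0,), embed_dim=4)
    fx, fy = make_stacks(rng, [(2, 3, 3)])
    with pytest.raises(ValueError, match="num_patches"):
        PatchSampler(cfg).sample_patches(fx, fy, np.random.default_rng(0))


# ---------------------------------------------------------------- patchnce
def embeddings_from(arrs):
    return PatchEmbeddings([Tensor(a) for a in arrs])


def test_patchnce_self_identification_at_low_tau(rng):
    e = np.linalg.qr(rng.standard_normal((6, 6)))[0]  # orthonormal rows
    cfg = NceConfig(tau=0.01, num_patches=6, layer_ids=(0,), embed_dim=6)
    loss = patchnce_loss(embeddings_from([e]), embeddings_from([e.copy()]), cfg)
    assert loss.item() < 1e-6


def test_patchnce_uniform_embeddings_give_log_s(rng):
    s = 5
    one = np.tile(unit(rng.standard_normal(4)), (s, 1))
    cfg = NceConfig(tau=0.07, num_patches=s, layer_ids=(0,), embed_dim=4)
    loss = patchnce_loss(embeddings_from([one]), embeddings_from([one.copy()]), cfg)
    assert loss.item() == pytest.approx(np.log(s), abs=1e-6)


def test_patchnce_matches_double_loop_oracle(rng):
    """L = 2 layers, S = 4 locations vs. a hand loop over the scalar oracle."""
    cfg = NceConfig(tau=0.07, num_patches=4, layer_ids=(0, 1), embed_dim=5)
    layers_q = [np.array([unit(rng.standard_normal(5)) for _ in range(4)]) for _ in range(2)]
    layers_k = [np.array([unit(rng.standard_normal(5)) for _ in range(4)]) for _ in range(2)]
    ours = patchnce_loss(embeddings_from(layers_q), embeddings_from(layers_k), cfg).item()
    acc = []
    for lq, lk in zip(layers_q, layers_k):
        for i in range(4):
            neg = [lk[j] for j in range(4) if j != i]
            acc.append(oracle_info_nce(lq[i], lk[i], neg, cfg.tau))
    assert ours == pytest.approx(np.mean(acc), abs=1e-6)


def test_patchnce_monotone_in_positive_alignment(rng):
    cfg = NceConfig(tau=0.07, num_patches=3, layer_ids=(0,), embed_dim=4)
    k = np.array([unit(rng.standard_normal(4)) for _ in range(3)])
    q = np.array([unit(v + 0.1 * rng.standard_normal(4)) for v in k])
    base = patchnce_loss(embeddings_from([q]), embeddings_from([k]), cfg).item()
    closer = patchnce_loss(embeddings_from([k.copy()]), embeddings_from([k]), cfg).item()
    assert closer < base
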