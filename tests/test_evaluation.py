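"""Segmentation metrics and the two evaluation schemes."""

import numpy as np
import pytest

from constructs.evaluation import (SegNet, aggregate_reports, consistency_eval,
                                   downstream_eval, identity_translator,
                                   seg_metrics, train_seg_model)
from constructs.images import LabelMask


def test_perfect_prediction_scores_one(rng):
    t = rng.integers(0, 3, (10, 10))
    r = seg_metrics(t, t.copy(), 3)
    assert r.pixel_acc == r.mean_class_acc == r.mean_iou == r.mean_dice == 1.0


def test_hand_counted_two_by_two_example():
    """truth [[0,0],[1,1]], pred [[0,1],[1,1]] enumerated by hand."""
    truth = np.array([[0, 0], [1, 1]])
    pred = np.array([[0, 1], [1, 1]])
    r = seg_metrics(pred, truth, 2)
    assert r.pixel_acc == pytest.approx(0.75)
    assert r.mean_class_acc == pytest.approx(0.75)          # (1/2 + 2/2) / 2
    assert r.mean_iou == pytest.approx((1 / 2 + 2 / 3) / 2, abs=1e-4)   # 0.5833
    assert r.mean_dice == pytest.approx((2 / 3 + 4 / 5) / 2, abs=1e-4)  # 0.7333


def test_disjoint_masks_score_zero_for_that_class():
    truth = np.zeros((4, 4), dtype=int)
    pred = np.ones((4, 4), dtype=int)
    r = seg_metrics(pred, truth, 2)
    assert r.per_class_iou[0] == 0.0 and r.per_class_iou[1] == 0.0
    assert r.per_class_dice[0] == 0.0 and r.mean_dice == 0.0


def test_dice_iou_identity_on_random_binary_masks():
    """Dice = 2 IoU / (1 + IoU) per class, exactly, on 1000 random masks."""
    r = np.random.default_rng(0)
    for _ in range(1000):
        t = r.integers(0, 2, (6, 6))
        p = r.integers(0, 2, (6, 6))
        rep = seg_metrics(p, t, 2)
        for c, iou in rep.per_class_iou.items():
            # identity is exact in rationals; 1e-12 covers float rounding only
            assert rep.per_class_dice[c] == pytest.approx(2 * iou / (1 + iou), abs=1e-12)


def test_pixel_accuracy_invariant_to_joint_class_permutation(rng):
    t = rng.integers(0, 4, (12, 12))
    p = rng.integers(0, 4, (12, 12))
    perm = np.array([2, 0, 3, 1])
    a = seg_metrics(p, t, 4)
    b = seg_metrics(perm[p], perm[t], 4)
    assert a.pixel_acc == b.pixel_acc


def test_absent_classes_excluded_from_means():
    t = np.zeros((4, 4), dtype=int)
    p = np.zeros((4, 4), dtype=int)
    r = seg_metrics(p, t, 5)  # classes 1..4 absent everywhere
    assert set(r.per_class_iou) == {0}
    assert r.mean_iou == 1.0


def test_shape_and_class_violations():
    with pytest.raises(ValueError, match="shapes differ"):
        seg_metrics(np.zeros((2, 2), int), np.zeros((2, 3), int), 2)
    with pytest.raises(ValueError, match="num_classes"):
        seg_metrics(np.full((2, 2), 7), np.zeros((2, 2), int), 2)


def test_aggregate_carries_mean_and_sd():
    reps = [seg_metrics(np.zeros((2, 2), int), np.zeros((2, 2), int), 2),
            seg_metrics(np.ones((2, 2), int), np.zeros((2, 2), int), 2)]
    agg = aggregate_reports(reps, fingerprint="abc")
    assert agg.pixel_acc == pytest.approx(0.5)
    assert agg.pixel_acc_sd == pytest.approx(0.5)
    assert agg.n_images == 2 and agg.fingerprint == "abc"


# ------------------------------------------------------------- seg network
@pytest.fixture(scope="module")
def four_scene_pairs():
    from dataclasses import replace

    from constructs.scenes import SceneSpec, generate_scene

    spec = SceneSpec(image_size=(32, 32))
    out = [generate_scene(replace(spec, seed=900 + i)) for i in range(4)]
    return [s[1] for s in out], [s[2] for s in out]


def test_seg_model_overfits_four_fixture_images(four_scene_pairs):
    ims, mks = four_scene_pairs
    net = train_seg_model(ims, mks, 4, steps=200, lr=2e-3, seed=0)
    accs = [seg_metrics(net.predict(np.asarray(im)[None])[0], mk, 4).pixel_acc
            for im, mk in zip(ims, mks)]
    assert np.mean(accs) > 0.95


def test_seg_training_is_deterministic(four_scene_pairs):
    ims, mks = four_scene_pairs
    n1 = train_seg_model(ims, mks, 4, steps=5, seed=3)
    n2 = train_seg_model(ims, mks, 4, steps=5, seed=3)
    p = np.asarray(ims[0])[None]
    assert np.array_equal(n1.predict(p), n2.predict(p))


def test_seg_training_rejects_out_of_range_masks(four_scene_pairs):
    ims, _ = four_scene_pairs
    bad = [np.full((32, 32), 9, dtype=int)] * len(ims)
    with pytest.raises(ValueError):
        train_seg_model(ims, bad, 4, steps=1)


# --------------------------------------------------------------- schemes
def test_consistency_of_perfect_translator_equals_reference(four_scene_pairs):
    """Paired fixtures give a known perfect translator: mapping each X image
    to its Y twin must reproduce the segmentation model's own Y-score."""
    from dataclasses import replace

    from constructs.scenes import SceneSpec, generate_scene

    spec = SceneSpec(image_size=(32, 32))
    scenes = [generate_scene(replace(spec, seed=950 + i)) for i in range(4)]
    xs = [s[0] for s in scenes]
    ys = [s[1] for s in scenes]
    mks = [s[2] for s in scenes]
    net = train_seg_model(*four_scene_pairs, 4, steps=60, seed=1)
    twin = dict(zip((id(x) for x in xs), ys))

    def perfect(im):
        return twin[id(im)]

    res = consistency_eval(perfect, net, xs, mks, 4, images_y=ys, masks_y=mks)
    assert res["translated"].mean_iou == pytest.approx(res["reference"].mean_iou, abs=1e-6)
    assert res["translated"].n_images == 4


def test_consistency_eval_deterministic(four_scene_pairs):
    ims, mks = four_scene_pairs
    net = train_seg_model(ims, mks, 4, steps=30, seed=2)
    a = consistency_eval(identity_translator, net, ims, mks, 4)
    b = consistency_eval(identity_translator, net, ims, mks, 4)
    assert a["translated"].to_dict() == b["translated"].to_dict()


def test_downstream_leak_fixture_scores_near_one(four_scene_pairs):
    """Deliberate test-set leak: evaluating on the training images must give
    Dice near 1 — a harness sanity check, not a model claim."""
    ims, mks = four_scene_pairs
    res = downstream_eval((ims, mks), (ims, mks), (ims, mks),
                          "real_baseline", 4, seed=0, steps=250)
    assert res["mean_dice"] > 0.85


def test_downstream_baseline_deterministic(four_scene_pairs):
    ims, mks = four_scene_pairs
    kw = dict(num_classes=4, seed=5, steps=10)
    a = downstream_eval((ims, mks), (ims, mks), (ims, mks), "real_baseline", **kw)
    b = downstream_eval((ims, mks), (ims, mks), (ims, mks), "real_baseline", **kw)
    assert a["mean_dice"] == b["mean_dice"]


def test_downstream_rejects_bad_mode_and_empty_split(four_scene_pairs):
    ims, mks = four_scene_pairs
    with pytest.raises(ValueError, match="mode"):
        downstream_eval((ims, mks), (ims, mks), (ims, mks), "hybrid", 4)
    with pytest.raises(ValueError, match="empty"):
        downstream_eval(([], []), (ims, mks), (ims, mks), "syn", 4)


def test_label_mask_validation():
    with pytest.raises(ValueError, match="num_classes"):
        LabelMask(np.array([[0, 5]]), 3)
    with pytest.raises(ValueError, match="H x W"):
        LabelMask(np.zeros((2, 2, 2), dtype=int), 3)
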