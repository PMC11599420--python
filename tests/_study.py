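"""The scaled-down end-to-end study backing the heavyweight acceptance tests.

One frozen segmentation model (trained on labelled Y-style scenes, the
"real" domain) scores the translations of every translator variant; the
same artifacts feed the downstream-training harness.  Everything is seeded
and cached for the session.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

from constructs.contrastive import NceConfig
from constructs.evaluation import (checkpoint_translator, consistency_eval,
                                   identity_translator, train_seg_model)
from constructs.scenes import SceneSpec, generate_scene
from constructs.training import LossConfig, make_ablation, train

SEEDS = (1, 2, 3)
TRAIN_STEPS = 500
N_TRAIN = 128
N_EVAL = 32
N_SEG_TRAIN = 32
N_SEG_TEST = 16
NUM_CLASSES = 4

_cache: dict = {}


def study_config() -> LossConfig:
    return LossConfig(nce=NceConfig(num_patches=64, embed_dim=64))


def make_splits(spec: SceneSpec):
    def scenes(lo, n):
        return [generate_scene(replace(spec, seed=spec.seed + lo + i)) for i in range(n)]

    return {
        "train_x": [s[0] for s in scenes(0, N_TRAIN)],
        "train_y": [s[1] for s in scenes(10_000, N_TRAIN)],
        "eval": scenes(20_000, N_EVAL),
        "seg_train": scenes(30_000, N_SEG_TRAIN),
        "seg_test": scenes(40_000, N_SEG_TEST),
    }


def run_study(tmp_root: Path | None = None) -> dict:
    if "result" in _cache:
        return _cache["result"]
    import tempfile

    root = Path(tmp_root or tempfile.mkdtemp(prefix="constructs-study-"))
    spec = SceneSpec(image_size=(64, 64), seed=0)
    splits = make_splits(spec)
    cfg = study_config()

    seg = train_seg_model([s[1] for s in splits["seg_train"]],
                          [s[2] for s in splits["seg_train"]],
                          NUM_CLASSES, steps=300, seed=7)

    ex = [s[0] for s in splits["eval"]]
    ey = [s[1] for s in splits["eval"]]
    em = [s[2] for s in splits["eval"]]
    ident = consistency_eval(identity_translator, seg, ex, em, NUM_CLASSES,
                             images_y=ey, masks_y=em)

    per_seed = {}
    keep_model = None
    for seed in SEEDS:
        out = {}
        model_f, _, rec_f = train(splits["train_x"], splits["train_y"], cfg,
                                  root / f"full_{seed}", steps=TRAIN_STEPS, seed=seed)
        model_a, _, _ = train(splits["train_x"], splits["train_y"],
                              make_ablation(cfg, "no_semantic"),
                              root / f"abl_{seed}", steps=TRAIN_STEPS, seed=seed)
        epoch = N_TRAIN
        out["sem_first_epoch"] = float(np.mean([r["semantic"] for r in rec_f[:epoch]]))
        out["sem_final_epoch"] = float(np.mean([r["semantic"] for r in rec_f[-epoch:]]))
        out["full"] = consistency_eval(checkpoint_translator(model_f), seg,
                                       ex, em, NUM_CLASSES)["translated"]
        out["no_semantic"] = consistency_eval(checkpoint_translator(model_a), seg,
                                              ex, em, NUM_CLASSES)["translated"]
        per_seed[seed] = out
        if keep_model is None:
            keep_model = model_f

    result = {
        "spec": spec,
        "splits": splits,
        "seg_model": seg,
        "identity": ident["translated"],
        "reference_on_y": ident["reference"],
        "per_seed": per_seed,
        "full_model_seed1": keep_model,
    }
    _cache["result"] = result
    return result
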