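"""Shared fixtures: small procedural scenes and a desk-scale loss config.

The heavy end-to-end study (three seeded training runs of the full model
and the no-semantic ablation, plus the segmentation-based evaluations) is
expensive, so it runs once per session and is shared by every test that
needs its artifacts.
"""

from dataclasses import replace

import numpy as np
import pytest

from constructs.contrastive import NceConfig
from constructs.scenes import SceneSpec, generate_scene
from constructs.semantic import MsSsimConfig
from constructs.training import LossConfig


@pytest.fixture(scope="session")
def scene_spec():
    return SceneSpec(image_size=(64, 64), seed=0)


@pytest.fixture(scope="session")
def paired_scenes(scene_spec):
    """Eight paired (x, y, mask) scenes at 64 x 64."""
    return [generate_scene(replace(scene_spec, seed=500 + i)) for i in range(8)]


@pytest.fixture(scope="session")
def small_loss_cfg():
    """Desk-scale objective configuration used across training tests."""
    return LossConfig(nce=NceConfig(num_patches=32, embed_dim=32),
                      msssim=MsSsimConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tiny_images(n, size=16, seed=0):
    """n random RGB images in [0, 1] (divisible-by-4 sizes for the nets)."""
    r = np.random.default_rng(seed)
    return [r.random((size, size, 3)) for _ in range(n)]


@pytest.fixture(scope="session")
def study():
    """Scaled-down translation study shared by the acceptance tests.

    Trains the full objective and the no-semantic ablation for 500 steps on
    128 + 128 unpaired 64 x 64 scenes for three seeds, evaluates the
    consistency scheme against an identity-passthrough control, and keeps
    the seed-1 full model for the downstream harness.
    """
    from tests._study import run_study

    return run_study()
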