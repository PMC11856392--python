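"""Shared fixtures: in-memory scene batches, on-disk datasets and trained
models reused across the suite (training is CPU-bound, so expensive fixtures
are session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from grapeyield import (
    CNNYieldRegressor,
    DatasetConfig,
    SceneParams,
    UNetSegmenter,
    generate_dataset,
    overlay,
    render_scene,
)
from grapeyield.simulate import derive_seed

EASY_PARAMS = SceneParams(
    rows=48, cols=64, color_variety="blue", foliage_level="low",
    background="white", packing_tightness=0.5,
)

# fewer berries per bunch so fully disjoint disks fit the 48x64 frame
NOOCC_PARAMS = SceneParams(
    rows=48, cols=64, color_variety="blue", foliage_level="low",
    background="white", packing_tightness=0.0, foliage_density=0.0,
    weight_noise_sd=0.0, berries_min=5, berries_max=15,
)


def render_batch(params: SceneParams, n: int, stream: int):
    return [render_scene(params, derive_seed(stream, i)) for i in range(n)]


@pytest.fixture(scope="session")
def easy_scenes():
    """High-contrast scenes (blue grapes, white wall, sparse foliage)."""
    return render_batch(EASY_PARAMS, 100, stream=101)


@pytest.fixture(scope="session")
def easy_arrays(easy_scenes):
    X = np.stack([s.image for s in easy_scenes])
    Y = np.stack([s.mask for s in easy_scenes])
    return X, Y


@pytest.fixture(scope="session")
def easy_segmenters(easy_arrays):
    """Three segmenters (seeds 0-2) trained on 80 easy scenes, plus the
    held-out 20-scene test arrays."""
    X, Y = easy_arrays
    models = [
        UNetSegmenter(depth=3, base_channels=8, epochs=10, learning_rate=2e-3,
                      seed=s).fit(X[:80], Y[:80])
        for s in (0, 1, 2)
    ]
    return models, X[80:], Y[80:]


@pytest.fixture(scope="session")
def noocc_scenes():
    """Zero-occlusion, noise-free scenes: every berry visible, weight exactly
    1.5 g per berry."""
    return render_batch(NOOCC_PARAMS, 150, stream=303)


@pytest.fixture(scope="session")
def noocc_counters(noocc_scenes):
    """Three counters (seeds 0-2) trained on 120 masked zero-occlusion
    scenes, plus held-out arrays."""
    X = np.stack([overlay(s.image, s.mask).image for s in noocc_scenes])
    Y = np.stack([[s.total_count, s.weight_g] for s in noocc_scenes]).astype(float)
    models = [
        CNNYieldRegressor(epochs=15, seed=s).fit(X[:120], Y[:120]) for s in (0, 1, 2)
    ]
    return models, X[120:], Y[120:]


@pytest.fixture(scope="session")
def lowcontrast_dataset(tmp_path_factory):
    """On-disk dataset for the ablation preset: green grapes over a green
    bokeh background (the colour regime where segmentation matters most)."""
    out = tmp_path_factory.mktemp("lowcontrast")
    cfg = DatasetConfig(
        out_dir=str(out), colors=("green",), foliage_levels=("medium",),
        backgrounds=("green_bokeh",), resolution_tiers=("medium",),
        arrangements_per_condition=35, base_seed=77,
        scene=SceneParams(packing_tightness=0.6),
    )
    manifest = generate_dataset(cfg)
    return manifest, out


@pytest.fixture(scope="session")
def lowcontrast_segmenter(lowcontrast_dataset):
    """One segmenter trained on the low-contrast dataset's train split."""
    from grapeyield.segmentation import load_training_arrays, split_by_group

    manifest, root = lowcontrast_dataset
    train_df, _ = split_by_group(manifest, 0.2, seed=0)
    X, Y = load_training_arrays(train_df, root, shape=(48, 64))
    return UNetSegmenter(depth=3, base_channels=8, epochs=20, learning_rate=2e-3,
                         seed=0).fit(X, Y)


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """On-disk dataset spanning blue and green varieties on green bokeh, used
    by the resolution and colour segmentation studies."""
    out = tmp_path_factory.mktemp("study")
    cfg = DatasetConfig(
        out_dir=str(out), colors=("blue", "green"), foliage_levels=("medium",),
        backgrounds=("green_bokeh",), resolution_tiers=("medium",),
        arrangements_per_condition=25, base_seed=55,
        scene=SceneParams(packing_tightness=0.5),
    )
    manifest = generate_dataset(cfg)
    return manifest, out
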