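"""Shared fixtures: synthetic annotated image pairs and one trained model.

The trained segmenter is expensive relative to everything else, so it is
built once per session on 40 quadrant tiles drawn from ten default-regime
scenes (three of which carry writing and glue artifacts labelled as
background, so the classifier learns to ignore them).
"""

from __future__ import annotations

import numpy as np
import pytest

from voidspot.annotations import AnnotationSet, mask_to_roi
from voidspot.detectors import finetune
from voidspot.synth_scenes import SceneConfig, generate_scene
from voidspot.training_data import build_training_set


def annotated_pairs(n_scenes: int, seed0: int, flags: tuple[str, ...] = (),
                    **config_kwargs):
    """Generate (GrayImage, AnnotationSet) pairs from synthetic truth."""
    pairs = []
    for i in range(n_scenes):
        kwargs = dict(n_spots=6 + (i % 5))
        kwargs.update(config_kwargs)
        cfg = SceneConfig(seed=seed0 + i, artifact_flags=flags, **kwargs)
        img, truth = generate_scene(cfg)
        shape = img.pixels.shape
        rois = [mask_to_roi(inst.to_mask(shape), name=f"{inst.spot_id:04d}")
                for inst in truth.spots.instances]
        pairs.append((img, AnnotationSet(image_label=img.label, rois=rois)))
    return pairs


@pytest.fixture(scope="session")
def trained_model():
    """Pixel-classification segmenter trained on 40 synthetic 256x256 tiles."""
    pairs = annotated_pairs(7, seed0=1000)
    pairs += annotated_pairs(3, seed0=2000, flags=("writing", "glue_blob"))
    samples = build_training_set(pairs, n_select=40, seed=7)
    return finetune(samples, epochs=8, learning_rate=0.1, seed=7)


def interior_spot_scenes(n_scenes: int, seed0: int = 200, size: int = 512,
                         margin: int = 31):
    """Yield (image, truth) for clean scenes whose spots all stay at least
    ``margin`` px clear of the 2x2 tile seams, so per-tile background
    estimation sees the same neighbourhood as the whole-frame run."""
    half = size // 2
    found = 0
    seed = seed0
    while found < n_scenes:
        cfg = SceneConfig(width=size, height=size, n_spots=6,
                          spot_radius_range=(5, 12), noise_sd=0.0,
                          edge_blur_sd=0.0, min_gap_px=30, seed=seed)
        img, truth = generate_scene(cfg)
        seed += 1
        clear = all(
            abs(inst.rows - half).min() > margin and
            abs(inst.cols - half).min() > margin
            for inst in truth.spots.instances
        )
        if clear:
            found += 1
            yield img, truth


@pytest.fixture
def oracle_scene_config():
    """Factory for scenes in the exact-detection regime: noise-free,
    hard-edged spots, gradient-only background, generous spacing."""

    def make(seed: int, **overrides):
        kwargs = dict(width=256, height=256, n_spots=6, spot_radius_range=(4, 9),
                      noise_sd=0.0, edge_blur_sd=0.0, min_gap_px=24, seed=seed)
        kwargs.update(overrides)
        return SceneConfig(**kwargs)

    return make
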