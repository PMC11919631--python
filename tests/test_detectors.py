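"""Baseline and learned detector contracts."""

import numpy as np
import pytest

from voidspot.detectors import (BaselineParams, DetectorModel, LearnedDetector,
                                SpotInstance, SpotSet, baseline_detect, detect,
                                finetune, load_model, save_model)
from voidspot.evaluation import match_spots
from voidspot.raster_io import GrayImage
from voidspot.synth_scenes import SceneConfig, generate_scene
from voidspot.training_data import TrainingSample


class TestSpotTypes:
    def test_instance_invariants(self):
        inst = SpotInstance(1, np.array([0, 0, 1]), np.array([0, 1, 0]), score=0.7)
        assert inst.area_px == 3
        assert inst.centroid == (pytest.approx(1 / 3), pytest.approx(1 / 3))
        with pytest.raises(ValueError):
            SpotInstance(1, np.array([0]), np.array([0]), score=1.5)

    def test_set_requires_sequential_ids(self):
        good = SpotInstance(1, np.array([0]), np.array([0]))
        bad = SpotInstance(3, np.array([1]), np.array([1]))
        with pytest.raises(ValueError, match="sequential"):
            SpotSet("x", [good, bad], "baseline")


class TestBaseline:
    def test_blank_image_empty(self):
        img = GrayImage(pixels=np.full((128, 128), 120, dtype=np.uint8))
        assert len(baseline_detect(img)) == 0

    @pytest.mark.parametrize("seed", [0, 17, 42])
    def test_exact_truth_on_clean_scenes(self, oracle_scene_config, seed):
        img, truth = generate_scene(oracle_scene_config(seed))
        det = baseline_detect(img, BaselineParams(bg_window_px=61))
        assert sorted(i.area_px for i in det.instances) == \
               sorted(i.area_px for i in truth.spots.instances)

    def test_deterministic(self, oracle_scene_config):
        img, _ = generate_scene(oracle_scene_config(9, noise_sd=3.0))
        a = baseline_detect(img)
        b = baseline_detect(img)
        assert [(i.area_px, i.centroid) for i in a.instances] == \
               [(i.area_px, i.centroid) for i in b.instances]

    def test_inverse_spot_requires_detect_dark(self):
        cfg = SceneConfig(seed=6, n_spots=1, contrast_range=(-70, -50))
        img, _ = generate_scene(cfg)
        assert len(baseline_detect(img, BaselineParams(detect_dark=True))) == 1
        assert len(baseline_detect(img, BaselineParams(detect_dark=False))) == 0

    def test_window_validation(self):
        img = GrayImage(pixels=np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(ValueError, match="bg_window_px"):
            baseline_detect(img, BaselineParams(bg_window_px=61))
        with pytest.raises(ValueError):
            BaselineParams(bg_window_px=10)  # even


def _tiny_sample(seed=0, n_spots=2):
    cfg = SceneConfig(width=96, height=96, seed=seed, n_spots=n_spots,
                      spot_radius_range=(5, 10))
    img, truth = generate_scene(cfg)
    masks = [inst.to_mask(img.pixels.shape) for inst in truth.spots.instances]
    return TrainingSample(tile=img, masks=masks)


class TestFinetune:
    def test_smoke_one_sample_one_epoch(self):
        model = finetune([_tiny_sample()], epochs=1, seed=0)
        assert model.is_trained
        assert model.metadata["n_samples"] == 1
        assert model.metadata["pretrained"] is False

    def test_pure_background_samples_allowed_but_not_alone(self):
        empty = _tiny_sample(seed=1, n_spots=0)
        with pytest.raises(ValueError, match="instance"):
            finetune([empty], epochs=1, seed=0)
        model = finetune([empty, _tiny_sample(seed=2)], epochs=1, seed=0)
        assert model.metadata["n_samples"] == 2

    def test_validation(self):
        with pytest.raises(ValueError):
            finetune([], epochs=1, seed=0)
        with pytest.raises(ValueError, match="epochs"):
            finetune([_tiny_sample()], epochs=0, seed=0)


class TestDetect:
    def test_untrained_model_rejected(self):
        img = GrayImage(pixels=np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(RuntimeError, match="trained"):
            detect(DetectorModel(), img)

    def test_blank_image_empty(self, trained_model):
        img = GrayImage(pixels=np.full((128, 128), 120, dtype=np.uint8))
        assert len(detect(trained_model, img)) == 0

    def test_postconditions_on_busy_scene(self, trained_model):
        img, _ = generate_scene(SceneConfig(seed=77, n_spots=10))
        spots = detect(trained_model, img)
        for inst in spots.instances:
            assert inst.area_px >= trained_model.min_area_px
            assert inst.score >= trained_model.score_threshold
        spots.validate_disjoint(img.width)
        scores = [i.score for i in spots.instances]
        assert scores == sorted(scores, reverse=True)

    def test_recall_on_training_distribution(self, trained_model):
        # spots of >= 1 uL equivalent must be recovered at IoU 0.5
        recalls = []
        for seed in (300, 301, 302, 303):
            img, truth = generate_scene(SceneConfig(seed=seed, n_spots=6))
            pred = detect(trained_model, img)
            recalls.append(match_spots(pred, truth.spots, 0.5).recall)
        assert np.mean(recalls) >= 0.9

    def test_checkpoint_roundtrip(self, trained_model, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(trained_model, path)
        back = load_model(path)
        img, _ = generate_scene(SceneConfig(seed=55, n_spots=4))
        a = detect(trained_model, img)
        b = detect(back, img)
        assert [(i.area_px, i.score) for i in a.instances] == \
               [(i.area_px, i.score) for i in b.instances]
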