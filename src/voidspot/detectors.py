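"""Spot detectors behind one contract.

Two interchangeable detectors produce :class:`SpotSet` objects:

* :func:`baseline_detect` — a deterministic median-background thresholding
  detector.  The background is estimated with a sliding-window median (which
  tracks uneven illumination gradients), the residual is thresholded at a
  multiple of its standard deviation, and 8-connected components become
  instances.  On clean scenes this is exact, which makes it the reference
  oracle for everything downstream; it is also a practical non-ML fallback.

* :func:`finetune` / :func:`detect` — a trainable instance segmenter built
  as a gradient-boosted pixel classifier over a multi-scale filter bank
  (Gaussian smoothings, gradient magnitudes and background-subtracted
  residuals), followed by hole filling and connected-component instancing.
  Training labels come from annotated tiles; because the classifier sees
  local contrast and texture rather than raw intensity, it transfers across
  illumination gradients and detects inverse (darker-than-paper) spots when
  trained on them.

Within a :class:`SpotSet` no two instances share a pixel; contested pixels
are awarded to the higher-scoring instance (ties to the lower id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Protocol, Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, sobel
from skimage.filters.rank import median as rank_median
from sklearn.ensemble import HistGradientBoostingClassifier

from .raster_io import GrayImage, SpotAreaRecord

__all__ = [
    "SpotInstance",
    "SpotSet",
    "BaselineParams",
    "DetectorModel",
    "Detector",
    "baseline_detect",
    "BaselineDetector",
    "finetune",
    "detect",
    "LearnedDetector",
    "save_model",
    "load_model",
]

Provenance = Literal["ground_truth", "baseline", "learned"]


@dataclass
class SpotInstance:
    """One detected or annotated urine spot.

    The mask is stored as parallel ``rows``/``cols`` index arrays into the
    image frame.  ``score`` is 1.0 for ground-truth and baseline instances.
    """

    spot_id: int
    rows: np.ndarray
    cols: np.ndarray
    score: float = 1.0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int32)
        self.cols = np.asarray(self.cols, dtype=np.int32)
        if self.rows.size != self.cols.size or self.rows.size == 0:
            raise ValueError("mask must be a non-empty set of (row, col) pixels")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.spot_id < 1:
            raise ValueError("spot_id must be positive")

    @property
    def area_px(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) mask centroid."""
        return float(self.cols.mean()), float(self.rows.mean())

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.rows, self.cols] = True
        return mask

    def linear_indices(self, width: int) -> np.ndarray:
        return self.rows.astype(np.int64) * width + self.cols


@dataclass
class SpotSet:
    """Per-image collection of disjoint spot instances, ids 1..n."""

    image_label: str
    instances: list[SpotInstance] = field(default_factory=list)
    provenance: Provenance = "ground_truth"

    def __post_init__(self) -> None:
        ids = [inst.spot_id for inst in self.instances]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"spot ids must be sequential 1..n, got {ids}")

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def total_area_px(self) -> int:
        return sum(inst.area_px for inst in self.instances)

    def to_area_records(self) -> list[SpotAreaRecord]:
        return [SpotAreaRecord(i.spot_id, i.area_px) for i in self.instances]

    def validate_disjoint(self, width: int) -> None:
        seen: np.ndarray | None = None
        for inst in self.instances:
            idx = inst.linear_indices(width)
            if seen is not None and np.intersect1d(seen, idx).size:
                raise ValueError("instances share pixels")
            seen = idx if seen is None else np.concatenate([seen, idx])


class Detector(Protocol):
    """Anything that maps a GrayImage to a SpotSet."""

    def detect(self, image: GrayImage) -> SpotSet: ...


def _instances_from_labels(labels: np.ndarray, scores_by_label=None) -> list[SpotInstance]:
    instances = []
    next_id = 1
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size == 0:
            continue
        score = 1.0 if scores_by_label is None else float(scores_by_label[lab])
        instances.append(SpotInstance(spot_id=next_id, rows=rows, cols=cols, score=score))
        next_id += 1
    return instances


_EIGHT = np.ones((3, 3), dtype=int)


# --------------------------------------------------------------------------
# Baseline thresholding detector
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineParams:
    """Median-background thresholding parameters.

    ``bg_window_px`` must be odd and comfortably larger than the biggest
    spot diameter, so the window median reflects paper rather than urine.
    ``min_threshold`` floors the residual threshold in intensity counts:
    8-bit quantization plus window reflection at the frame border leave a
    wobble of up to ~3 counts in the median-subtracted background even on
    a noise-free ramp, so thresholds below that are meaningless.
    """

    bg_window_px: int = 61
    k_sigma: float = 3.0
    min_area_px: int = 9
    detect_dark: bool = False
    min_threshold: float = 3.5

    def __post_init__(self) -> None:
        if self.bg_window_px < 3 or self.bg_window_px % 2 == 0:
            raise ValueError("bg_window_px must be odd and >= 3")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")


def baseline_detect(image: GrayImage, params: BaselineParams | None = None) -> SpotSet:
    """Detect spots by median background subtraction and thresholding.

    Deterministic: background = sliding median over ``bg_window_px``;
    residual = image − background; foreground = residual beyond
    ``k_sigma`` residual standard deviations (both signs when
    ``detect_dark``); 8-connected components with holes filled become
    instances; components below ``min_area_px`` are dropped.
    """
    params = params or BaselineParams()
    h, w = image.pixels.shape
    if params.bg_window_px > min(h, w):
        raise ValueError(
            f"bg_window_px={params.bg_window_px} exceeds image side {min(h, w)}"
        )
    footprint = np.ones((params.bg_window_px, params.bg_window_px), dtype=np.uint8)
    background = rank_median(image.pixels, footprint)
    residual = image.pixels.astype(np.int64) - background.astype(np.int64)
    sigma = float(residual.std())
    threshold = max(params.k_sigma * sigma, params.min_threshold)
    bright = residual > threshold
    fg = ndi.binary_fill_holes(bright)
    if params.detect_dark:
        dark = residual < -threshold
        fg = fg | ndi.binary_fill_holes(dark)
    labels, _ = ndi.label(fg, structure=_EIGHT)
    if params.min_area_px > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < params.min_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
    instances = _instances_from_labels(labels)
    return SpotSet(image_label=image.label, instances=instances, provenance="baseline")


@dataclass
class BaselineDetector:
    """:class:`Detector` wrapper around :func:`baseline_detect`."""

    params: BaselineParams = field(default_factory=BaselineParams)

    def detect(self, image: GrayImage) -> SpotSet:
        return baseline_detect(image, self.params)


# --------------------------------------------------------------------------
# Trainable pixel-classification segmenter
# --------------------------------------------------------------------------

#: Gaussian scales (px) for the per-pixel filter bank.
_SMOOTH_SIGMAS = (1.0, 2.0, 4.0)
_EDGE_SIGMAS = (1.0, 2.0, 4.0)
#: Large-scale background estimates subtracted to form residual channels.
_BACKGROUND_SIGMAS = (16.0, 32.0)


def pixel_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack, shape (H, W, F).

    Channels: raw intensity; Gaussian smoothings; Sobel gradient magnitude
    at several scales; and background-subtracted residuals (intensity minus
    a large-sigma Gaussian), which carry the urine/paper contrast
    independent of the illumination gradient.
    """
    img = pixels.astype(np.float32)
    chans = [img]
    for s in _SMOOTH_SIGMAS:
        chans.append(gaussian(img, sigma=s, preserve_range=True))
    for s in _EDGE_SIGMAS:
        chans.append(sobel(gaussian(img, sigma=s, preserve_range=True)))
    for s in _BACKGROUND_SIGMAS:
        chans.append(img - gaussian(img, sigma=s, preserve_range=True))
    return np.stack(chans, axis=-1).astype(np.float32)


@dataclass
class DetectorModel:
    """Trained pixel-classifier handle plus deployment thresholds."""

    classifier: HistGradientBoostingClassifier | None = None
    score_threshold: float = 0.5
    min_area_px: int = 9
    pixel_threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold outside [0, 1]")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")

    @property
    def is_trained(self) -> bool:
        return self.classifier is not None


#: Boosting rounds that one nominal training epoch corresponds to.
_ITER_PER_EPOCH = 10
#: Cap on training pixels drawn per sample tile.
_MAX_PIXELS_PER_SAMPLE = 12000


def finetune(samples: Sequence, epochs: int = 8, learning_rate: float = 0.1,
             seed: int = 0) -> DetectorModel:
    """Train the pixel-classification segmenter on annotated tiles.

    ``samples`` are :class:`~voidspot.training_data.TrainingSample` objects
    (or any object with ``.tile`` GrayImage and ``.masks`` list of boolean
    arrays).  Tiles with zero instances are allowed (pure background) but an
    all-empty training set raises.  One epoch corresponds to 10 boosting
    rounds; ``seed`` fixes pixel subsampling and the classifier's internal
    randomness.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if not samples:
        raise ValueError("training set is empty")
    n_instances = sum(len(s.masks) for s in samples)
    if n_instances == 0:
        raise ValueError("no sample contains an instance; nothing to learn")

    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for sample in samples:
        feats = pixel_features(sample.tile.pixels)
        h, w, nf = feats.shape
        label = np.zeros((h, w), dtype=bool)
        for mask in sample.masks:
            label |= mask
        flat_feats = feats.reshape(-1, nf)
        flat_label = label.ravel()
        fg_idx = np.flatnonzero(flat_label)
        bg_idx = np.flatnonzero(~flat_label)
        n_fg = min(fg_idx.size, _MAX_PIXELS_PER_SAMPLE // 3)
        n_bg = min(bg_idx.size, _MAX_PIXELS_PER_SAMPLE - n_fg)
        if n_fg:
            fg_idx = rng.choice(fg_idx, size=n_fg, replace=False)
            xs.append(flat_feats[fg_idx])
            ys.append(np.ones(n_fg, dtype=np.int8))
        if n_bg:
            bg_idx = rng.choice(bg_idx, size=n_bg, replace=False)
            xs.append(flat_feats[bg_idx])
            ys.append(np.zeros(n_bg, dtype=np.int8))
    X = np.concatenate(xs)
    y = np.concatenate(ys)

    clf = HistGradientBoostingClassifier(
        max_iter=epochs * _ITER_PER_EPOCH,
        learning_rate=learning_rate,
        max_depth=6,
        early_stopping=False,
        random_state=int(seed) % (2**31),
    )
    clf.fit(X, y)
    meta = {
        "n_samples": len(samples),
        "n_instances": n_instances,
        "n_pixels": int(X.shape[0]),
        "epochs": epochs,
        "learning_rate": learning_rate,
        "seed": int(seed),
        "pretrained": False,
    }
    return DetectorModel(classifier=clf, metadata=meta)


def detect(model: DetectorModel, image: GrayImage) -> SpotSet:
    """Run the trained segmenter on an image.

    Per-pixel void probabilities are thresholded, holes filled, 8-connected
    components instanced; each instance scores the mean probability over
    its mask.  Instances below ``min_area_px`` or ``score_threshold`` are
    dropped and survivors renumbered 1..n by descending score (ties by
    earlier raster position).
    """
    if not model.is_trained:
        raise RuntimeError("detector model has not been trained")
    feats = pixel_features(image.pixels)
    h, w, nf = feats.shape
    proba = model.classifier.predict_proba(feats.reshape(-1, nf))[:, 1].reshape(h, w)
    fg = ndi.binary_fill_holes(proba >= model.pixel_threshold)
    labels, n_raw = ndi.label(fg, structure=_EIGHT)
    candidates = []
    for lab in range(1, n_raw + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < model.min_area_px:
            continue
        score = float(proba[rows, cols].mean())
        if score < model.score_threshold:
            continue
        first = rows[0] * w + cols[0]
        candidates.append((score, -int(first), rows, cols))
    candidates.sort(key=lambda t: (t[0], t[1]), reverse=True)
    instances = [
        SpotInstance(spot_id=i, rows=rows, cols=cols, score=min(score, 1.0))
        for i, (score, _, rows, cols) in enumerate(candidates, start=1)
    ]
    return SpotSet(image_label=image.label, instances=instances, provenance="learned")


@dataclass
class LearnedDetector:
    """:class:`Detector` wrapper around a trained :class:`DetectorModel`."""

    model: DetectorModel

    def detect(self, image: GrayImage) -> SpotSet:
        return detect(self.model, image)


def save_model(model: DetectorModel, path: str | Path) -> None:
    joblib.dump(
        {
            "classifier": model.classifier,
            "score_threshold": model.score_threshold,
            "min_area_px": model.min_area_px,
            "pixel_threshold": model.pixel_threshold,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path: str | Path) -> DetectorModel:
    payload = joblib.load(path)
    return DetectorModel(**payload)
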