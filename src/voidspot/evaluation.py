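"""Detector performance metrics.

Two levels of scrutiny: a per-image count regression (ordinary least
squares of predicted spot count on ground-truth count, the field's
headline accuracy figure), and a stricter per-spot mask matching that
pairs predictions with truth greedily by descending IoU and reports
precision and recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CountRegression", "MatchResult", "count_regression", "match_spots"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountRegression:
    """OLS of predicted count (response) on truth count (predictor)."""

    slope: float
    intercept: float
    r_squared: float
    n_images: int

    def __post_init__(self) -> None:
        if self.n_images < 2:
            raise ValueError("need at least 2 images")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class MatchResult:
    """Greedy IoU matching of predicted against truth instances."""

    pairs: tuple[tuple[int, int, float], ...]  # (pred id, truth id, IoU)
    precision: float
    recall: float
    n_predicted: int
    n_truth: int


def count_regression(per_image: Sequence[tuple[int, int]]) -> CountRegression:
    """Fit predicted counts against truth counts across images."""
    data = np.asarray(per_image, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need (truth, predicted) counts for at least 2 images")
    truth, pred = data[:, 0], data[:, 1]
    if np.any(data < 0):
        raise ValueError("counts must be non-negative")
    if np.unique(truth).size < 2:
        raise ValueError("degenerate fit: all truth counts identical")
    res = stats.linregress(truth, pred)
    return CountRegression(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue**2), n_images=len(truth))


def match_spots(predicted, truth, iou_threshold: float = 0.5) -> MatchResult:
    """Match predicted to truth instances greedily by descending mask IoU.

    Pairs below ``iou_threshold`` are rejected; each instance matches at
    most once.  Precision is matches/|predicted| and recall is
    matches/|truth|; an empty side scores 1.0 by convention (logged).
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie strictly between 0 and 1")
    n_pred, n_truth = len(predicted.instances), len(truth.instances)
    if n_pred == 0 or n_truth == 0:
        if n_pred == 0 and n_truth > 0:
            logger.info("no predictions: precision 1.0 by convention")
        if n_truth == 0 and n_pred > 0:
            logger.info("no truth instances: recall 1.0 by convention")
        return MatchResult(pairs=(), precision=1.0 if n_pred == 0 else 0.0,
                           recall=1.0 if n_truth == 0 else 0.0,
                           n_predicted=n_pred, n_truth=n_truth)

    width = 1 + max(
        max(int(i.cols.max()) for i in predicted.instances),
        max(int(i.cols.max()) for i in truth.instances),
    )
    pred_idx = [np.sort(i.linear_indices(width)) for i in predicted.instances]
    truth_idx = [np.sort(i.linear_indices(width)) for i in truth.instances]

    candidates = []
    for pi, p in enumerate(pred_idx):
        for ti, t in enumerate(truth_idx):
            inter = np.intersect1d(p, t, assume_unique=True).size
            if inter == 0:
                continue
            iou = inter / (p.size + t.size - inter)
            if iou >= iou_threshold:
                candidates.append((iou, pi, ti))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    used_p, used_t = set(), set()
    pairs = []
    for iou, pi, ti in candidates:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        pairs.append((predicted.instances[pi].spot_id,
                      truth.instances[ti].spot_id, float(iou)))
    n_match = len(pairs)
    return MatchResult(pairs=tuple(pairs),
                       precision=n_match / n_pred,
                       recall=n_match / n_truth,
                       n_predicted=n_pred, n_truth=n_truth)
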