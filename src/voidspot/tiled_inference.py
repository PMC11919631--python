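"""Deploy a detector on images larger than its training tiles.

The frame is cut into a rows x cols grid, each tile optionally extended by
``overlap_px`` into its neighbours so spots near a seam are seen whole by
at least one tile.  Per-tile detections are translated back to the full
frame and merged: instances whose masks overlap with IoU >= 0.3 are fused
(union of masks, max score), and fragments of one spot cut by a
zero-overlap seam that touch across it are unioned.  Contested pixels go
to the higher-scoring instance so the merged set stays disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detectors import Detector, SpotInstance, SpotSet
from .raster_io import GrayImage

__all__ = ["TileSpec", "run_tiled", "merge_detections", "FUSE_IOU"]

#: Mask-IoU above which two per-tile detections are the same physical spot.
FUSE_IOU = 0.3


@dataclass(frozen=True)
class TileSpec:
    rows: int = 2
    cols: int = 2
    overlap_px: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.overlap_px < 0:
            raise ValueError("overlap_px must be >= 0")


def _grid_edges(n: int, parts: int) -> list[tuple[int, int]]:
    cuts = [round(i * n / parts) for i in range(parts + 1)]
    return [(cuts[i], cuts[i + 1]) for i in range(parts)]


def run_tiled(detector: Detector, image: GrayImage,
              spec: TileSpec | None = None) -> SpotSet:
    """Run ``detector`` per tile and merge into one full-frame SpotSet."""
    spec = spec or TileSpec()
    h, w = image.pixels.shape
    tile_h = h // spec.rows
    tile_w = w // spec.cols
    if min(tile_h, tile_w) < 2 * spec.overlap_px:
        raise ValueError(
            f"tile size {tile_w}x{tile_h} smaller than twice overlap_px={spec.overlap_px}"
        )
    per_tile: list[tuple[SpotSet, tuple[int, int]]] = []
    for y0, y1 in _grid_edges(h, spec.rows):
        for x0, x1 in _grid_edges(w, spec.cols):
            ey0 = max(y0 - spec.overlap_px, 0)
            ey1 = min(y1 + spec.overlap_px, h)
            ex0 = max(x0 - spec.overlap_px, 0)
            ex1 = min(x1 + spec.overlap_px, w)
            tile = GrayImage(pixels=image.pixels[ey0:ey1, ex0:ex1].copy(),
                             label=f"{image.label}_t{y0}_{x0}")
            per_tile.append((detector.detect(tile), (ex0, ey0)))
    provenance = per_tile[0][0].provenance if per_tile else "baseline"
    merged = merge_detections(per_tile, shape=(h, w))
    merged.image_label = image.label
    merged.provenance = provenance
    return merged


def _iou(idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    inter = np.intersect1d(idx_a, idx_b, assume_unique=True).size
    if inter == 0:
        return 0.0
    return inter / (idx_a.size + idx_b.size - inter)


def _touching(mask_a: np.ndarray, idx_b: np.ndarray, width: int) -> bool:
    """True if any pixel of b 8-neighbours (or equals) a pixel of a."""
    rows_b, cols_b = idx_b // width, idx_b % width
    h = mask_a.shape[0]
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr = rows_b + dr
            cc = cols_b + dc
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < width)
            if mask_a[rr[ok], cc[ok]].any():
                return True
    return False


def merge_detections(per_tile: Sequence[tuple[SpotSet, tuple[int, int]]],
                     shape: tuple[int, int], fuse_iou: float = FUSE_IOU) -> SpotSet:
    """Fuse per-tile detections (with (x, y) offsets) into one SpotSet."""
    h, w = shape
    entries = []  # (tile_index, linear indices sorted, score)
    for tile_idx, (spots, (dx, dy)) in enumerate(per_tile):
        for inst in spots.instances:
            rows = inst.rows.astype(np.int64) + dy
            cols = inst.cols.astype(np.int64) + dx
            if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
                raise ValueError("offset places a detection outside the frame")
            idx = np.sort(rows * w + cols)
            entries.append([tile_idx, idx, inst.score])

    n = len(entries)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(n):
        tile_i, idx_i, _ = entries[i]
        mask_i = np.zeros((h, w), dtype=bool)
        mask_i[idx_i // w, idx_i % w] = True
        for j in range(i + 1, n):
            tile_j, idx_j, _ = entries[j]
            if tile_i == tile_j:
                continue
            if _iou(idx_i, idx_j) >= fuse_iou:
                union(i, j)
            elif _touching(mask_i, idx_j, w):
                # seam-cut fragments of one spot touch across the boundary
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    fused = []  # (score, first_idx, linear indices)
    claimed = np.zeros(h * w, dtype=bool)
    # higher score claims contested pixels first
    ordered = sorted(groups.values(),
                     key=lambda g: (max(entries[i][2] for i in g),
                                    -min(entries[i][1][0] for i in g)),
                     reverse=True)
    for group in ordered:
        idx = np.unique(np.concatenate([entries[i][1] for i in group]))
        idx = idx[~claimed[idx]]
        if idx.size == 0:
            continue
        claimed[idx] = True
        score = max(entries[i][2] for i in group)
        fused.append((score, int(idx[0]), idx))

    instances = [
        SpotInstance(spot_id=k, rows=(idx // w).astype(np.int32),
                     cols=(idx % w).astype(np.int32), score=score)
        for k, (score, _, idx) in enumerate(fused, start=1)
    ]
    return SpotSet(image_label="", instances=instances, provenance="baseline")
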