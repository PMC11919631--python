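"""Build training sets from annotated full-size images.

Full filter photographs are split into four quadrant tiles (native
resolution, no resizing) and a seeded random subset of tiles becomes the
training set.  Each sample carries the tile raster plus the instance masks
of annotations clipped to that tile; an outline straddling a cut
contributes its clipped part to each side unless the fragment is smaller
than ``min_fragment_px``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import AnnotationSet, rois_to_masks
from .raster_io import GrayImage

__all__ = ["Tile", "TrainingSample", "split_quadrants", "build_training_set",
           "MIN_FRAGMENT_PX"]

#: Clipped mask slivers below this area are dropped from training labels.
MIN_FRAGMENT_PX = 4


@dataclass
class Tile:
    """One quadrant with its (x, y) offset in the parent image."""

    image: GrayImage
    x_offset: int
    y_offset: int


@dataclass
class TrainingSample:
    """One training tile plus its instance masks (tile-local boolean arrays)."""

    tile: GrayImage
    masks: list[np.ndarray]
    source_label: str = ""
    quadrant: int = 0


def split_quadrants(image: GrayImage) -> list[Tile]:
    """Split into four tiles that partition the frame exactly.

    Order: top-left, top-right, bottom-left, bottom-right.  Odd dimensions
    put the extra pixel in the right/bottom tiles, so a 2136x1424 frame
    yields four 1068x712 tiles.
    """
    h, w = image.pixels.shape
    if h < 2 or w < 2:
        raise ValueError(f"cannot split a {w}x{h} image into quadrants")
    h1, w1 = h // 2, w // 2
    tiles = []
    for qi, (y0, y1, x0, x1) in enumerate(
        [(0, h1, 0, w1), (0, h1, w1, w), (h1, h, 0, w1), (h1, h, w1, w)]
    ):
        sub = GrayImage(pixels=image.pixels[y0:y1, x0:x1].copy(),
                        label=f"{image.label}_q{qi + 1}")
        tiles.append(Tile(image=sub, x_offset=x0, y_offset=y0))
    return tiles


def reassemble(tiles: Sequence[Tile], width: int, height: int) -> GrayImage:
    """Losslessly rebuild the parent image from tiles and offsets."""
    out = np.zeros((height, width), dtype=np.uint8)
    for t in tiles:
        th, tw = t.image.pixels.shape
        out[t.y_offset:t.y_offset + th, t.x_offset:t.x_offset + tw] = t.image.pixels
    return GrayImage(pixels=out)


def build_training_set(pairs: Sequence[tuple[GrayImage, AnnotationSet]],
                       n_select: int, seed: int = 0,
                       min_fragment_px: int = MIN_FRAGMENT_PX,
                       ) -> list[TrainingSample]:
    """Quadrant-tile the annotated images and draw ``n_select`` tiles.

    Selection is a seeded uniform draw without replacement over all
    4 * len(pairs) candidate tiles.
    """
    candidates: list[TrainingSample] = []
    for image, annotations in pairs:
        h, w = image.pixels.shape
        truth = rois_to_masks(annotations, width=w, height=h)
        full_masks = [inst.to_mask((h, w)) for inst in truth.instances]
        for qi, tile in enumerate(split_quadrants(image)):
            th, tw = tile.image.pixels.shape
            y0, x0 = tile.y_offset, tile.x_offset
            masks = []
            for mask in full_masks:
                clipped = mask[y0:y0 + th, x0:x0 + tw]
                if clipped.sum() >= min_fragment_px:
                    masks.append(clipped.copy())
            candidates.append(TrainingSample(tile=tile.image, masks=masks,
                                             source_label=image.label,
                                             quadrant=qi + 1))
    if n_select > len(candidates):
        raise ValueError(
            f"n_select={n_select} exceeds the {len(candidates)} candidate tiles"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_select, replace=False)
    return [candidates[i] for i in sorted(chosen)]
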