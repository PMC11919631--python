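"""Raster and tabular I/O for the void spot pipeline.

Images travel through the pipeline as 8-bit single-channel rasters
(:class:`GrayImage`).  Higher bit depths are rescaled linearly over the
*dtype* range (not per-image min/max) so that a blank 16-bit frame stays
blank, and colour inputs are collapsed to luminance.  Per-spot pixel areas
are exchanged as two-column CSV files (``id,area``) named
``<label>_areas.csv``, and detection results can be rendered onto the
source image as an outline-plus-number overlay PNG.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image, ImageDraw

__all__ = [
    "GrayImage",
    "SpotAreaRecord",
    "FormatError",
    "read_image",
    "write_image",
    "read_spot_csv",
    "write_spot_csv",
    "write_overlay",
    "areas_csv_name",
]

#: ITU-R BT.601 luminance weights, the same convention PIL's "L" mode uses.
_LUMA = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Raised when a file cannot be read as the expected format."""


@dataclass
class GrayImage:
    """An 8-bit grayscale raster with an identifying label.

    ``pixels`` is a ``(height, width)`` ``uint8`` array; origin top-left,
    x rightward, y downward.
    """

    pixels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel grid")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class SpotAreaRecord:
    """One row of a per-image areas CSV: a numbered spot and its pixel area."""

    spot_id: int
    area_px: int

    def __post_init__(self) -> None:
        if self.spot_id < 1:
            raise ValueError(f"spot_id must be positive, got {self.spot_id}")
        if self.area_px < 1:
            raise ValueError(f"area_px must be >= 1, got {self.area_px}")


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Rescale any integer/float raster to uint8 over its dtype range."""
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        span = info.max - info.min
        scaled = (arr.astype(np.float64) - info.min) * (255.0 / span)
        return np.round(scaled).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        # Float rasters are assumed normalised to [0, 1].
        return np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    raise FormatError(f"unsupported pixel dtype {arr.dtype}")


def read_image(path: str | Path) -> GrayImage:
    """Read a TIFF or PNG photograph as an 8-bit grayscale image.

    Multi-channel frames are converted to luminance before rescaling;
    16-bit inputs are mapped linearly over the full dtype range.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise FormatError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise FormatError(f"unsupported channel count {arr.shape[2]} in {path}")
        arr = _to_uint8(arr)
        arr = np.round(arr.astype(np.float64) @ _LUMA).astype(np.uint8)
    elif arr.ndim == 2:
        arr = _to_uint8(arr)
    else:
        raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return GrayImage(pixels=arr, label=path.stem)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as TIFF or PNG depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        Image.fromarray(image.pixels, mode="L").save(path)


def areas_csv_name(label: str) -> str:
    """File name convention for per-image area tables."""
    return f"{label}_areas.csv"


def write_spot_csv(spots: Sequence[SpotAreaRecord], path: str | Path) -> None:
    """Write an areas CSV (header ``id,area``), rows in ascending id order."""
    records = sorted(spots, key=lambda r: r.spot_id)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "area"])
        for rec in records:
            writer.writerow([rec.spot_id, rec.area_px])


def read_spot_csv(path: str | Path) -> list[SpotAreaRecord]:
    """Read an areas CSV back into records.

    Raises :class:`FormatError` naming the offending line on malformed rows.
    """
    path = Path(path)
    records: list[SpotAreaRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row") from None
        if len(header) < 2:
            raise FormatError(f"{path}: line 1: expected two columns, got {len(header)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: missing column")
            try:
                spot_id, area = int(row[0]), int(row[1])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer value in {row[:2]!r}"
                ) from None
            try:
                records.append(SpotAreaRecord(spot_id=spot_id, area_px=area))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return records


# Fixed overlay style: outlines and id numbers in one colour.
_OVERLAY_COLOR = (255, 64, 64)


def write_overlay(image: GrayImage, spots, path: str | Path) -> None:
    """Render spot outlines and id numbers onto the image and save as PNG.

    ``spots`` is a :class:`~voidspot.detectors.SpotSet`.  Pixel dimensions
    are preserved; each instance contributes a 1-px outline plus its id
    drawn at the mask centroid.
    """
    h, w = image.pixels.shape
    for inst in spots.instances:
        if inst.rows.min() < 0 or inst.rows.max() >= h or inst.cols.min() < 0 or inst.cols.max() >= w:
            raise ValueError(f"spot {inst.spot_id} mask falls outside the {w}x{h} image")
    rgb = np.stack([image.pixels] * 3, axis=-1)
    for inst in spots.instances:
        mask = np.zeros((h, w), dtype=bool)
        mask[inst.rows, inst.cols] = True
        # 1-px outline: mask pixels with at least one non-mask 4-neighbour.
        interior = mask.copy()
        interior[1:, :] &= mask[:-1, :]
        interior[:-1, :] &= mask[1:, :]
        interior[:, 1:] &= mask[:, :-1]
        interior[:, :-1] &= mask[:, 1:]
        outline = mask & ~interior
        rgb[outline] = _OVERLAY_COLOR
    pil = Image.fromarray(rgb, mode="RGB")
    draw = ImageDraw.Draw(pil)
    for inst in spots.instances:
        cx, cy = inst.centroid
        draw.text((float(cx), float(cy)), str(inst.spot_id), fill=_OVERLAY_COLOR)
    pil.save(path, format="PNG")
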