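"""Fiji/ImageJ ROI annotations: binary codec and rasterization.

Urine spots are annotated in Fiji by outlining each spot; the ROI manager
saves one binary ``.roi`` record per spot, or a ``RoiSet.zip`` archive per
image.  This module reads and writes the subset of the ImageJ ROI format
used for such outlines (polygon, rectangle, oval, freehand) and rasterizes
annotations into per-spot instance masks.

The binary layout follows ImageJ's RoiDecoder: a 64-byte big-endian header
beginning with the magic ``Iout``, bounding-box shorts at offsets 8-15, a
vertex count at 16, relative int16 vertex coordinates after the header, and
an optional second header carrying the ROI name as UTF-16BE.

Rasterization convention: 0-based pixel indices with origin at the top-left
corner; vertex coordinates live on the pixel-corner grid, so pixel (x, y)
has its center at (x + 0.5, y + 0.5).  A pixel belongs to a polygon mask if
its center is inside under the even-odd rule, or if it lies on the
Bresenham outline of the polygon (annotators trace the visible spot edge,
so boundary pixels count as spot).
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from skimage.draw import line as _bresenham

__all__ = [
    "PolygonROI",
    "AnnotationSet",
    "RoiFormatError",
    "UnsupportedRoiKind",
    "read_fiji_rois",
    "write_fiji_roi",
    "write_fiji_roiset",
    "rois_to_masks",
    "fill_polygon",
    "fill_oval",
    "mask_to_roi",
]

RoiKind = Literal["polygon", "freehand", "oval", "rectangle"]

_MAGIC = b"Iout"
_VERSION = 227

# ImageJ ROI type bytes.
_TYPE_TO_KIND = {0: "polygon", 1: "rectangle", 2: "oval", 7: "freehand"}
_KIND_TO_TYPE = {v: k for k, v in _TYPE_TO_KIND.items()}
_TYPE_NAMES = {
    3: "line", 4: "freeline", 5: "polyline", 6: "noRoi",
    8: "traced", 9: "angle", 10: "point",
}


class RoiFormatError(ValueError):
    """Raised on malformed ROI bytes (bad magic, truncated record)."""


class UnsupportedRoiKind(ValueError):
    """Raised when an ROI record encodes a kind outside the supported subset."""


@dataclass
class PolygonROI:
    """One spot outline.

    ``vertices`` are ordered ``(x, y)`` pixel-corner coordinates.  For
    ``oval`` and ``rectangle`` kinds the vertices are the four bounding-box
    corners (top-left first, clockwise).
    """

    name: str
    kind: RoiKind
    vertices: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.kind in ("polygon", "freehand") and len(self.vertices) < 3:
            raise ValueError(f"ROI {self.name!r}: {self.kind} needs >= 3 vertices")
        if self.kind in ("oval", "rectangle") and len(self.vertices) != 4:
            raise ValueError(f"ROI {self.name!r}: {self.kind} needs 4 bounding-box corners")
        for x, y in self.vertices:
            if x < 0 or y < 0:
                raise ValueError(f"ROI {self.name!r}: negative coordinate ({x}, {y})")

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """(left, top, right, bottom) over the vertex set."""
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return min(xs), min(ys), max(xs), max(ys)


@dataclass
class AnnotationSet:
    """All spot outlines for one image."""

    image_label: str
    rois: list[PolygonROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate ROI names in set: {dupes}")


def _bbox_corners(left: int, top: int, right: int, bottom: int) -> list[tuple[int, int]]:
    return [(left, top), (right, top), (right, bottom), (left, bottom)]


def encode_roi(roi: PolygonROI) -> bytes:
    """Serialize one ROI to ImageJ .roi bytes (big-endian, version 227)."""
    left, top, right, bottom = roi.bounding_box
    roi_type = _KIND_TO_TYPE[roi.kind]
    if roi.kind in ("polygon", "freehand"):
        n = len(roi.vertices)
        xs = [x - left for x, _ in roi.vertices]
        ys = [y - top for _, y in roi.vertices]
    else:
        n = 0
        xs, ys = [], []
    header = bytearray(64)
    header[0:4] = _MAGIC
    struct.pack_into(">h", header, 4, _VERSION)
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    coord_bytes = struct.pack(f">{n}h", *xs) + struct.pack(f">{n}h", *ys)
    hdr2_offset = 64 + len(coord_bytes)
    struct.pack_into(">i", header, 60, hdr2_offset)
    # Second header: 64 bytes; name offset at +16, name length at +20.
    name_bytes = roi.name.encode("utf-16-be")
    header2 = bytearray(64)
    struct.pack_into(">i", header2, 16, hdr2_offset + 64)
    struct.pack_into(">i", header2, 20, len(roi.name))
    return bytes(header) + coord_bytes + bytes(header2) + name_bytes


def decode_roi(data: bytes, fallback_name: str = "") -> PolygonROI:
    """Parse one ImageJ .roi record."""
    if len(data) < 64:
        raise RoiFormatError("truncated ROI record (< 64 byte header)")
    if data[0:4] != _MAGIC:
        raise RoiFormatError(f"bad magic bytes {data[0:4]!r}, expected {_MAGIC!r}")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack_from(">4h", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    (hdr2_offset,) = struct.unpack_from(">i", data, 60)

    name = fallback_name
    if hdr2_offset > 0 and hdr2_offset + 64 <= len(data):
        name_offset, name_length = struct.unpack_from(">2i", data, hdr2_offset + 16)
        if name_offset > 0 and name_length > 0:
            raw = data[name_offset:name_offset + 2 * name_length]
            name = raw.decode("utf-16-be")

    if roi_type not in _TYPE_TO_KIND:
        kind_name = _TYPE_NAMES.get(roi_type, f"type-{roi_type}")
        raise UnsupportedRoiKind(
            f"ROI {name or fallback_name or '<unnamed>'!r}: "
            f"unsupported kind {kind_name!r}"
        )
    kind: RoiKind = _TYPE_TO_KIND[roi_type]  # type: ignore[assignment]

    if kind in ("polygon", "freehand"):
        need = 64 + 4 * n
        if len(data) < need:
            raise RoiFormatError(f"truncated coordinate block ({len(data)} < {need} bytes)")
        xs = struct.unpack_from(f">{n}h", data, 64)
        ys = struct.unpack_from(f">{n}h", data, 64 + 2 * n)
        vertices = [(left + x, top + y) for x, y in zip(xs, ys)]
    else:
        vertices = _bbox_corners(left, top, right, bottom)
    return PolygonROI(name=name or "roi", kind=kind, vertices=vertices)


def write_fiji_roi(roi: PolygonROI, path: str | Path) -> None:
    Path(path).write_bytes(encode_roi(roi))


def write_fiji_roiset(annotations: AnnotationSet, path: str | Path) -> None:
    """Write a RoiSet.zip archive, members sorted by ROI name."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for roi in sorted(annotations.rois, key=lambda r: r.name):
            zf.writestr(f"{roi.name}.roi", encode_roi(roi))


def read_fiji_rois(path: str | Path) -> AnnotationSet:
    """Read a single .roi file or a RoiSet zip archive of .roi members."""
    path = Path(path)
    if zipfile.is_zipfile(path):
        rois = []
        with zipfile.ZipFile(path) as zf:
            for member in sorted(zf.namelist()):
                if not member.lower().endswith(".roi"):
                    continue
                stem = Path(member).stem
                rois.append(decode_roi(zf.read(member), fallback_name=stem))
        return AnnotationSet(image_label=path.stem, rois=rois)
    roi = decode_roi(path.read_bytes(), fallback_name=path.stem)
    return AnnotationSet(image_label=path.stem, rois=[roi])


# --------------------------------------------------------------------------
# Rasterization
# --------------------------------------------------------------------------

def fill_polygon(vertices, width: int, height: int) -> np.ndarray:
    """Rasterize a closed polygon to a boolean mask.

    Fill: pixel centers (x+0.5, y+0.5) inside under the even-odd
    (ray-crossing) rule.  Outline: Bresenham lines between consecutive
    vertices are added, clipped to the frame.
    """
    verts = np.asarray(vertices, dtype=np.float64)
    xs, ys = verts[:, 0], verts[:, 1]
    x0 = max(int(np.floor(xs.min())) - 1, 0)
    x1 = min(int(np.ceil(xs.max())) + 1, width)
    y0 = max(int(np.floor(ys.min())) - 1, 0)
    y1 = min(int(np.ceil(ys.max())) + 1, height)
    mask = np.zeros((height, width), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask

    cx = np.arange(x0, x1) + 0.5
    cy = np.arange(y0, y1) + 0.5
    px, py = np.meshgrid(cx, cy)
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        xa, ya = verts[i]
        xb, yb = verts[(i + 1) % n]
        if ya == yb:
            continue
        crosses = (py >= min(ya, yb)) & (py < max(ya, yb))
        x_at = xa + (py - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (px < x_at)
    mask[y0:y1, x0:x1] = inside

    # Boundary pixels traced by the annotator count as spot.
    iv = np.round(verts).astype(int)
    for i in range(n):
        rr, cc = _bresenham(iv[i, 1], iv[i, 0], iv[(i + 1) % n, 1], iv[(i + 1) % n, 0])
        keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
        mask[rr[keep], cc[keep]] = True
    return mask


def fill_oval(left: int, top: int, right: int, bottom: int,
              width: int, height: int) -> np.ndarray:
    """Rasterize an oval by its bounding box: centers inside the ellipse."""
    rx = (right - left) / 2.0
    ry = (bottom - top) / 2.0
    ox = left + rx
    oy = top + ry
    mask = np.zeros((height, width), dtype=bool)
    if rx <= 0 or ry <= 0:
        return mask
    x0, x1 = max(left, 0), min(right + 1, width)
    y0, y1 = max(top, 0), min(bottom + 1, height)
    cx = np.arange(x0, x1) + 0.5
    cy = np.arange(y0, y1) + 0.5
    px, py = np.meshgrid(cx, cy)
    inside = ((px - ox) / rx) ** 2 + ((py - oy) / ry) ** 2 <= 1.0
    mask[y0:y1, x0:x1] = inside
    return mask


def roi_to_mask(roi: PolygonROI, width: int, height: int) -> np.ndarray:
    left, top, right, bottom = roi.bounding_box
    if roi.kind == "rectangle":
        mask = np.zeros((height, width), dtype=bool)
        mask[top:bottom, left:right] = True
        return mask
    if roi.kind == "oval":
        return fill_oval(left, top, right, bottom, width, height)
    return fill_polygon(roi.vertices, width, height)


def rois_to_masks(annotations: AnnotationSet, width: int, height: int):
    """Rasterize every ROI into a ground-truth :class:`~voidspot.detectors.SpotSet`.

    Spots are numbered 1..n in ROI order, each with score 1.0 and
    ground-truth provenance.  Vertices outside ``[0,width)x[0,height)``
    raise a bounds error naming the ROI.
    """
    from .detectors import SpotInstance, SpotSet  # cycle-free at runtime

    instances = []
    for i, roi in enumerate(annotations.rois, start=1):
        for x, y in roi.vertices:
            if not (0 <= x <= width and 0 <= y <= height):
                raise ValueError(
                    f"ROI {roi.name!r}: vertex ({x}, {y}) outside {width}x{height} frame"
                )
        mask = roi_to_mask(roi, width, height)
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        instances.append(SpotInstance(spot_id=i, rows=rows, cols=cols, score=1.0))
    return SpotSet(image_label=annotations.image_label, instances=instances,
                   provenance="ground_truth")


def mask_to_roi(mask: np.ndarray, name: str) -> PolygonROI:
    """Trace a connected boolean mask into a freehand outline ROI.

    The marching-squares contour at level 0.5 is mapped from pixel-center
    to pixel-corner coordinates and rounded to the integer grid the ROI
    format stores, so the re-rasterized mask matches the input to within
    about one boundary pixel.
    """
    from skimage.measure import find_contours

    padded = np.pad(mask, 1).astype(float)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError(f"mask for ROI {name!r} is empty")
    contour = max(contours, key=len)
    # padded pixel-center (r, c) -> original corner coords (x, y)
    ys = contour[:, 0] - 0.5
    xs = contour[:, 1] - 0.5
    pts = np.round(np.column_stack([xs, ys])).astype(int)
    pts = np.clip(pts, 0, None)
    # Drop consecutive duplicates introduced by rounding.
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        x0, y0 = pts[0]
        pts = np.array([[x0, y0], [x0 + 1, y0], [x0 + 1, y0 + 1], [x0, y0 + 1]])
    return PolygonROI(name=name, kind="freehand",
                      vertices=[(int(x), int(y)) for x, y in pts])
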