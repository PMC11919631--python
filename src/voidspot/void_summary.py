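"""Per-filter aggregation of detected spots into summary rows.

Each filter's per-spot pixel areas are converted to volumes with the
standard curve and binned: primary voids are deliberate voiding events of
more than 20 μL; micro voids are 1–20 μL deposits, typically marking
behaviour; spots under 1 μL are more likely claw marks or fur
contamination and are excluded from every reported count and total.
Volumes are summed before rounding and every reported volume carries one
decimal place.  A folder of ``<label>_areas.csv`` files aggregates into a
``VoidDataSummary.csv`` written into the same folder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .calibration import CalibrationCurve, area_to_volume
from .raster_io import FormatError, GrayImage, SpotAreaRecord, read_spot_csv

__all__ = [
    "PRIMARY_MIN_UL", "MICRO_MIN_UL", "SUMMARY_HEADER", "SUMMARY_FILENAME",
    "SpotMeasurement", "FilterSummary",
    "segregate_background", "summarize", "summarize_folder",
]

logger = logging.getLogger(__name__)

#: Primary voids are strictly greater than 20 μL; exactly 20 μL is micro.
PRIMARY_MIN_UL = 20.0
#: Spots below 1 μL are excluded; exactly 1 μL is micro.
MICRO_MIN_UL = 1.0

SUMMARY_FILENAME = "VoidDataSummary.csv"
SUMMARY_HEADER = [
    "Image",
    "Total_Volume (μl)",
    "Total_Spot_No.",
    "Primary_Voids",
    "Primary_Voids_Mean_Volume (μl)",
    "Micro_Voids",
]

Bin = Literal["primary", "micro", "sub_threshold"]


@dataclass(frozen=True)
class SpotMeasurement:
    spot_id: int
    area_px: int
    volume_ul: float
    bin: Bin


@dataclass(frozen=True)
class FilterSummary:
    """One summary row for one filter image."""

    image_label: str
    total_volume_ul: float
    total_spot_count: int
    primary_count: int
    primary_mean_volume_ul: float
    micro_count: int

    def __post_init__(self) -> None:
        if self.total_spot_count != self.primary_count + self.micro_count:
            raise ValueError("total spot count must equal primary + micro")
        if min(self.total_spot_count, self.primary_count, self.micro_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.total_volume_ul < 0:
            raise ValueError("total volume must be non-negative")

    def as_row(self) -> list[str]:
        return [
            self.image_label,
            f"{self.total_volume_ul:.1f}",
            str(self.total_spot_count),
            str(self.primary_count),
            f"{self.primary_mean_volume_ul:.1f}",
            str(self.micro_count),
        ]


def _bin_volume(volume_ul: float) -> Bin:
    if volume_ul > PRIMARY_MIN_UL:
        return "primary"
    if volume_ul >= MICRO_MIN_UL:
        return "micro"
    return "sub_threshold"


def measure_spots(spots: Sequence[SpotAreaRecord],
                  curve: CalibrationCurve) -> list[SpotMeasurement]:
    return [
        SpotMeasurement(
            spot_id=rec.spot_id, area_px=rec.area_px,
            volume_ul=(v := area_to_volume(curve, rec.area_px)),
            bin=_bin_volume(v),
        )
        for rec in spots
    ]


def summarize(label: str, spots: Sequence[SpotAreaRecord],
              curve: CalibrationCurve) -> FilterSummary:
    """Aggregate one filter's spot areas into a summary row.

    Sub-threshold (< 1 μL) spots are excluded from every count and total;
    volumes are summed, then rounded to one decimal.  With no primary
    voids the primary mean is reported as 0.
    """
    measured = measure_spots(spots, curve)
    primary = [m.volume_ul for m in measured if m.bin == "primary"]
    micro = [m.volume_ul for m in measured if m.bin == "micro"]
    n_sub = sum(1 for m in measured if m.bin == "sub_threshold")
    if n_sub:
        logger.info("%s: excluded %d sub-threshold (<%g μL) spots",
                    label, n_sub, MICRO_MIN_UL)
    total = round(sum(primary) + sum(micro), 1)
    mean_primary = round(float(np.mean(primary)), 1) if primary else 0.0
    return FilterSummary(
        image_label=label,
        total_volume_ul=total,
        total_spot_count=len(primary) + len(micro),
        primary_count=len(primary),
        primary_mean_volume_ul=mean_primary,
        micro_count=len(micro),
    )


def segregate_background(image: GrayImage) -> tuple[np.ndarray, int]:
    """Separate filter-paper pixels from the dark surround.

    Circular filters photographed on a dark surface are strongly bimodal:
    Otsu thresholding followed by keeping the largest bright connected
    region (holes filled) isolates the paper disk.  Full-frame rectangular
    filters lack a dark surround, so the whole frame is paper; the two
    regimes are told apart by the contrast between the Otsu classes and
    the dark-class coverage.

    Returns ``(paper_mask, paper_area_px)``.
    """
    px = image.pixels
    full = np.ones(px.shape, dtype=bool)
    if px.max() == px.min():
        return full, int(full.sum())
    t = threshold_otsu(px)
    dark = px <= t
    dark_frac = float(dark.mean())
    mean_dark = float(px[dark].mean()) if dark.any() else 0.0
    mean_bright = float(px[~dark].mean()) if (~dark).any() else 255.0
    surround = dark_frac >= 0.10 and mean_dark < 0.45 * mean_bright
    if not surround:
        return full, int(full.sum())
    labels, n = ndi.label(~dark)
    if n == 0:
        return full, int(full.sum())
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    paper = ndi.binary_fill_holes(labels == counts.argmax())
    return paper, int(paper.sum())


def filter_offpaper_spots(spots, paper_mask: np.ndarray):
    """Drop detections whose centroid falls off the paper region.

    Takes and returns a :class:`~voidspot.detectors.SpotSet`; survivors
    are renumbered 1..n.
    """
    from .detectors import SpotInstance, SpotSet

    kept = []
    for inst in spots.instances:
        cx, cy = inst.centroid
        if paper_mask[int(round(cy)), int(round(cx))]:
            kept.append(inst)
    instances = [
        SpotInstance(spot_id=i, rows=inst.rows, cols=inst.cols, score=inst.score)
        for i, inst in enumerate(kept, start=1)
    ]
    return SpotSet(image_label=spots.image_label, instances=instances,
                   provenance=spots.provenance)


def summarize_folder(folder: str | Path, curve: CalibrationCurve) -> tuple[Path, int]:
    """Summarize every ``*_areas.csv`` in a folder into VoidDataSummary.csv.

    Rows are ordered by file name; the summary is (over)written into the
    input folder.  Unreadable CSVs are skipped with a logged warning.
    Returns ``(summary_path, n_errors)``.
    """
    folder = Path(folder)
    rows: list[FilterSummary] = []
    n_errors = 0
    area_files = sorted(p for p in folder.glob("*_areas.csv"))
    if not area_files:
        logger.warning("%s: no *_areas.csv files found", folder)
    for path in area_files:
        try:
            records = read_spot_csv(path)
        except FormatError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            n_errors += 1
            continue
        rows.append(summarize(path.name, records, curve))
    out = folder / SUMMARY_FILENAME
    with open(out, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(",".join(SUMMARY_HEADER) + "\n")
        for row in rows:
            fh.write(",".join(row.as_row()) + "\n")
    return out, n_errors
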