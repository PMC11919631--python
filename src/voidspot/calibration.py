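"""Area-to-volume standard-curve calibration.

A pipetted volume ladder on the target paper gives paired observations of
spot pixel area and deposited volume.  The relationship is linear, so a
single ordinary least squares fit of volume (response, μL) on pixel area
(predictor, px²) calibrates the deployment direction; osmolality does not
enter the model.  An optional through-origin fit suppresses the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CalibrationCurve", "fit_curve", "area_to_volume",
           "save_curve", "load_curve", "read_pairs_csv"]


@dataclass
class CalibrationCurve:
    """Linear pixel-area → microliter map with fit diagnostics."""

    slope: float            # μL per px²
    intercept: float        # μL
    r_squared: float
    n_points: int
    n_clamped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if self.n_points < 2:
            raise ValueError("a curve needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


def fit_curve(points: Sequence[tuple[float, float]],
              through_origin: bool = False) -> CalibrationCurve:
    """OLS fit of volume on area over ``(area_px, volume_ul)`` pairs.

    ``r_squared`` is computed against the fitted line (centered total sum
    of squares), including for through-origin fits.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (area, volume) points")
    areas, volumes = pts[:, 0], pts[:, 1]
    if np.any(volumes <= 0):
        raise ValueError("pipetted volumes must be positive")
    if np.unique(areas).size < 2:
        raise ValueError("degenerate fit: all areas identical")
    if through_origin:
        slope = float(np.dot(areas, volumes) / np.dot(areas, areas))
        intercept = 0.0
        fitted = slope * areas
        ss_res = float(np.sum((volumes - fitted) ** 2))
        ss_tot = float(np.sum((volumes - volumes.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(areas, volumes)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return CalibrationCurve(slope=slope, intercept=intercept,
                            r_squared=max(min(r2, 1.0), 0.0),
                            n_points=int(pts.shape[0]))


def area_to_volume(curve: CalibrationCurve, area_px: float) -> float:
    """Apply the curve; negative extrapolations clamp to 0 μL (counted)."""
    if area_px < 0:
        raise ValueError("area_px must be >= 0")
    volume = curve.slope * area_px + curve.intercept
    if volume < 0:
        curve.n_clamped += 1
        return 0.0
    return float(volume)


def save_curve(curve: CalibrationCurve, path: str | Path) -> None:
    Path(path).write_text(
        f"slope={curve.slope!r}\nintercept={curve.intercept!r}\n"
        f"r_squared={curve.r_squared!r}\nn_points={curve.n_points}\n",
        encoding="utf-8",
    )


def load_curve(path: str | Path) -> CalibrationCurve:
    values: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected key=value")
        key, _, raw = line.partition("=")
        values[key.strip()] = float(raw)
    return CalibrationCurve(slope=values["slope"], intercept=values["intercept"],
                            r_squared=values["r_squared"],
                            n_points=int(values["n_points"]))


def read_pairs_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read a two-column (area, volume) CSV with a header row."""
    import csv

    pairs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader, None)
        for row in reader:
            if len(row) >= 2:
                pairs.append((float(row[0]), float(row[1])))
    return pairs
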