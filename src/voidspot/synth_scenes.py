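"""Synthetic filter-paper scenes with exact ground truth.

Real void spot assay photographs vary enormously between labs: uneven UV
illumination produces steep background gradients, urine spots range from
bright to barely fluorescing to inverse (darker than the paper), and
papers carry non-void artifacts — pencil writing, glue bleed-through from
identification stickers, chewed or torn edges.  This module generates 8-bit
scenes exhibiting all of these regimes with pixel-exact truth masks, so
the detection, calibration and summary stages can be tested end to end
without photographic data.

A scene is background (base intensity plus a planar or radial gradient
plus Gaussian noise) composited with boundary-perturbed elliptical spots.
Each spot's opacity profile is its perturbed-ellipse silhouette blurred by
``edge_blur_sd``; the truth mask is the set of pixels with opacity >= 0.5
*before* noise, so truth is independent of the noise draw.  Truth volume
is ``area_px / px_per_ul``.  Artifacts are recorded in the truth inventory
but never count as spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage.draw import line as _bresenham

from .annotations import AnnotationSet, mask_to_roi, write_fiji_roiset
from .detectors import SpotInstance, SpotSet
from .raster_io import GrayImage, write_image

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "PlacementError",
    "generate_scene",
    "generate_ladder",
    "export_scene",
]

#: Fig. 6-style pipetted volume ladder (μL).
LADDER_VOLUMES_UL = (1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0, 150.0)


class PlacementError(RuntimeError):
    """Raised when spots cannot be placed disjointly; use fewer or smaller spots."""


@dataclass(frozen=True)
class SceneConfig:
    """Knobs for one synthetic filter-paper scene.

    Defaults describe a typical 4-h assay photograph at desk scale: a
    bright paper (base 120/255) with a planar illumination gradient of
    ±40 counts, mild sensor noise, and spots spanning micro-void to
    primary-void sizes at 100 px² per μL.
    """

    width: int = 512
    height: int = 512
    filter_shape: Literal["rectangular", "circular"] = "rectangular"
    base_intensity: float = 120.0
    gradient_amplitude: float = 40.0
    gradient_kind: Literal["planar", "radial"] = "planar"
    noise_sd: float = 3.0
    n_spots: int = 8
    spot_radius_range: tuple[float, float] = (5.0, 40.0)
    contrast_range: tuple[float, float] = (40.0, 80.0)
    axis_ratio_range: tuple[float, float] = (0.75, 1.0)
    edge_blur_sd: float = 1.0
    artifact_flags: tuple[str, ...] = ()
    px_per_ul: float = 100.0
    min_gap_px: int = 6
    overlap_pairs: int = 0
    overlap_iou: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8x8 pixels")
        if self.px_per_ul <= 0:
            raise ValueError("px_per_ul must be positive")
        lo, hi = self.spot_radius_range
        if not (0 < lo <= hi):
            raise ValueError("spot_radius_range must be a non-empty positive range")
        clo, chi = self.contrast_range
        if clo > chi:
            raise ValueError("contrast_range must be non-empty")
        for flag in self.artifact_flags:
            if flag not in ("writing", "glue_blob", "tear"):
                raise ValueError(f"unknown artifact flag {flag!r}")
        if not 0 <= self.base_intensity - self.gradient_amplitude <= 255 or \
           not 0 <= self.base_intensity + self.gradient_amplitude <= 255:
            raise ValueError("base_intensity ± gradient_amplitude must stay in [0, 255]")


@dataclass
class SceneTruth:
    """Exact ground truth for a generated scene."""

    spots: SpotSet
    true_volumes_ul: list[float]
    artifact_masks: list[tuple[str, np.ndarray]]
    spot_axes_px: list[tuple[float, float]]
    config: SceneConfig

    @property
    def seed(self) -> int:
        return self.config.seed


# Low-order Fourier boundary perturbation amplitude (fraction of radius).
_BOUNDARY_AMP = 0.04
_PLACEMENT_RETRIES = 300


def _spot_opacity(rng: np.random.Generator, radius: float, edge_blur_sd: float,
                  boundary_amp: float = _BOUNDARY_AMP,
                  axis_ratio_range: tuple[float, float] = (0.75, 1.0)):
    """Opacity patch for one boundary-perturbed ellipse.

    Returns (patch, half, (a, b)) where ``patch`` is float opacity in
    [0, 1] of side ``2*half+1`` and (a, b) the nominal semi-axes.
    """
    ratio = rng.uniform(*axis_ratio_range)
    a, b = radius, radius * ratio
    theta = rng.uniform(0.0, math.pi)
    amps = boundary_amp * rng.uniform(0.0, 1.0, size=3) / np.array([1.0, 1.5, 2.0])
    phases = rng.uniform(0.0, 2 * math.pi, size=3)

    half = int(math.ceil(a * (1 + boundary_amp) + 3 * edge_blur_sd)) + 2
    coords = np.arange(-half, half + 1, dtype=np.float64)
    dx, dy = np.meshgrid(coords, coords)
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    r_norm = np.hypot(u, v)
    phi = np.arctan2(v, u)
    rho = np.ones_like(phi)
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        rho += amp * np.cos(k * phi + ph)
    shape = (r_norm <= rho).astype(np.float64)
    if edge_blur_sd > 0:
        from skimage.filters import gaussian
        shape = gaussian(shape, sigma=edge_blur_sd, preserve_range=True)
    return shape, half, (a, b)


def _background(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    bg = np.full((h, w), config.base_intensity)
    if config.gradient_amplitude > 0:
        if config.gradient_kind == "planar":
            angle = rng.uniform(0.0, 2 * math.pi)
            proj = (xx - w / 2) * math.cos(angle) + (yy - h / 2) * math.sin(angle)
            span = max(abs(proj).max(), 1.0)
            bg = bg + config.gradient_amplitude * proj / span
        else:
            rr = np.hypot(xx - w / 2, yy - h / 2)
            bg = bg + config.gradient_amplitude * (1 - 2 * rr / max(rr.max(), 1.0))
    else:
        # keep the stream aligned across gradient settings
        rng.uniform(0.0, 2 * math.pi)
    return bg


_DARK_SURROUND = 12.0


def _filter_mask(config: SceneConfig) -> tuple[np.ndarray, float]:
    """(paper-region mask, disk radius or inf for rectangular)."""
    h, w = config.height, config.width
    if config.filter_shape == "rectangular":
        return np.ones((h, w), dtype=bool), math.inf
    radius = 0.5 * min(h, w) - 4
    yy, xx = np.mgrid[0:h, 0:w]
    disk = (xx - w / 2 + 0.5) ** 2 + (yy - h / 2 + 0.5) ** 2 <= radius**2
    return disk, radius


def _place(rng, occupied: np.ndarray, allowed: np.ndarray, patch_mask: np.ndarray,
           half: int, gap: int) -> tuple[int, int] | None:
    """Find a center where patch_mask fits inside `allowed` clear of `occupied`."""
    h, w = occupied.shape
    pr, pc = np.nonzero(patch_mask)
    for _ in range(_PLACEMENT_RETRIES):
        cy = int(rng.integers(half, h - half)) if h > 2 * half else half
        cx = int(rng.integers(half, w - half)) if w > 2 * half else half
        rows = pr + cy - half
        cols = pc + cx - half
        if not allowed[rows, cols].all():
            continue
        r0, r1 = max(rows.min() - gap, 0), min(rows.max() + gap + 1, h)
        c0, c1 = max(cols.min() - gap, 0), min(cols.max() + gap + 1, w)
        if occupied[r0:r1, c0:c1].any():
            # cheap reject box; refine with exact dilated check
            window = occupied[r0:r1, c0:c1]
            if window.any():
                continue
        return cy, cx
    return None


def generate_scene(config: SceneConfig) -> tuple[GrayImage, SceneTruth]:
    """Generate one scene and its exact truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    paper, _ = _filter_mask(config)
    canvas = _background(config, rng)
    if config.filter_shape == "circular":
        canvas = np.where(paper, canvas, _DARK_SURROUND)

    occupied = np.zeros((h, w), dtype=bool)
    instances: list[SpotInstance] = []
    axes: list[tuple[float, float]] = []
    gap = config.min_gap_px

    def composite(cy: int, cx: int, patch: np.ndarray, half: int, contrast: float):
        r0, c0 = cy - half, cx - half
        r1, c1 = r0 + patch.shape[0], c0 + patch.shape[1]
        canvas[r0:r1, c0:c1] += contrast * patch
        mask = patch >= 0.5
        rows, cols = np.nonzero(mask)
        return rows + r0, cols + c0

    lo_r, hi_r = config.spot_radius_range
    for i in range(config.n_spots):
        radius = rng.uniform(lo_r, hi_r)
        contrast = rng.uniform(*config.contrast_range)
        patch, half, ab = _spot_opacity(rng, radius, config.edge_blur_sd,
                                        axis_ratio_range=config.axis_ratio_range)
        truth_patch = patch >= 0.5
        pos = _place(rng, occupied, paper, truth_patch, half, gap)
        if pos is None:
            raise PlacementError(
                f"could not place spot {i + 1}/{config.n_spots} after "
                f"{_PLACEMENT_RETRIES} tries; use fewer or smaller spots"
            )
        rows, cols = composite(pos[0], pos[1], patch, half, contrast)
        occupied[rows, cols] = True
        instances.append(SpotInstance(spot_id=len(instances) + 1, rows=rows,
                                      cols=cols, score=1.0))
        axes.append(ab)

    # Optional overlapping pairs exercising the documented failure mode.
    for _ in range(config.overlap_pairs):
        radius = rng.uniform(lo_r, hi_r)
        contrast = rng.uniform(*config.contrast_range)
        d = _distance_for_iou(radius, config.overlap_iou)
        patch, half, ab = _spot_opacity(rng, radius, config.edge_blur_sd)
        pair_half = half + int(math.ceil(d)) + 2
        probe = np.zeros((2 * pair_half + 1, 2 * pair_half + 1), dtype=bool)
        probe[pair_half - half:pair_half + half + 1,
              pair_half - half:pair_half + half + 1] = patch >= 0.5
        pos = _place(rng, occupied, paper, probe, pair_half, gap + int(d) + half)
        if pos is None:
            raise PlacementError("could not place overlapping pair; enlarge the scene")
        cy, cx = pos
        for k, (oy, ox) in enumerate(((0, 0), (0, int(round(d))))):
            p2, h2, ab2 = _spot_opacity(rng, radius, config.edge_blur_sd)
            rows, cols = composite(cy + oy, cx + ox, p2, h2, contrast)
            occupied[rows, cols] = True
            instances.append(SpotInstance(spot_id=len(instances) + 1, rows=rows,
                                          cols=cols, score=1.0))
            axes.append(ab2)

    artifacts = _add_artifacts(canvas, occupied, paper, config, rng)

    if config.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sd, size=canvas.shape)
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    label = f"scene_{config.seed:06d}"
    spots = SpotSet(image_label=label, instances=instances, provenance="ground_truth")
    volumes = [inst.area_px / config.px_per_ul for inst in instances]
    truth = SceneTruth(spots=spots, true_volumes_ul=volumes,
                       artifact_masks=artifacts, spot_axes_px=axes, config=config)
    return GrayImage(pixels=pixels, label=label), truth


def _distance_for_iou(radius: float, iou: float) -> float:
    """Center distance giving the requested IoU for two equal discs (bisection)."""
    r = radius
    area = math.pi * r * r

    def iou_at(d: float) -> float:
        if d >= 2 * r:
            return 0.0
        inter = 2 * r * r * math.acos(d / (2 * r)) - 0.5 * d * math.sqrt(4 * r * r - d * d)
        return inter / (2 * area - inter)

    lo, hi = 0.0, 2 * r
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if iou_at(mid) > iou:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Artifacts: recorded in truth, never counted as spots
# --------------------------------------------------------------------------

def _add_artifacts(canvas, occupied, paper, config: SceneConfig, rng):
    artifacts: list[tuple[str, np.ndarray]] = []
    h, w = canvas.shape
    for flag in config.artifact_flags:
        mask = np.zeros((h, w), dtype=bool)
        if flag == "writing":
            # a few dark pencil strokes (1-2 px wide polylines)
            for _ in range(int(rng.integers(2, 5))):
                n_pts = int(rng.integers(2, 5))
                ys = rng.integers(5, h - 5, size=n_pts)
                xs = rng.integers(5, w - 5, size=n_pts)
                for (y0, x0), (y1, x1) in zip(zip(ys, xs), zip(ys[1:], xs[1:])):
                    rr, cc = _bresenham(int(y0), int(x0), int(y1), int(x1))
                    mask[rr, cc] = True
            from scipy import ndimage as ndi
            mask = ndi.binary_dilation(mask)
            mask &= paper & ~occupied
            canvas[mask] -= 55.0
        elif flag == "glue_blob":
            # bright bleed-through with a ragged edge and mottled interior
            radius = rng.uniform(10.0, 25.0)
            patch, half, _ = _spot_opacity(rng, radius, edge_blur_sd=0.5,
                                           boundary_amp=0.25)
            pos = _place(rng, occupied, paper, patch >= 0.5, half, config.min_gap_px)
            if pos is None:
                continue
            cy, cx = pos
            r0, c0 = cy - half, cx - half
            mottle = rng.normal(1.0, 0.35, size=patch.shape)
            from skimage.filters import gaussian
            mottle = gaussian(mottle, sigma=1.5, preserve_range=True)
            canvas[r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] += \
                50.0 * patch * np.clip(mottle, 0.0, 2.0)
            sub = np.zeros_like(mask)
            rr, cc = np.nonzero(patch >= 0.5)
            sub[rr + r0, cc + c0] = True
            mask = sub
        elif flag == "tear":
            # dark jagged wedge from a frame edge
            edge = int(rng.integers(0, 4))
            depth = int(rng.uniform(0.08, 0.18) * min(h, w))
            span = int(rng.uniform(0.1, 0.25) * (w if edge < 2 else h))
            pos0 = int(rng.integers(0, (w if edge < 2 else h) - span))
            tri = np.zeros((h, w), dtype=bool)
            if edge < 2:  # top/bottom
                apex_x = pos0 + span // 2
                rows = np.arange(depth)
                for r in rows:
                    frac = 1 - r / depth
                    half_sp = max(int(span * frac / 2), 1)
                    rr = r if edge == 0 else h - 1 - r
                    tri[rr, max(apex_x - half_sp, 0):min(apex_x + half_sp, w)] = True
            else:  # left/right
                apex_y = pos0 + span // 2
                for c in range(depth):
                    frac = 1 - c / depth
                    half_sp = max(int(span * frac / 2), 1)
                    cc = c if edge == 2 else w - 1 - c
                    tri[max(apex_y - half_sp, 0):min(apex_y + half_sp, h), cc] = True
            mask = tri & ~occupied
            canvas[mask] = _DARK_SURROUND + 8.0
        if mask.any():
            occupied |= mask
            artifacts.append((flag, mask))
    return artifacts


# --------------------------------------------------------------------------
# Pipetted volume ladder (standard-curve scenes)
# --------------------------------------------------------------------------

def _disc_pixel_count(radius: float) -> int:
    half = int(math.ceil(radius)) + 1
    coords = np.arange(-half, half + 1) + 0.0
    dx, dy = np.meshgrid(coords, coords)
    return int(np.count_nonzero(dx * dx + dy * dy <= radius * radius))


def _radius_for_area(target: int) -> float:
    """Disc radius whose rasterized pixel count best matches ``target``."""
    lo = max(math.sqrt(target / math.pi) - 2.0, 0.5)
    hi = math.sqrt(target / math.pi) + 2.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _disc_pixel_count(mid) < target:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi, 0.5 * (lo + hi)),
               key=lambda r: abs(_disc_pixel_count(r) - target))
    return best


def generate_ladder(volumes_ul: Sequence[float] = LADDER_VOLUMES_UL,
                    px_per_ul: float = 100.0, duplicates: int = 2,
                    seed: int = 0, base_intensity: float = 120.0,
                    contrast: float = 60.0, noise_sd: float = 2.0,
                    ) -> tuple[GrayImage, SceneTruth]:
    """Pipetted volume ladder: a grid of discs, one row per duplicate.

    Each disc's truth area is the rasterized pixel count closest to
    ``round(volume * px_per_ul)`` (within 2 %); truth volume is the
    pipetted volume, so ladder truth pairs are calibration input.
    """
    if any(v <= 0 for v in volumes_ul):
        raise ValueError("pipetted volumes must be positive")
    if duplicates < 1:
        raise ValueError("duplicates must be >= 1")
    rng = np.random.default_rng(seed)
    radii = [_radius_for_area(int(round(v * px_per_ul))) for v in volumes_ul]
    margin = 8
    cell = int(2 * max(radii)) + 2 * margin
    wid = cell * len(volumes_ul)
    hei = cell * duplicates
    canvas = np.full((hei, wid), base_intensity, dtype=np.float64)

    instances: list[SpotInstance] = []
    volumes: list[float] = []
    axes: list[tuple[float, float]] = []
    for row in range(duplicates):
        for col, (vol, radius) in enumerate(zip(volumes_ul, radii)):
            cy = row * cell + cell // 2
            cx = col * cell + cell // 2
            half = int(math.ceil(radius)) + 1
            coords = np.arange(-half, half + 1) + 0.0
            dx, dy = np.meshgrid(coords, coords)
            disc = dx * dx + dy * dy <= radius * radius
            canvas[cy - half:cy + half + 1, cx - half:cx + half + 1] += contrast * disc
            rows_, cols_ = np.nonzero(disc)
            instances.append(SpotInstance(spot_id=len(instances) + 1,
                                          rows=rows_ + cy - half,
                                          cols=cols_ + cx - half, score=1.0))
            volumes.append(float(vol))
            axes.append((radius, radius))

    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, size=canvas.shape)
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    label = f"ladder_{seed:06d}"
    config = SceneConfig(width=wid, height=hei, base_intensity=base_intensity,
                         gradient_amplitude=0.0, noise_sd=noise_sd,
                         n_spots=len(instances), px_per_ul=px_per_ul, seed=seed,
                         spot_radius_range=(min(radii), max(radii)),
                         contrast_range=(contrast, contrast), edge_blur_sd=0.0)
    spots = SpotSet(image_label=label, instances=instances, provenance="ground_truth")
    truth = SceneTruth(spots=spots, true_volumes_ul=volumes,
                       artifact_masks=[], spot_axes_px=axes, config=config)
    return GrayImage(pixels=pixels, label=label), truth


# --------------------------------------------------------------------------
# Export: a generated scene is a valid pipeline input and training annotation
# --------------------------------------------------------------------------

def export_scene(image: GrayImage, truth: SceneTruth, outdir: str | Path) -> dict:
    """Write <label>.tif, <label>_RoiSet.zip and <label>_truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tif = outdir / f"{image.label}.tif"
    write_image(image, tif)
    shape = image.pixels.shape
    rois = [mask_to_roi(inst.to_mask(shape), name=f"{inst.spot_id:04d}")
            for inst in truth.spots.instances]
    roiset = outdir / f"{image.label}_RoiSet.zip"
    write_fiji_roiset(AnnotationSet(image_label=image.label, rois=rois), roiset)
    truth_csv = outdir / f"{image.label}_truth.csv"
    with open(truth_csv, "w", encoding="utf-8") as fh:
        fh.write("id,area_px,volume_ul\n")
        for inst, vol in zip(truth.spots.instances, truth.true_volumes_ul):
            fh.write(f"{inst.spot_id},{inst.area_px},{vol:.6g}\n")
    return {"image": tif, "roiset": roiset, "truth": truth_csv}
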