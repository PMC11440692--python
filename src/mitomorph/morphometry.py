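"""Per-mitochondrion shape indices and per-cell aggregates.

Five indices per the standard TEM readout:

1. density        — mitochondria per unit cell area (1/µm²), per cell;
2. area           — area of a single mitochondrion (µm²);
3. perimeter      — perimeter of a single mitochondrion (µm);
4. area ratio     — summed mitochondrial area / cell area, per cell;
5. circularity    — 4π·area / perimeter² (ImageJ definition).

Plus cristae occupancy: cristae pixel count / mitochondrion pixel count.

Perimeter convention for raster masks: a marching-squares contour at the
0.5 level, lightly smoothed with a closed moving average (window 5) before
measuring its length.  Raw marching squares on binary data systematically
overestimates smooth-boundary length (~6% for discs, depressing circularity
below 0.9); the smoothed trace recovers analytic perimeters to <1% on discs
of radius ≥ 20 px.  Polygon-backed instances are measured analytically from
their vertices.  Holes in raster masks contribute neither area nor
perimeter (outer contour only); they are treated as annotation noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import measure

from .model import AnnotatedImage, CellRegion, MitoInstance, PixelScale, Role
from .model import polygon_rings_to_geometry

_SMOOTH_WINDOW = 5


@dataclass
class MorphometryRecord:
    """The per-instance indices for one mitochondrion within its cell."""

    image_id: str
    cell_id: Optional[int]
    instance_id: int
    area_um2: float
    perimeter_um: float
    circularity: float
    cristae_occupancy: Optional[float] = None
    grade: Optional[int] = None
    omm_intact: Optional[bool] = None
    mrc_type: Optional[int] = None


@dataclass
class CellSummary:
    """Per-cell aggregates: mitochondrion count, density, area ratio."""

    image_id: str
    cell_id: int
    cell_area_um2: float
    mito_count: int
    density_per_um2: float
    area_ratio: float
    grade: Optional[int] = None


def _smooth_closed(points: np.ndarray, window: int) -> np.ndarray:
    if len(points) <= window:
        return points
    acc = np.zeros_like(points)
    half = window // 2
    for shift in range(-half, half + 1):
        acc += np.roll(points, shift, axis=0)
    return acc / window


def _polyline_length(points: np.ndarray) -> float:
    d = np.diff(points, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def mask_perimeter_px(mask: np.ndarray) -> float:
    """Smoothed marching-squares contour length of the outer boundary, px."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    outer = max(contours, key=lambda c: _polyline_length(c))
    ring = outer[:-1]  # closed: last point repeats the first
    ring = _smooth_closed(ring, _SMOOTH_WINDOW)
    closed = np.vstack([ring, ring[:1]])
    return _polyline_length(closed)


def measure_instance(
    inst: MitoInstance,
    scale: PixelScale,
    frame: Optional[tuple[int, int]] = None,
) -> tuple[float, float, float]:
    """Return ``(area_um2, perimeter_um, circularity)`` for one instance.

    Polygon-backed instances are measured analytically; raster-only
    instances use pixel-count area and the smoothed contour perimeter.
    Single-pixel instances are degenerate under any perimeter convention
    and are measured with a warning.
    """
    s = scale.microns_per_pixel
    if inst.polygon is not None:
        geom = polygon_rings_to_geometry(inst.polygon)
        area = geom.area * s * s
        perim = geom.length * s
    else:
        mask = inst.mask
        if mask is None or not mask.any():
            raise ValueError(f"instance {inst.instance_id}: empty mask")
        n = int(mask.sum())
        if n == 1:
            warnings.warn(
                f"instance {inst.instance_id}: single-pixel mask; perimeter "
                "convention is degenerate at this size"
            )
        area = n * s * s
        perim = mask_perimeter_px(mask) * s
    if area <= 0 or perim <= 0:
        raise ValueError(
            f"instance {inst.instance_id}: non-positive area or perimeter"
        )
    circularity = 4.0 * np.pi * area / (perim * perim)
    return area, perim, circularity


def cristae_occupancy(inst: MitoInstance) -> Optional[float]:
    """Cristae area / mitochondrion area, by pixel counts (scale cancels).

    Returns None when no cristae mask is present (distinct from 0.0).
    """
    if inst.cristae_mask is None:
        return None
    if inst.mask is None:
        raise ValueError(
            f"instance {inst.instance_id}: cristae occupancy needs a raster mask"
        )
    if np.any(inst.cristae_mask & ~inst.mask):
        raise ValueError(
            f"instance {inst.instance_id}: cristae pixels outside the mask"
        )
    return float(inst.cristae_mask.sum()) / float(inst.mask.sum())


def assign_instances_to_cells(
    image: AnnotatedImage,
) -> dict[int, Optional[int]]:
    """Map instance_id -> cell_id by majority pixel overlap.

    Instances straddling a boundary go to the cell holding most of their
    pixels; instances overlapping no cell map to None.
    """
    cell_masks = {
        c.cell_id: c.get_mask(image.height_px, image.width_px)
        for c in image.cells
    }
    out: dict[int, Optional[int]] = {}
    for inst in image.instances:
        m = inst.get_mask(image.height_px, image.width_px)
        best_id, best_overlap = None, 0
        for cid, cmask in cell_masks.items():
            overlap = int(np.count_nonzero(m & cmask))
            if overlap > best_overlap:
                best_id, best_overlap = cid, overlap
        out[inst.instance_id] = best_id
    return out


def summarize_cell(
    cell: CellRegion,
    instances: list[MitoInstance],
    scale: PixelScale,
    image_id: str = "",
    grade: Optional[int] = None,
    frame: Optional[tuple[int, int]] = None,
) -> CellSummary:
    """Density (count / cell area) and area ratio (Σ mito area / cell area)."""
    s = scale.microns_per_pixel
    if cell.mask is None:
        if frame is None:
            raise ValueError("frame required to rasterize a polygon cell")
        cell.get_mask(*frame)
    cell_area = cell.area_px * s * s
    if cell_area <= 0:
        raise ValueError(f"cell {cell.cell_id}: zero area")
    # pixel-count areas on both sides of the ratio keep area_ratio <= 1
    # exact for non-overlapping raster instances inside the cell
    total_mito_area = 0.0
    for inst in instances:
        if inst.mask is not None:
            total_mito_area += inst.area_px * s * s
        else:
            total_mito_area += polygon_rings_to_geometry(inst.polygon).area * s * s
    n = len(instances)
    return CellSummary(
        image_id=image_id,
        cell_id=cell.cell_id,
        cell_area_um2=cell_area,
        mito_count=n,
        density_per_um2=n / cell_area,
        area_ratio=total_mito_area / cell_area,
        grade=grade,
    )


def measure_dataset(
    images: list[AnnotatedImage],
) -> tuple[list[MorphometryRecord], list[CellSummary]]:
    """Measure every instance and cell of a ground-truth image set.

    Returns one MorphometryRecord per instance and one CellSummary per
    cell, sorted by (image_id, cell_id/instance_id) so the output does not
    depend on input ordering.
    """
    records: list[MorphometryRecord] = []
    summaries: list[CellSummary] = []
    for image in images:
        if image.scale is None:
            raise ValueError(f"image {image.image_id}: missing pixel scale")
        cell_of = assign_instances_to_cells(image)
        for inst in image.instances:
            area, perim, circ = measure_instance(inst, image.scale)
            records.append(
                MorphometryRecord(
                    image_id=image.image_id,
                    cell_id=cell_of.get(inst.instance_id),
                    instance_id=inst.instance_id,
                    area_um2=area,
                    perimeter_um=perim,
                    circularity=circ,
                    cristae_occupancy=cristae_occupancy(inst)
                    if inst.cristae_mask is not None
                    else None,
                    grade=image.grade,
                    omm_intact=inst.omm_intact,
                    mrc_type=inst.mrc_type,
                )
            )
        by_cell: dict[int, list[MitoInstance]] = {
            c.cell_id: [] for c in image.cells
        }
        for inst in image.instances:
            cid = cell_of.get(inst.instance_id)
            if cid is not None:
                by_cell[cid].append(inst)
        for cell in image.cells:
            summaries.append(
                summarize_cell(
                    cell,
                    by_cell[cell.cell_id],
                    image.scale,
                    image_id=image.image_id,
                    grade=image.grade,
                    frame=(image.height_px, image.width_px),
                )
            )
    records.sort(key=lambda r: (r.image_id, r.instance_id))
    summaries.sort(key=lambda c: (c.image_id, c.cell_id))
    return records, summaries


def measurements_by_id(
    records: list[MorphometryRecord],
) -> dict[tuple[str, int], MorphometryRecord]:
    return {(r.image_id, r.instance_id): r for r in records}
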