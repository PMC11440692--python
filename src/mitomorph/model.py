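"""Core data model: pixel scale, instances, cells, annotated images.

Coordinate convention: pixel coordinates, 0-based, origin at the top-left
corner, y pointing down.  Polygons are rings of ``(x, y)`` vertices; a pixel
``(row, col)`` belongs to a polygon iff its center ``(col + 0.5, row + 0.5)``
lies inside (center sampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union


class Role(str, Enum):
    """Whether an annotated image holds ground truth or model predictions."""

    GROUND_TRUTH = "ground_truth"
    PREDICTION = "prediction"


@dataclass(frozen=True)
class PixelScale:
    """Physical calibration of the raster, in microns per pixel."""

    microns_per_pixel: float

    def __post_init__(self) -> None:
        s = self.microns_per_pixel
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"microns_per_pixel must be finite and > 0, got {s}")


def polygon_rings_to_geometry(rings: Sequence[np.ndarray]):
    """Union of simple polygons, one per ring (COCO multi-part instances)."""
    polys = []
    for ring in rings:
        ring = np.asarray(ring, dtype=float)
        if ring.ndim != 2 or ring.shape[1] != 2 or len(ring) < 3:
            raise ValueError("polygon ring must be an (N>=3, 2) array of (x, y)")
        p = Polygon(ring)
        if not p.is_valid:
            p = p.buffer(0)
        polys.append(p)
    return unary_union(polys)


def rasterize_rings(
    rings: Sequence[np.ndarray], height: int, width: int
) -> np.ndarray:
    """Rasterize polygon ring(s) into a boolean mask by center sampling."""
    geom = polygon_rings_to_geometry(rings)
    mask = np.zeros((height, width), dtype=bool)
    if geom.is_empty:
        return mask
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(int(np.floor(minx - 1)), 0)
    c1 = min(int(np.ceil(maxx + 1)), width)
    r0 = max(int(np.floor(miny - 1)), 0)
    r1 = min(int(np.ceil(maxy + 1)), height)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xx, yy = np.meshgrid(cols + 0.5, rows + 0.5)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel())
    mask[r0:r1, c0:c1] = inside.reshape(len(rows), len(cols))
    return mask


@dataclass
class MitoInstance:
    """One mitochondrion: a raster mask and/or polygon ring(s), plus
    optional prediction score, cristae mask, OMM flag, and human type label.
    """

    instance_id: int
    mask: Optional[np.ndarray] = None
    polygon: Optional[list[np.ndarray]] = None  # list of (N,2) (x,y) rings
    score: Optional[float] = None
    cristae_mask: Optional[np.ndarray] = None
    omm_intact: Optional[bool] = None
    mrc_type: Optional[int] = None  # human-assigned 1/2/3, overrides proxy

    def __post_init__(self) -> None:
        if self.mask is None and self.polygon is None:
            raise ValueError(
                f"instance {self.instance_id}: needs a mask or a polygon"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValueError(f"instance {self.instance_id}: empty mask")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(
                f"instance {self.instance_id}: score {self.score} outside [0, 1]"
            )
        if self.cristae_mask is not None:
            self.cristae_mask = np.asarray(self.cristae_mask, dtype=bool)
            if self.mask is not None and np.any(self.cristae_mask & ~self.mask):
                raise ValueError(
                    f"instance {self.instance_id}: cristae mask escapes the "
                    "mitochondrion mask"
                )

    def get_mask(self, height: int, width: int) -> np.ndarray:
        """Boolean raster of this instance; rasterized from the polygon on
        first use when no mask was supplied."""
        if self.mask is not None:
            return self.mask
        self.mask = rasterize_rings(self.polygon, height, width)
        if not self.mask.any():
            raise ValueError(
                f"instance {self.instance_id}: polygon rasterizes to an "
                "empty mask"
            )
        return self.mask

    @property
    def area_px(self) -> int:
        if self.mask is None:
            raise ValueError("mask not realized; call get_mask first")
        return int(self.mask.sum())


@dataclass
class CellRegion:
    """A cell with an intact membrane; the aggregation unit for density."""

    cell_id: int
    mask: Optional[np.ndarray] = None
    polygon: Optional[list[np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.mask is None and self.polygon is None:
            raise ValueError(f"cell {self.cell_id}: needs a mask or a polygon")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValueError(f"cell {self.cell_id}: empty region")

    def get_mask(self, height: int, width: int) -> np.ndarray:
        if self.mask is None:
            self.mask = rasterize_rings(self.polygon, height, width)
            if not self.mask.any():
                raise ValueError(f"cell {self.cell_id}: empty region")
        return self.mask

    @property
    def area_px(self) -> int:
        if self.mask is None:
            raise ValueError("mask not realized; call get_mask first")
        return int(self.mask.sum())


@dataclass
class AnnotatedImage:
    """One TEM field: cells, mitochondrion instances, scale and role."""

    image_id: str
    width_px: int
    height_px: int
    scale: PixelScale
    role: Role = Role.GROUND_TRUTH
    cells: list[CellRegion] = field(default_factory=list)
    instances: list[MitoInstance] = field(default_factory=list)
    grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.grade is not None and self.grade not in (1, 2, 3, 4):
            raise ValueError(f"grade must be 1-4, got {self.grade}")
        self.role = Role(self.role)
        ids = [inst.instance_id for inst in self.instances]
        if len(ids) != len(set(ids)):
            raise ValueError(f"image {self.image_id}: duplicate instance ids")

    def instance_masks(self) -> dict[int, np.ndarray]:
        return {
            inst.instance_id: inst.get_mask(self.height_px, self.width_px)
            for inst in self.instances
        }

    def validate_bounds(self) -> None:
        for inst in self.instances:
            m = inst.get_mask(self.height_px, self.width_px)
            if m.shape != (self.height_px, self.width_px):
                raise ValueError(
                    f"image {self.image_id}, instance {inst.instance_id}: "
                    f"mask shape {m.shape} does not match frame "
                    f"({self.height_px}, {self.width_px})"
                )


def warn_once(message: str) -> None:
    warnings.warn(message, stacklevel=3)
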