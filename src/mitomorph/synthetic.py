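"""Synthetic annotated-image generator.

Ground truth: cells containing non-overlapping mitochondrion blobs
(ellipses with radial Fourier noise) whose area, circularity, count,
cristae occupancy and membrane-integrity distributions follow per-grade
profiles.  The default profiles encode only the qualitative high-grade vs
low-grade direction (smaller area, higher density, rounder shape, more
Type-1); the magnitudes are invented and are not estimates of any
clinical distribution.

Predictions: perturbed copies of the ground truth with controllable
instance drop rate, spurious-blob rate, target IoU (via calibrated
translation), signed perimeter/area biases (via calibrated radial
ripple / circle-blending), and a score distribution.

All randomness flows from explicit seeds; per-image generators are derived
deterministically, so outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml

from .model import (
    AnnotatedImage,
    CellRegion,
    MitoInstance,
    PixelScale,
    Role,
    polygon_rings_to_geometry,
    rasterize_rings,
)

_N_VERTICES = 72


class PackingError(RuntimeError):
    """Requested instance count cannot be packed without overlap."""


@dataclass(frozen=True)
class GradeProfile:
    """Distribution parameters for one WHO grade (invented magnitudes)."""

    grade: int
    mito_count_mean: float = 10.0
    mito_count_dispersion: float = 1.0  # variance/mean; 1 -> Poisson
    area_um2_median: float = 0.30
    area_um2_sigma: float = 0.35  # lognormal sigma
    circularity_alpha: float = 6.0
    circularity_beta: float = 4.0
    cristae_alpha: float = 4.0
    cristae_beta: float = 6.0
    p_omm_intact: float = 0.8
    type_mixture: tuple[float, float, float] = (0.4, 0.35, 0.25)

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4):
            raise ValueError(f"grade must be 1-4, got {self.grade}")
        if not 0.0 <= self.p_omm_intact <= 1.0:
            raise ValueError("p_omm_intact outside [0, 1]")
        if abs(sum(self.type_mixture) - 1.0) > 1e-9:
            raise ValueError("type_mixture must sum to 1")
        for name in ("mito_count_mean", "area_um2_median", "area_um2_sigma",
                     "circularity_alpha", "circularity_beta",
                     "cristae_alpha", "cristae_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


#: direction-only defaults: higher grade -> smaller, denser, rounder, more
#: intact cristae and a larger Type-1 fraction
DEFAULT_PROFILES: dict[int, GradeProfile] = {
    1: GradeProfile(1, 8, 1.0, 0.40, 0.35, 5.0, 4.5, 3.5, 6.5, 0.72,
                    (0.30, 0.40, 0.30)),
    2: GradeProfile(2, 9, 1.0, 0.36, 0.35, 5.5, 4.0, 3.8, 6.0, 0.76,
                    (0.35, 0.38, 0.27)),
    3: GradeProfile(3, 12, 1.0, 0.26, 0.35, 8.0, 3.5, 5.0, 5.0, 0.84,
                    (0.52, 0.28, 0.20)),
    4: GradeProfile(4, 14, 1.0, 0.22, 0.35, 10.0, 3.0, 5.5, 4.5, 0.88,
                    (0.60, 0.25, 0.15)),
}


@dataclass(frozen=True)
class PerturbationConfig:
    """How to degrade ground truth into a synthetic prediction set."""

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    jitter_iou_target: float = 1.0
    perimeter_bias: float = 0.0
    area_bias: float = 0.0
    score_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_rate <= 1.0:
            raise ValueError("drop_rate outside [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")
        if not 0.0 < self.jitter_iou_target <= 1.0:
            raise ValueError("jitter_iou_target outside (0, 1]")
        if self.area_bias <= -1.0:
            raise ValueError("area_bias must be > -1")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for a reproducible synthetic dataset."""

    n_images: int = 4
    cells_per_image: int = 1
    image_size_px: int = 384
    scale: PixelScale = field(default_factory=lambda: PixelScale(0.02))
    profiles: dict[int, GradeProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.cells_per_image < 1:
            raise ValueError("cells_per_image must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticDatasetSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        profiles = {}
        for key, pdoc in (doc.get("profiles") or {}).items():
            grade = int(key)
            base = DEFAULT_PROFILES[grade]
            if "type_mixture" in pdoc:
                pdoc["type_mixture"] = tuple(pdoc["type_mixture"])
            profiles[grade] = replace(base, **pdoc)
        return cls(
            n_images=doc.get("n_images", 4),
            cells_per_image=doc.get("cells_per_image", 1),
            image_size_px=doc.get("image_size_px", 384),
            scale=PixelScale(doc.get("scale_um_per_px", 0.02)),
            profiles=profiles or dict(DEFAULT_PROFILES),
            seed=doc.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# shape machinery

def _ring_metrics(ring: np.ndarray) -> tuple[float, float]:
    x, y = ring[:, 0], ring[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * yn - xn * y))
    perim = float(np.sum(np.hypot(xn - x, yn - y)))
    return area, perim


def _ring_circularity(ring: np.ndarray) -> float:
    area, perim = _ring_metrics(ring)
    return 4.0 * math.pi * area / (perim * perim)


def _noisy_ellipse(rng: np.random.Generator, circ_target: float) -> np.ndarray:
    """Unit-area blob with approximately the requested circularity."""
    t = np.linspace(0.0, 2.0 * math.pi, _N_VERTICES, endpoint=False)
    # radial Fourier noise, small when a round shape is requested
    amp = 0.05 * min(1.0, 2.0 * (1.0 - circ_target))
    noise = np.ones_like(t)
    for m in (2, 3, 4, 5):
        noise += amp * rng.uniform(0.2, 1.0) * np.cos(
            m * t + rng.uniform(0, 2 * math.pi)
        )

    def ring_for(q: float) -> np.ndarray:
        x = np.cos(t) * noise
        y = q * np.sin(t) * noise
        return np.column_stack([x, y])

    lo, hi = 0.05, 1.0
    if _ring_circularity(ring_for(1.0)) < circ_target:
        ring = ring_for(1.0)  # noise already caps circularity; best effort
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if _ring_circularity(ring_for(mid)) < circ_target:
                lo = mid
            else:
                hi = mid
        ring = ring_for(0.5 * (lo + hi))
    area, _ = _ring_metrics(ring)
    ring /= math.sqrt(area)
    theta = rng.uniform(0, 2 * math.pi)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    return ring @ rot.T


def _cell_ring(rng: np.random.Generator, center: np.ndarray,
               radius: float) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * math.pi, 96, endpoint=False)
    r = radius * (1.0 + 0.06 * np.cos(3 * t + rng.uniform(0, 2 * math.pi))
                  + 0.04 * np.cos(5 * t + rng.uniform(0, 2 * math.pi)))
    return np.column_stack([center[0] + r * np.cos(t),
                            center[1] + r * np.sin(t)])


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 1.0 + 1e-9:
        return int(rng.poisson(mean))
    p = 1.0 / dispersion
    r = mean * p / (1.0 - p)
    return int(rng.negative_binomial(r, p))


def _stripe_cristae(mask: np.ndarray, fraction: float,
                    period: int = 6, width: int = 3) -> np.ndarray:
    """Interior stripe pattern covering round(fraction * |mask|) pixels.

    Only the covered fraction carries meaning downstream; stripe geometry
    is cosmetic.
    """
    n = int(mask.sum())
    target = int(round(fraction * n))
    stripe = mask & (np.arange(mask.shape[0])[:, None] % period < width)
    flat_idx = np.flatnonzero(mask.ravel())
    stripe_flat = np.flatnonzero(stripe.ravel())
    chosen = list(stripe_flat[:target])
    if len(chosen) < target:
        in_stripe = set(stripe_flat.tolist())
        extra = [i for i in flat_idx.tolist() if i not in in_stripe]
        chosen.extend(extra[: target - len(chosen)])
    out = np.zeros(mask.size, dtype=bool)
    out[chosen] = True
    return out.reshape(mask.shape)


# ---------------------------------------------------------------------------
# ground truth

def generate_ground_truth(spec: SyntheticDatasetSpec) -> list[AnnotatedImage]:
    """Generate non-overlapping, cell-contained mitochondrion instances.

    Images cycle through the profile grades in sorted order.  Raises
    :class:`PackingError` naming the image when a drawn count cannot be
    placed without overlap within the retry budget.
    """
    grades = sorted(spec.profiles)
    size = spec.image_size_px
    s = spec.scale.microns_per_pixel
    images: list[AnnotatedImage] = []
    for idx in range(spec.n_images):
        rng = np.random.default_rng([spec.seed, idx])
        grade = grades[idx % len(grades)]
        profile = spec.profiles[grade]
        image = AnnotatedImage(
            image_id=f"synthetic_{idx:04d}",
            width_px=size,
            height_px=size,
            scale=spec.scale,
            role=Role.GROUND_TRUTH,
            grade=grade,
        )
        # cells on a jittered grid so they never collide
        k = spec.cells_per_image
        ncols = int(math.ceil(math.sqrt(k)))
        nrows = int(math.ceil(k / ncols))
        gw, gh = size / ncols, size / nrows
        cell_geoms = []
        for ci in range(k):
            gx, gy = ci % ncols, ci // ncols
            center = np.array([
                (gx + 0.5) * gw + rng.uniform(-0.03, 0.03) * gw,
                (gy + 0.5) * gh + rng.uniform(-0.03, 0.03) * gh,
            ])
            radius = 0.40 * min(gw, gh)
            ring = _cell_ring(rng, center, radius)
            image.cells.append(CellRegion(cell_id=ci + 1, polygon=[ring]))
            cell_geoms.append(polygon_rings_to_geometry([ring]))

        inst_id = 1
        for ci, cell_geom in enumerate(cell_geoms):
            count = _draw_count(
                rng, profile.mito_count_mean, profile.mito_count_dispersion
            )
            placed_geoms = []
            minx, miny, maxx, maxy = cell_geom.bounds
            for _ in range(count):
                area_um2 = profile.area_um2_median * rng.lognormal(
                    0.0, profile.area_um2_sigma
                )
                area_px = max(area_um2 / (s * s), 30.0)
                circ = float(np.clip(
                    rng.beta(profile.circularity_alpha,
                             profile.circularity_beta),
                    0.30, 0.985,
                ))
                unit = _noisy_ellipse(rng, circ) * math.sqrt(area_px)
                ok = False
                for _attempt in range(400):
                    center = np.array([rng.uniform(minx, maxx),
                                       rng.uniform(miny, maxy)])
                    ring = unit + center
                    geom = polygon_rings_to_geometry([ring])
                    if not cell_geom.contains(geom):
                        continue
                    # 1.5 px clearance guarantees disjoint rasterization
                    if any(geom.distance(g) < 1.5 for g in placed_geoms):
                        continue
                    ok = True
                    break
                if not ok:
                    raise PackingError(
                        f"image {image.image_id}: cannot place instance "
                        f"{inst_id} ({count} requested in cell {ci + 1})"
                    )
                placed_geoms.append(geom)
                mask = rasterize_rings([ring], size, size)
                occupancy = float(rng.beta(profile.cristae_alpha,
                                           profile.cristae_beta))
                inst = MitoInstance(
                    instance_id=inst_id,
                    mask=mask,
                    polygon=[ring],
                    cristae_mask=_stripe_cristae(mask, occupancy),
                    omm_intact=bool(rng.random() < profile.p_omm_intact),
                    mrc_type=int(rng.choice(
                        [1, 2, 3], p=list(profile.type_mixture)
                    )),
                )
                image.instances.append(inst)
                inst_id += 1
        images.append(image)
    return images


# ---------------------------------------------------------------------------
# predictions

def _to_polar(ring: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centroid = ring.mean(axis=0)
    d = ring - centroid
    return centroid, np.hypot(d[:, 0], d[:, 1]), np.arctan2(d[:, 1], d[:, 0])


def _rescale_area(ring: np.ndarray, target_area: float) -> np.ndarray:
    area, _ = _ring_metrics(ring)
    c = ring.mean(axis=0)
    return (ring - c) * math.sqrt(target_area / area) + c


def _adjust_perimeter(ring: np.ndarray, factor: float) -> np.ndarray:
    """Rescale the ring's perimeter by ``factor`` at constant area.

    factor > 1: calibrated radial ripple; factor < 1: calibrated blend
    toward the equal-area circle (the perimeter minimizer).  Works for
    star-shaped rings (all generated blobs are star-shaped about their
    centroid).  Clamped best-effort at the parameterization's range limit.
    """
    if abs(factor - 1.0) < 1e-9:
        return ring
    area0, perim0 = _ring_metrics(ring)
    target = factor * perim0
    centroid, r, theta = _to_polar(ring)

    if factor > 1.0:
        k = 9  # ripple frequency

        def make(eps: float) -> np.ndarray:
            rr = r * (1.0 + eps * np.cos(k * theta))
            cand = np.column_stack([
                centroid[0] + rr * np.cos(theta),
                centroid[1] + rr * np.sin(theta),
            ])
            return _rescale_area(cand, area0)

        lo, hi = 0.0, 0.8
    else:
        rbar = math.sqrt(area0 / math.pi)

        def make(t: float) -> np.ndarray:
            rr = (1.0 - t) * r + t * rbar
            cand = np.column_stack([
                centroid[0] + rr * np.cos(theta),
                centroid[1] + rr * np.sin(theta),
            ])
            return _rescale_area(cand, area0)

        lo, hi = 0.0, 1.0

    def length(p: float) -> float:
        return _ring_metrics(make(p))[1]

    increasing = factor > 1.0
    reach = length(hi)
    if (increasing and reach < target) or (not increasing and reach > target):
        return make(hi)  # best effort at range limit
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        if (length(mid) < target) == increasing:
            lo = mid
        else:
            hi = mid
    return make(0.5 * (lo + hi))


def _local_iou(ring_a: np.ndarray, ring_b: np.ndarray) -> float:
    allpts = np.vstack([ring_a, ring_b])
    off = np.floor(allpts.min(axis=0)) - 2
    span = np.ceil(allpts.max(axis=0)) - off + 4
    h, w = int(span[1]), int(span[0])
    ma = rasterize_rings([ring_a - off], h, w)
    mb = rasterize_rings([ring_b - off], h, w)
    union = np.count_nonzero(ma | mb)
    if union == 0:
        return 0.0
    return np.count_nonzero(ma & mb) / union


def _jitter_to_iou(ring: np.ndarray, reference: np.ndarray,
                   iou_target: float, rng: np.random.Generator) -> np.ndarray:
    """Translate ``ring`` so its raster IoU against ``reference``
    approximates the target (bisection on shift distance)."""
    phi = rng.uniform(0, 2 * math.pi)
    direction = np.array([math.cos(phi), math.sin(phi)])
    area, _ = _ring_metrics(reference)
    d_max = 2.5 * math.sqrt(area)  # IoU ~ 0 out here
    lo, hi = 0.0, d_max
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if _local_iou(ring + mid * direction, reference) > iou_target:
            lo = mid
        else:
            hi = mid
    return ring + 0.5 * (lo + hi) * direction


def generate_predictions(
    gt: list[AnnotatedImage], cfg: PerturbationConfig
) -> list[AnnotatedImage]:
    """Perturbed copies of ground-truth images posing as model output.

    Retained instances keep their ground-truth instance id; spurious blobs
    get fresh ids and are placed with zero pixel overlap against every
    ground-truth instance (hence IoU < 0.5 by construction).
    """
    neutral = (
        cfg.jitter_iou_target >= 0.999
        and cfg.perimeter_bias == 0.0
        and cfg.area_bias == 0.0
    )
    out: list[AnnotatedImage] = []
    for idx, gim in enumerate(gt):
        rng = np.random.default_rng([cfg.seed, 7919, idx])
        pim = AnnotatedImage(
            image_id=gim.image_id,
            width_px=gim.width_px,
            height_px=gim.height_px,
            scale=gim.scale,
            role=Role.PREDICTION,
            grade=gim.grade,
        )
        area_scale = math.sqrt(1.0 + cfg.area_bias)
        for inst in gim.instances:
            if rng.random() < cfg.drop_rate:
                continue
            score = float(rng.uniform(*cfg.score_range))
            if inst.polygon is None:
                raise ValueError(
                    "generate_predictions requires polygon-backed ground truth"
                )
            ring = np.array(inst.polygon[0], dtype=float)
            if not neutral:
                if cfg.area_bias != 0.0:
                    c = ring.mean(axis=0)
                    ring = (ring - c) * area_scale + c
                perim_factor = (1.0 + cfg.perimeter_bias) / area_scale
                ring = _adjust_perimeter(ring, perim_factor)
                if cfg.jitter_iou_target < 0.999:
                    ring = _jitter_to_iou(
                        ring, np.array(inst.polygon[0], dtype=float),
                        cfg.jitter_iou_target, rng,
                    )
            pim.instances.append(
                MitoInstance(
                    instance_id=inst.instance_id,
                    polygon=[ring],
                    score=score,
                )
            )
        n_spurious = int(rng.poisson(cfg.spurious_rate))
        if n_spurious:
            gt_union = np.zeros((gim.height_px, gim.width_px), dtype=bool)
            for inst in gim.instances:
                gt_union |= inst.get_mask(gim.height_px, gim.width_px)
            areas = [inst.area_px for inst in gim.instances] or [400]
            next_id = max(
                (i.instance_id for i in gim.instances), default=0
            ) + 1000
            for j in range(n_spurious):
                area_px = float(np.mean(areas))
                unit = _noisy_ellipse(rng, 0.8) * math.sqrt(area_px)
                for _attempt in range(200):
                    center = rng.uniform(
                        [0.1 * gim.width_px, 0.1 * gim.height_px],
                        [0.9 * gim.width_px, 0.9 * gim.height_px],
                    )
                    ring = unit + center
                    mask = rasterize_rings(
                        [ring], gim.height_px, gim.width_px
                    )
                    if mask.any() and not (mask & gt_union).any():
                        pim.instances.append(
                            MitoInstance(
                                instance_id=next_id + j,
                                polygon=[ring],
                                mask=mask,
                                score=float(rng.uniform(*cfg.score_range)),
                            )
                        )
                        break
        out.append(pim)
    return out


# ---------------------------------------------------------------------------
# hand-built fixture

def _square(x0: float, y0: float, side: float) -> np.ndarray:
    return np.array([
        [x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]
    ], dtype=float)


def reference_fixture(
    scores: Optional[dict[str, float]] = None,
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Tiny 2-image fixture with known outcomes at the 0.5/0.5 thresholds.

    Image 1: two true positives (IoU 1.0 and 2/3), one false positive, one
    false negative; translated square predictions keep perimeter exactly,
    so the image-1 signed perimeter error is exactly 0.  Image 2: a single
    clean true positive.  ``scores`` overrides prediction scores by
    prediction key ("p1".."p3", "p4").
    """
    scores = scores or {}
    scale = PixelScale(0.05)

    def make(image_id, role, squares, grade=None):
        im = AnnotatedImage(
            image_id=image_id, width_px=64, height_px=64,
            scale=scale, role=role, grade=grade,
        )
        im.cells.append(CellRegion(cell_id=1, polygon=[_square(1, 1, 62)]))
        for iid, ring, score in squares:
            im.instances.append(
                MitoInstance(instance_id=iid, polygon=[ring], score=score)
            )
        return im

    gt1 = make("fixture_1", Role.GROUND_TRUTH, [
        (1, _square(5, 5, 10), None),
        (2, _square(5, 30, 10), None),
        (3, _square(30, 5, 10), None),
    ], grade=2)
    pred1 = make("fixture_1", Role.PREDICTION, [
        (1, _square(5, 5, 10), scores.get("p1", 0.9)),    # TP, IoU 1
        (2, _square(7, 30, 10), scores.get("p2", 0.9)),   # TP, IoU 2/3
        (99, _square(45, 45, 10), scores.get("p3", 0.9)), # FP
    ], grade=2)
    gt2 = make("fixture_2", Role.GROUND_TRUTH, [
        (1, _square(20, 20, 10), None),
    ], grade=3)
    pred2 = make("fixture_2", Role.PREDICTION, [
        (1, _square(20, 20, 10), scores.get("p4", 0.8)),  # TP, IoU 1
    ], grade=3)
    return [gt1, gt2], [pred1, pred2]
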