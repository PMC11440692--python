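"""Reading and writing instance annotations.

Supported formats:

* label images — single-channel TIFF/PNG, integer labels, 0 = background;
* a COCO-instance JSON dialect (``images`` / ``annotations`` / ``categories``,
  ``segmentation`` as polygon list or uncompressed RLE, optional ``score``);
* a measurements CSV (one row per mitochondrion).

Label images cannot encode overlap; COCO annotations may overlap and are
preserved as-is (matching copes with overlapping predictions).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .model import AnnotatedImage, CellRegion, MitoInstance, PixelScale, Role

PathLike = Union[str, Path]

MEASUREMENT_COLUMNS = [
    "image_id",
    "cell_id",
    "instance_id",
    "area_um2",
    "perimeter_um",
    "circularity",
    "cristae_occupancy",
    "grade",
]


class AnnotationFormatError(ValueError):
    """Raised when an annotation file violates the expected structure."""


def _read_label_array(path: PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise AnnotationFormatError(
            f"{path}: expected a single-channel label image, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise AnnotationFormatError(
            f"{path}: label image must have an integer dtype, got {arr.dtype}"
        )
    return arr


def load_label_mask(
    path: PathLike,
    scale: PixelScale,
    role: Role = Role.GROUND_TRUTH,
    image_id: Optional[str] = None,
    grade: Optional[int] = None,
) -> AnnotatedImage:
    """Load a label image (0 = background) into one instance per label.

    An all-zero image yields an AnnotatedImage with no instances.
    """
    arr = _read_label_array(path)
    h, w = arr.shape
    image = AnnotatedImage(
        image_id=image_id or Path(path).stem,
        width_px=w,
        height_px=h,
        scale=scale,
        role=role,
        grade=grade,
    )
    for label in np.unique(arr):
        if label == 0:
            continue
        image.instances.append(
            MitoInstance(instance_id=int(label), mask=arr == label)
        )
    return image


def write_label_mask(image: AnnotatedImage, path: PathLike) -> None:
    """Write instances as a uint16 label image (instance_id = label)."""
    path = Path(path)
    arr = np.zeros((image.height_px, image.width_px), dtype=np.uint16)
    for inst in image.instances:
        m = inst.get_mask(image.height_px, image.width_px)
        if np.any(arr[m] != 0):
            raise ValueError(
                f"image {image.image_id}: overlapping instances cannot be "
                "written as a label image"
            )
        if not 0 < inst.instance_id < 2**16:
            raise ValueError(
                f"instance id {inst.instance_id} not representable as uint16"
            )
        arr[m] = inst.instance_id
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def _decode_uncompressed_rle(rle: dict, height: int, width: int) -> np.ndarray:
    # COCO uncompressed RLE: column-major runs, starting with background.
    counts = rle["counts"]
    rh, rw = rle.get("size", (height, width))
    flat = np.zeros(rh * rw, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    if pos != rh * rw:
        raise AnnotationFormatError("RLE run lengths do not cover the frame")
    return flat.reshape((rw, rh)).T  # column-major


def _flat_to_rings(segmentation: list) -> list[np.ndarray]:
    rings = []
    for flat in segmentation:
        pts = np.asarray(flat, dtype=float).reshape(-1, 2)
        if len(pts) < 3:
            raise AnnotationFormatError("degenerate polygon (<3 vertices)")
        rings.append(pts)
    return rings


def load_coco_annotations(
    path: PathLike,
    scale: PixelScale,
    role: Role = Role.GROUND_TRUTH,
) -> list[AnnotatedImage]:
    """Load a COCO-style instance JSON into AnnotatedImages.

    Polygons are kept as vertex rings (rasterized lazily by center
    sampling); uncompressed RLE segmentations are decoded to masks.
    Annotations with a ``score`` field carry it through; annotations in a
    category named ``cell`` become CellRegions rather than instances.
    Degenerate polygons (<3 vertices) are skipped with a warning.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations"):
        if key not in doc:
            raise AnnotationFormatError(f"{path}: missing '{key}' section")

    cell_cat_ids = {
        c["id"]
        for c in doc.get("categories", [])
        if c.get("name", "").lower() == "cell"
    }
    images: dict[int, AnnotatedImage] = {}
    for im in doc["images"]:
        images[im["id"]] = AnnotatedImage(
            image_id=str(im.get("file_name", im["id"])),
            width_px=im["width"],
            height_px=im["height"],
            scale=scale,
            role=role,
            grade=im.get("grade"),
        )

    for ann in doc["annotations"]:
        img_id = ann["image_id"]
        if img_id not in images:
            raise AnnotationFormatError(
                f"annotation {ann.get('id')} references unknown image {img_id}"
            )
        image = images[img_id]
        seg = ann["segmentation"]
        mask = None
        rings = None
        if isinstance(seg, dict):
            mask = _decode_uncompressed_rle(seg, image.height_px, image.width_px)
        else:
            try:
                rings = _flat_to_rings(seg)
            except AnnotationFormatError:
                warnings.warn(
                    f"annotation {ann.get('id')} on image {image.image_id}: "
                    "degenerate polygon skipped"
                )
                continue
        if ann.get("category_id") in cell_cat_ids:
            image.cells.append(
                CellRegion(cell_id=int(ann["id"]), mask=mask, polygon=rings)
            )
            continue
        image.instances.append(
            MitoInstance(
                instance_id=int(ann["id"]),
                mask=mask,
                polygon=rings,
                score=ann.get("score"),
                omm_intact=ann.get("omm_intact"),
                mrc_type=ann.get("mrc_type"),
            )
        )
    return [images[k] for k in sorted(images)]


def write_coco_annotations(
    images: list[AnnotatedImage], path: PathLike
) -> None:
    """Write AnnotatedImages to the COCO dialect read by
    :func:`load_coco_annotations`.  Polygon-backed instances keep their
    vertices; raster-only instances are encoded as uncompressed RLE."""
    doc = {
        "images": [],
        "annotations": [],
        "categories": [
            {"id": 1, "name": "mitochondrion"},
            {"id": 2, "name": "cell"},
        ],
    }
    ann_id = 1
    for idx, image in enumerate(images, start=1):
        entry = {
            "id": idx,
            "file_name": image.image_id,
            "width": image.width_px,
            "height": image.height_px,
        }
        if image.grade is not None:
            entry["grade"] = image.grade
        doc["images"].append(entry)
        for cell in image.cells:
            doc["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": idx,
                    "category_id": 2,
                    "segmentation": _encode_segmentation(
                        cell.polygon, cell.mask, image
                    ),
                }
            )
            ann_id += 1
        for inst in image.instances:
            ann = {
                "id": ann_id,
                "image_id": idx,
                "category_id": 1,
                "segmentation": _encode_segmentation(
                    inst.polygon, inst.mask, image
                ),
            }
            if inst.score is not None:
                ann["score"] = float(inst.score)
            if inst.omm_intact is not None:
                ann["omm_intact"] = bool(inst.omm_intact)
            if inst.mrc_type is not None:
                ann["mrc_type"] = int(inst.mrc_type)
            doc["annotations"].append(ann)
            ann_id += 1
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def _encode_segmentation(rings, mask, image: AnnotatedImage):
    if rings is not None:
        return [np.asarray(r, dtype=float).ravel().round(4).tolist() for r in rings]
    flat = mask.T.ravel()  # column-major per COCO RLE
    # run-length encode starting from background
    change = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate([[0], change + 1, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat[0]:
        counts = [0] + counts
    return {"size": [image.height_px, image.width_px], "counts": counts}


def write_measurements_csv(records, path: PathLike) -> None:
    """One row per mitochondrion; lossless to ~1e-12 relative precision."""
    rows = []
    for rec in records:
        rows.append({col: getattr(rec, col) for col in MEASUREMENT_COLUMNS})
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_measurements_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationFormatError(
            f"{path}: missing measurement columns {sorted(missing)}"
        )
    return df
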