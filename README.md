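# mitomorph

Quantitative analysis of mitochondria in transmission-electron-microscopy
(TEM) images: per-mitochondrion shape indices, cristae occupancy and a
three-type cristae-health classification, low-grade vs high-grade group
statistics, and instance-segmentation evaluation metrics (IoU-thresholded
matching with per-image Precision / Recall / F1 plus perimeter and area
error rates). A synthetic-data module generates grade-profiled
ground-truth and perturbed prediction sets so the whole pipeline runs
end-to-end without any clinical archive.

## Modules

| module           | what it does |
|------------------|--------------|
| `model`          | data model (`PixelScale`, `MitoInstance`, `CellRegion`, `AnnotatedImage`) and polygon rasterization (center sampling) |
| `mask_io`        | label-image masks (TIFF/PNG, uint16, 0 = background), a COCO-instance JSON dialect (polygons / uncompressed RLE, optional `score`), measurements CSV |
| `synthetic`      | grade-profiled ground-truth generator, controllable perturbation (drop / spurious / IoU jitter / perimeter & area bias), hand-built reference fixture |
| `morphometry`    | area (µm²), perimeter (µm), circularity `4πA/P²`, cristae occupancy, per-cell density and area ratio |
| `matching`       | score-filtered greedy IoU matching, per-image + macro P/R/F1, signed perimeter/area error rates |
| `classification` | three-type cristae classification (thresholded proxy; human labels override) and LGG/HGG grade grouping |
| `stats`          | Kruskal–Wallis / ANOVA / Mann–Whitney / t-test comparisons, dataset summaries, radar-style normalized means |

Conventions worth knowing:

* **Perimeter of raster masks** is the length of a marching-squares
  contour (0.5 level) smoothed with a closed 5-point moving average —
  an ImageJ-like smooth trace. Raw marching squares on binary data
  overestimates smooth perimeters by ~6%, which would bias circularity
  down to ~0.89 for perfect discs; the smoothed trace is within 1%.
  Polygon-backed instances are measured analytically from vertices.
* **Area error rate** is implemented as `(A_pred − A_gt)/A_gt`, the
  perimeter-analogous signed relative error. (The originally published
  display equation reads `(A_pred − A_pred)/A_pred`, which is identically
  zero — an evident typo.) Signed rates can cancel across a dataset, so
  an absolute-value companion is always reported.
* **Matching** is one-to-one greedy on descending IoU among pairs at or
  above the IoU threshold, after discarding predictions with score < 0.5;
  ties break by higher score, then lower prediction id.
* **Macro averaging**: every metric is computed per image and averaged
  `1/N` over the images where it is defined.

## CLI

```bash
# synthetic ground truth + predictions (COCO JSON pair)
mitomorph simulate --out sim/ --seed 3 --drop-rate 0.1 --spurious-rate 1 --jitter-iou 0.85

# morphometry CSV + dataset summary
mitomorph measure --annotations sim/gt.json --scale-um-per-px 0.02 --out measurements.csv

# matching metrics report (JSON + per-image CSV)
mitomorph evaluate --pred sim/pred.json --gt sim/gt.json --scale-um-per-px 0.02 --out report.json

# group comparisons, radar table, summary
mitomorph report --measurements measurements.csv --grouping lgg-hgg --out report/
```

`simulate` also accepts a YAML dataset spec (`--config spec.yaml`) with
`n_images`, `cells_per_image`, `image_size_px`, `scale_um_per_px`, `seed`
and per-grade `profiles` overrides.

The default synthetic grade profiles encode only a qualitative direction
(higher grade → smaller, denser, rounder mitochondria with more intact
cristae); the magnitudes are invented and must not be read as estimates
of any clinical distribution.

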