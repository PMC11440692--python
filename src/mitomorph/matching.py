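"""Prediction-to-ground-truth matching and the four evaluation statistics.

Per image: predictions with score < 0.5 are discarded; retained
predictions are matched one-to-one to ground truths greedily in descending
IoU order (candidates restricted to pairs with IoU >= the threshold; ties
broken by higher score, then lower prediction id).  Matched pairs are TP,
unmatched retained predictions FP, unmatched ground truths FN.

Precision, Recall and F1 are computed per image as TP/(TP+FP),
TP/(TP+FN) and TP/(TP+(FN+FP)/2), then macro-averaged with 1/N over the
images where the ratio is defined.

Perimeter / area error rates: per TP pair the signed relative difference
(pred - gt)/gt of the measured perimeter (area), averaged per image over
that image's TP pairs, then macro-averaged 1/N over images.  Because
signed contributions can cancel, an absolute-value companion is always
reported.  (The source formulation of the area error rate contains an
evident typo that would make it identically zero; the perimeter-analogous
signed relative error is implemented.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import AnnotatedImage
from .morphometry import MorphometryRecord


@dataclass
class MatchResult:
    """Outcome of score-filtered IoU matching for one image."""

    image_id: str
    tp_pairs: list[tuple[int, int, float]]  # (prediction_id, gt_id, iou)
    fp_ids: list[int]
    fn_ids: list[int]
    n_discarded_low_score: int = 0

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_ids)

    @property
    def fn(self) -> int:
        return len(self.fn_ids)


@dataclass
class MetricsReport:
    """Per-image and macro-averaged evaluation statistics."""

    per_image: dict[str, dict[str, Optional[float]]]
    macro: dict[str, Optional[float]]
    n_images_used: dict[str, int]
    notes: list[str] = field(default_factory=list)


def compute_iou(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∩ b| / |a ∪ b| of two boolean masks on the same raster frame."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask frames differ: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a)) + int(np.count_nonzero(b)) - inter
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    return inter / union


def match_instances(
    pred: AnnotatedImage,
    gt: AnnotatedImage,
    score_thr: float = 0.5,
    iou_thr: float = 0.5,
) -> MatchResult:
    """Score-filter predictions and match them one-to-one to ground truth.

    Ground-truth instances never carry scores; filtering applies to
    predictions only (a prediction without a score is treated as retained).
    """
    if (pred.height_px, pred.width_px) != (gt.height_px, gt.width_px):
        raise ValueError(
            f"raster frames differ between prediction ({pred.height_px}x"
            f"{pred.width_px}) and ground truth ({gt.height_px}x{gt.width_px})"
        )
    retained = []
    n_discarded = 0
    for inst in pred.instances:
        if inst.score is not None and inst.score < score_thr:
            n_discarded += 1
        else:
            retained.append(inst)

    gt_masks = gt.instance_masks()
    pred_masks = {
        p.instance_id: p.get_mask(pred.height_px, pred.width_px)
        for p in retained
    }
    scores = {p.instance_id: (p.score if p.score is not None else 1.0)
              for p in retained}

    candidates = []
    for pid, pmask in pred_masks.items():
        for gid, gmask in gt_masks.items():
            iou = compute_iou(pmask, gmask)
            if iou >= iou_thr:
                candidates.append((iou, scores[pid], pid, gid))
    # descending IoU, ties by higher score then lower prediction id
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))

    matched_pred: set[int] = set()
    matched_gt: set[int] = set()
    tp_pairs: list[tuple[int, int, float]] = []
    for iou, _, pid, gid in candidates:
        if pid in matched_pred or gid in matched_gt:
            continue
        matched_pred.add(pid)
        matched_gt.add(gid)
        tp_pairs.append((pid, gid, iou))

    result = MatchResult(
        image_id=gt.image_id,
        tp_pairs=sorted(tp_pairs),
        fp_ids=sorted(set(pred_masks) - matched_pred),
        fn_ids=sorted(set(gt_masks) - matched_gt),
        n_discarded_low_score=n_discarded,
    )
    # counting identities
    assert result.tp + result.fn == len(gt_masks)
    assert result.tp + result.fp == len(pred_masks)
    return result


def _macro(values: list[Optional[float]]) -> tuple[Optional[float], int]:
    defined = [v for v in values if v is not None]
    if not defined:
        return None, 0
    return float(np.mean(defined)), len(defined)


def precision_recall_f1(matches: list[MatchResult]) -> MetricsReport:
    """Per-image Precision/Recall/F1 and their 1/N macro averages.

    Images where a ratio has a zero denominator are excluded from that
    metric's mean; ``n_images_used`` records how many contributed.
    """
    if not matches:
        raise ValueError("at least one MatchResult is required")
    per_image: dict[str, dict[str, Optional[float]]] = {}
    for m in matches:
        tp, fp, fn = m.tp, m.fp, m.fn
        row: dict[str, Optional[float]] = {
            "precision": tp / (tp + fp) if tp + fp > 0 else None,
            "recall": tp / (tp + fn) if tp + fn > 0 else None,
            "f1": tp / (tp + (fn + fp) / 2) if tp + fp + fn > 0 else None,
        }
        per_image[m.image_id] = row
    macro = {}
    n_used = {}
    notes = []
    for key in ("precision", "recall", "f1"):
        macro[key], n_used[key] = _macro(
            [per_image[i][key] for i in per_image]
        )
        if macro[key] is None:
            notes.append(f"{key} undefined in every image")
    return MetricsReport(
        per_image=per_image, macro=macro, n_images_used=n_used, notes=notes
    )


def _error_rate(
    matches: list[MatchResult],
    pred_measurements: dict[tuple[str, int], MorphometryRecord],
    gt_measurements: dict[tuple[str, int], MorphometryRecord],
    attr: str,
) -> tuple[Optional[float], Optional[float], dict[str, Optional[float]]]:
    per_image: dict[str, Optional[float]] = {}
    per_image_abs: dict[str, Optional[float]] = {}
    for m in matches:
        signed = []
        for pid, gid, _ in m.tp_pairs:
            try:
                pv = getattr(pred_measurements[(m.image_id, pid)], attr)
                gv = getattr(gt_measurements[(m.image_id, gid)], attr)
            except KeyError as exc:
                raise ValueError(
                    f"missing {attr} measurement for TP pair "
                    f"(pred {pid}, gt {gid}) on image {m.image_id}"
                ) from exc
            signed.append((pv - gv) / gv)
        per_image[m.image_id] = float(np.mean(signed)) if signed else None
        per_image_abs[m.image_id] = (
            float(np.mean(np.abs(signed))) if signed else None
        )
    signed_macro, _ = _macro(list(per_image.values()))
    abs_macro, _ = _macro(list(per_image_abs.values()))
    return signed_macro, abs_macro, per_image


def perimeter_error_rate(matches, pred_measurements, gt_measurements):
    """Signed macro, absolute macro, and per-image mean relative
    perimeter errors over TP pairs."""
    return _error_rate(
        matches, pred_measurements, gt_measurements, "perimeter_um"
    )


def area_error_rate(matches, pred_measurements, gt_measurements):
    """Signed macro, absolute macro, and per-image mean relative area
    errors over TP pairs ((A_pred - A_gt)/A_gt; see module docstring on
    the source typo)."""
    return _error_rate(matches, pred_measurements, gt_measurements, "area_um2")


def evaluate(
    pred_images: list[AnnotatedImage],
    gt_images: list[AnnotatedImage],
    score_thr: float = 0.5,
    iou_thr: float = 0.5,
) -> tuple[list[MatchResult], MetricsReport]:
    """Match each prediction image to its ground truth by image_id and
    produce the full metrics report (P/R/F1 + both error rates)."""
    from .morphometry import measure_instance, measurements_by_id, MorphometryRecord

    gt_by_id = {im.image_id: im for im in gt_images}
    matches = []
    pred_records, gt_records = [], []
    for pim in pred_images:
        if pim.image_id not in gt_by_id:
            raise ValueError(f"no ground truth for image {pim.image_id}")
        gim = gt_by_id[pim.image_id]
        matches.append(match_instances(pim, gim, score_thr, iou_thr))
        for im, sink in ((pim, pred_records), (gim, gt_records)):
            for inst in im.instances:
                area, perim, circ = measure_instance(inst, im.scale)
                sink.append(
                    MorphometryRecord(
                        image_id=im.image_id,
                        cell_id=None,
                        instance_id=inst.instance_id,
                        area_um2=area,
                        perimeter_um=perim,
                        circularity=circ,
                    )
                )
    report = precision_recall_f1(matches)
    pm = measurements_by_id(pred_records)
    gm = measurements_by_id(gt_records)
    p_signed, p_abs, p_per = perimeter_error_rate(matches, pm, gm)
    a_signed, a_abs, a_per = area_error_rate(matches, pm, gm)
    report.macro["perimeter_error_rate"] = p_signed
    report.macro["perimeter_error_rate_abs"] = p_abs
    report.macro["area_error_rate"] = a_signed
    report.macro["area_error_rate_abs"] = a_abs
    for image_id in report.per_image:
        report.per_image[image_id]["perimeter_error_rate"] = p_per.get(image_id)
        report.per_image[image_id]["area_error_rate"] = a_per.get(image_id)
    report.n_images_used["perimeter_error_rate"] = sum(
        v is not None for v in p_per.values()
    )
    report.n_images_used["area_error_rate"] = sum(
        v is not None for v in a_per.values()
    )
    return matches, report
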