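import itertools

import numpy as np
import pytest

from mitomorph import (
    AnnotatedImage,
    MitoInstance,
    PixelScale,
    Role,
    compute_iou,
    evaluate,
    match_instances,
    precision_recall_f1,
    perimeter_error_rate,
    area_error_rate,
)
from mitomorph.matching import MatchResult
from mitomorph.morphometry import MorphometryRecord


def rect_mask(frame, r0, c0, h, w):
    m = np.zeros(frame, dtype=bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


class TestComputeIou:
    def test_identical(self):
        m = rect_mask((10, 10), 2, 2, 4, 4)
        assert compute_iou(m, m) == 1.0

    def test_disjoint(self):
        a = rect_mask((10, 10), 0, 0, 3, 3)
        b = rect_mask((10, 10), 6, 6, 3, 3)
        assert compute_iou(a, b) == 0.0

    def test_partial_overlap_brute_force(self):
        # two 2x2 squares overlapping in a 1x2 strip -> 2/6
        a = rect_mask((8, 8), 2, 2, 2, 2)
        b = rect_mask((8, 8), 3, 2, 2, 2)
        inter = int((a & b).sum())
        union = int((a | b).sum())
        assert (inter, union) == (2, 6)
        assert compute_iou(a, b) == pytest.approx(2 / 6)

    def test_both_empty_is_error(self):
        z = np.zeros((5, 5), dtype=bool)
        with pytest.raises(ValueError):
            compute_iou(z, z)

    def test_symmetry(self, rng):
        a = rng.random((12, 12)) > 0.5
        b = rng.random((12, 12)) > 0.5
        a[0, 0] = b[1, 1] = True
        assert compute_iou(a, b) == compute_iou(b, a)


def build_image(image_id, instances, role, frame=(32, 32)):
    im = AnnotatedImage(
        image_id=image_id, width_px=frame[1], height_px=frame[0],
        scale=PixelScale(1.0), role=role,
    )
    im.instances = instances
    return im


class TestMatchInstances:
    def test_identity_all_tp(self):
        masks = [rect_mask((32, 32), 2 + 8 * i, 2, 5, 5) for i in range(3)]
        gt = build_image("a", [
            MitoInstance(instance_id=i + 1, mask=m)
            for i, m in enumerate(masks)
        ], Role.GROUND_TRUTH)
        pred = build_image("a", [
            MitoInstance(instance_id=i + 1, mask=m.copy(), score=0.9)
            for i, m in enumerate(masks)
        ], Role.PREDICTION)
        res = match_instances(pred, gt)
        assert (res.tp, res.fp, res.fn) == (3, 0, 0)

    def test_low_scores_all_discarded(self):
        m = rect_mask((32, 32), 2, 2, 5, 5)
        gt = build_image("a", [MitoInstance(instance_id=1, mask=m)],
                         Role.GROUND_TRUTH)
        pred = build_image("a", [
            MitoInstance(instance_id=1, mask=m.copy(), score=0.4)
        ], Role.PREDICTION)
        res = match_instances(pred, gt)
        assert (res.tp, res.fp, res.fn) == (0, 0, 1)
        assert res.n_discarded_low_score == 1

    def test_two_predictions_one_gt(self):
        gt_mask = rect_mask((32, 32), 5, 5, 10, 10)
        p_hi = rect_mask((32, 32), 5, 5, 10, 11)  # IoU 100/110
        p_lo = rect_mask((32, 32), 5, 5, 10, 14)  # IoU 100/140
        gt = build_image("a", [MitoInstance(instance_id=1, mask=gt_mask)],
                         Role.GROUND_TRUTH)
        pred = build_image("a", [
            MitoInstance(instance_id=1, mask=p_lo, score=0.9),
            MitoInstance(instance_id=2, mask=p_hi, score=0.9),
        ], Role.PREDICTION)
        res = match_instances(pred, gt)
        assert res.tp_pairs[0][0] == 2  # the higher-IoU prediction wins
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_frame_mismatch_rejected(self):
        m = rect_mask((32, 32), 2, 2, 5, 5)
        gt = build_image("a", [MitoInstance(instance_id=1, mask=m)],
                         Role.GROUND_TRUTH)
        m2 = rect_mask((16, 16), 2, 2, 5, 5)
        pred = build_image("a", [MitoInstance(instance_id=1, mask=m2)],
                           Role.PREDICTION, frame=(16, 16))
        with pytest.raises(ValueError, match="frames differ"):
            match_instances(pred, gt)

    def test_counting_identities_random(self, rng):
        for _ in range(30):
            frame = (24, 24)
            gts, preds = random_instances(rng, frame)
            gt = build_image("a", gts, Role.GROUND_TRUTH, frame)
            pred = build_image("a", preds, Role.PREDICTION, frame)
            res = match_instances(pred, gt)
            retained = [p for p in preds if (p.score or 1.0) >= 0.5]
            assert res.tp + res.fn == len(gts)
            assert res.tp + res.fp == len(retained)
            pids = [p for p, _, _ in res.tp_pairs]
            gids = [g for _, g, _ in res.tp_pairs]
            assert len(pids) == len(set(pids))
            assert len(gids) == len(set(gids))


def random_instances(rng, frame, max_gt=6, max_pred=6):
    """Disjoint GT rectangles plus jittered/spurious predictions."""
    gts = []
    row = 1
    for i in range(rng.integers(1, max_gt + 1)):
        h, w = rng.integers(3, 6, size=2)
        if row + h >= frame[0] - 1:
            break
        c0 = int(rng.integers(1, frame[1] - w - 1))
        gts.append(MitoInstance(
            instance_id=i + 1, mask=rect_mask(frame, row, c0, h, w)
        ))
        row += h + 1
    preds = []
    pid = 1
    for g in gts:
        for _ in range(rng.integers(0, 3)):
            rr, cc = np.nonzero(g.mask)
            dr, dc = rng.integers(-2, 3, size=2)
            r0 = int(np.clip(rr.min() + dr, 0, frame[0] - 2))
            c0 = int(np.clip(cc.min() + dc, 0, frame[1] - 2))
            h = rr.max() - rr.min() + 1
            w = cc.max() - cc.min() + 1
            h2 = int(min(h, frame[0] - r0))
            w2 = int(min(w, frame[1] - c0))
            preds.append(MitoInstance(
                instance_id=pid,
                mask=rect_mask(frame, r0, c0, h2, w2),
                score=float(rng.uniform(0.3, 1.0)),
            ))
            pid += 1
            if len(preds) >= max_pred:
                break
        if len(preds) >= max_pred:
            break
    if not preds:
        preds.append(MitoInstance(
            instance_id=pid, mask=rect_mask(frame, 1, 1, 3, 3), score=0.9
        ))
    return gts, preds


def brute_force_match(pred_masks, gt_masks, iou_thr=0.5):
    """Exhaustive optimal assignment: max matched pairs, then max ΣIoU."""
    pids = list(pred_masks)
    gids = list(gt_masks)
    candidates = {}
    for p in pids:
        for g in gids:
            iou = compute_iou(pred_masks[p], gt_masks[g])
            if iou >= iou_thr:
                candidates[(p, g)] = iou
    best = (0, 0.0)
    k_max = min(len(pids), len(gids))
    for k in range(k_max, -1, -1):
        found = False
        for psub in itertools.combinations(pids, k):
            for gperm in itertools.permutations(gids, k):
                pairs = list(zip(psub, gperm))
                if all(pr in candidates for pr in pairs):
                    total = sum(candidates[pr] for pr in pairs)
                    best = max(best, (k, total))
                    found = True
        if found:
            break
    return best


class TestGreedyAgainstOracle:
    def test_greedy_equals_brute_force(self, rng):
        frame = (24, 24)
        for _ in range(100):
            gts, preds = random_instances(rng, frame)
            gt = build_image("a", gts, Role.GROUND_TRUTH, frame)
            pred = build_image("a", preds, Role.PREDICTION, frame)
            res = match_instances(pred, gt)
            retained = {
                p.instance_id: p.mask for p in preds
                if (p.score or 1.0) >= 0.5
            }
            gt_masks = {g.instance_id: g.mask for g in gts}
            n_opt, iou_opt = brute_force_match(retained, gt_masks)
            assert res.tp == n_opt
            assert sum(i for _, _, i in res.tp_pairs) == pytest.approx(iou_opt)


class TestPrecisionRecallF1:
    def _mr(self, image_id, tp, fp, fn):
        return MatchResult(
            image_id=image_id,
            tp_pairs=[(i, i, 1.0) for i in range(tp)],
            fp_ids=list(range(100, 100 + fp)),
            fn_ids=list(range(200, 200 + fn)),
        )

    def test_single_image_printed_formulas(self):
        rep = precision_recall_f1([self._mr("a", 2, 1, 1)])
        assert rep.macro["precision"] == pytest.approx(2 / 3, abs=1e-12)
        assert rep.macro["recall"] == pytest.approx(2 / 3, abs=1e-12)
        # F1 = TP/(TP + (FN+FP)/2) = 2/(2+1) = 2/3
        assert rep.macro["f1"] == pytest.approx(2 / 3, abs=1e-12)

    def test_macro_is_mean_of_per_image(self):
        rep = precision_recall_f1(
            [self._mr("a", 2, 0, 0), self._mr("b", 1, 1, 0)]
        )
        assert rep.macro["precision"] == pytest.approx(0.75)

    def test_f1_equals_harmonic_mean(self, rng):
        for _ in range(50):
            tp = int(rng.integers(1, 8))
            fp = int(rng.integers(0, 5))
            fn = int(rng.integers(0, 5))
            rep = precision_recall_f1([self._mr("a", tp, fp, fn)])
            p = rep.macro["precision"]
            r = rep.macro["recall"]
            assert rep.macro["f1"] == pytest.approx(
                2 * p * r / (p + r), abs=1e-12
            )

    def test_undefined_metric_excluded_from_mean(self):
        rep = precision_recall_f1(
            [self._mr("a", 0, 0, 2), self._mr("b", 1, 0, 0)]
        )
        assert rep.macro["precision"] == 1.0  # image a has no predictions
        assert rep.n_images_used["precision"] == 1
        assert rep.macro["recall"] == pytest.approx(0.5)

    def test_adding_spurious_never_increases_precision(self, rng):
        for _ in range(20):
            tp = int(rng.integers(1, 6))
            fp = int(rng.integers(0, 4))
            before = precision_recall_f1([self._mr("a", tp, fp, 0)])
            after = precision_recall_f1([self._mr("a", tp, fp + 1, 0)])
            assert after.macro["precision"] <= before.macro["precision"]

    def test_dropping_matched_prediction_never_increases_recall(self, rng):
        for _ in range(20):
            tp = int(rng.integers(1, 6))
            fn = int(rng.integers(0, 4))
            before = precision_recall_f1([self._mr("a", tp, 0, fn)])
            after = precision_recall_f1([self._mr("a", tp - 1, 0, fn + 1)])
            assert after.macro["recall"] <= before.macro["recall"]


def _measurement(image_id, instance_id, area, perim):
    return MorphometryRecord(
        image_id=image_id, cell_id=None, instance_id=instance_id,
        area_um2=area, perimeter_um=perim, circularity=0.7,
    )


class TestErrorRates:
    def _setup(self, pairs):
        matches = [MatchResult(
            image_id="a",
            tp_pairs=[(i, i, 1.0) for i in range(len(pairs))],
            fp_ids=[], fn_ids=[],
        )]
        pm = {("a", i): _measurement("a", i, ap, pp)
              for i, (ap, pp, _, _) in enumerate(pairs)}
        gm = {("a", i): _measurement("a", i, ag, pg)
              for i, (_, _, ag, pg) in enumerate(pairs)}
        return matches, pm, gm

    def test_equal_measurements_zero(self):
        matches, pm, gm = self._setup([(100, 40, 100, 40)] * 3)
        signed, abs_, _ = perimeter_error_rate(matches, pm, gm)
        assert signed == 0.0 and abs_ == 0.0
        signed, abs_, _ = area_error_rate(matches, pm, gm)
        assert signed == 0.0 and abs_ == 0.0

    def test_single_pair_perimeter(self):
        matches, pm, gm = self._setup([(100, 11, 100, 10)])
        signed, _, per = perimeter_error_rate(matches, pm, gm)
        assert signed == pytest.approx(0.1, abs=1e-12)
        assert per["a"] == pytest.approx(0.1, abs=1e-12)

    def test_single_pair_area_negative(self):
        matches, pm, gm = self._setup([(90, 40, 100, 40)])
        signed, abs_, _ = area_error_rate(matches, pm, gm)
        assert signed == pytest.approx(-0.1, abs=1e-12)
        assert abs_ == pytest.approx(0.1, abs=1e-12)

    def test_signed_cancellation_visible_in_abs(self):
        matches, pm, gm = self._setup([(110, 40, 100, 40),
                                       (90, 40, 100, 40)])
        signed, abs_, _ = area_error_rate(matches, pm, gm)
        assert signed == pytest.approx(0.0, abs=1e-12)
        assert abs_ == pytest.approx(0.1, abs=1e-12)

    def test_missing_measurement_names_pair(self):
        matches, pm, gm = self._setup([(100, 40, 100, 40)])
        del pm[("a", 0)]
        with pytest.raises(ValueError, match=r"pred 0"):
            perimeter_error_rate(matches, pm, gm)
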