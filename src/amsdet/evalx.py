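"""Detection metrics: precision/recall, per-class AP, mAP50, mAP50:95 and a
background-aware confusion matrix.

AP uses greedy confidence-ordered one-to-one matching at an IoU threshold and
the 101-point interpolated precision envelope (COCO convention).  mAP50:95
averages the class-mean AP over IoU thresholds 0.50 to 0.95 in steps of 0.05.
Reported P/R are taken at the maximum-F1 point of the pooled PR curve.

Detections are (class_id, confidence, x1, y1, x2, y2); ground truths are
(class_id, x1, y1, x2, y2); both carry an image identifier so matching never
crosses images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

IOU_THRESHOLDS = np.round(np.arange(0.5, 0.96, 0.05), 2)


def iou(box_a, box_b):
    """Intersection-over-union of two xyxy boxes; degenerate boxes give 0."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    union = area_a + area_b - inter
    return float(inter / union) if union > 0 else 0.0


@dataclass
class MatchResult:
    tp_flags: np.ndarray       # per-detection, confidence-descending order
    n_gt: int
    confidences: np.ndarray


@dataclass
class MetricsReport:
    precision: float
    recall: float
    per_class_ap50: dict
    map50: float
    map50_95: float
    confusion: np.ndarray = None

    def to_dict(self):
        return {
            "precision": self.precision,
            "recall": self.recall,
            "per_class_ap50": {int(k): float(v) for k, v in self.per_class_ap50.items()},
            "mAP50": self.map50,
            "mAP50_95": self.map50_95,
        }


def _match(detections, ground_truths, iou_thr):
    """Greedy one-to-one matching within one class.

    ``detections``: (image_id, conf, box) sorted later by confidence.
    ``ground_truths``: (image_id, box).  Each detection, in descending
    confidence, claims the highest-IoU unmatched ground truth of its image at
    or above the threshold.
    """
    order = sorted(range(len(detections)), key=lambda i: -detections[i][1])
    gt_by_img = {}
    for j, (img, box) in enumerate(ground_truths):
        gt_by_img.setdefault(img, []).append((j, box))
    used = set()
    tp = np.zeros(len(detections), dtype=bool)
    matched_gt = np.full(len(detections), -1)
    for rank, i in enumerate(order):
        img, conf, box = detections[i]
        best, best_iou = -1, iou_thr
        for j, gt_box in gt_by_img.get(img, []):
            if j in used:
                continue
            v = iou(box, gt_box)
            if v >= best_iou:
                best, best_iou = j, v
        if best >= 0:
            used.add(best)
            tp[rank] = True
            matched_gt[rank] = best
    confs = np.array([detections[i][1] for i in order], dtype=float)
    return MatchResult(tp_flags=tp, n_gt=len(ground_truths), confidences=confs), matched_gt, order


def precision_recall(match: MatchResult):
    """Set-level P and R from a match result: P=TP/(TP+FP), R=TP/(TP+FN);
    no detections gives P=0 by convention."""
    tp = int(match.tp_flags.sum())
    fp = len(match.tp_flags) - tp
    fn = match.n_gt - tp
    p = tp / (tp + fp) if (tp + fp) else 0.0
    r = tp / (tp + fn) if (tp + fn) else 0.0
    return p, r


def average_precision(detections, ground_truths, iou_thr=0.5):
    """AP for one class: 101-point interpolated envelope over recall."""
    if not ground_truths:
        return 0.0 if detections else float("nan")
    if not detections:
        return 0.0
    match, _, _ = _match(detections, ground_truths, iou_thr)
    tp_cum = np.cumsum(match.tp_flags)
    fp_cum = np.cumsum(~match.tp_flags)
    recall = tp_cum / match.n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # precision envelope, then sample at 101 recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        idx = np.searchsorted(recall, r, side="left")
        ap += env[idx] if idx < len(env) else 0.0
    return float(ap / 101)


def _pooled_pr_max_f1(dets_by_class, gts_by_class, iou_thr=0.5):
    """Pool all classes' detections, sweep confidence, return P/R at max F1."""
    rows = []
    total_gt = 0
    for cid, dets in dets_by_class.items():
        gts = gts_by_class.get(cid, [])
        if not dets and not gts:
            continue
        match, _, _ = _match(dets, gts, iou_thr)
        for conf, flag in zip(match.confidences, match.tp_flags):
            rows.append((conf, flag))
    total_gt = sum(len(g) for g in gts_by_class.values())
    if not rows or total_gt == 0:
        return 0.0, 0.0
    rows.sort(key=lambda t: -t[0])
    flags = np.array([f for _, f in rows])
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    p = tp / np.maximum(tp + fp, 1)
    r = tp / total_gt
    f1 = 2 * p * r / np.maximum(p + r, 1e-12)
    i = int(np.argmax(f1))
    return float(p[i]), float(r[i])


def _group(detections, ground_truths, num_classes):
    dets_by_class = {c: [] for c in range(num_classes)}
    gts_by_class = {c: [] for c in range(num_classes)}
    for d in detections:
        img, cid, conf, box = d
        if not 0 <= cid < num_classes:
            raise InputError(f"unknown class id {cid}")
        dets_by_class[cid].append((img, conf, box))
    for g in ground_truths:
        img, cid, box = g
        if not 0 <= cid < num_classes:
            raise InputError(f"unknown class id {cid}")
        gts_by_class[cid].append((img, box))
    return dets_by_class, gts_by_class


def map_suite(detections, ground_truths, num_classes):
    """Full metric bundle.

    ``detections``: iterable of (image_id, class_id, conf, (x1,y1,x2,y2));
    ``ground_truths``: iterable of (image_id, class_id, (x1,y1,x2,y2)).
    Classes with no ground truth anywhere are excluded from the mAP means.
    """
    dets_by_class, gts_by_class = _group(detections, ground_truths, num_classes)
    active = [c for c in range(num_classes) if gts_by_class[c]]
    per_class_ap50 = {}
    ap_per_thr = {t: [] for t in IOU_THRESHOLDS}
    for c in active:
        for t in IOU_THRESHOLDS:
            ap = average_precision(dets_by_class[c], gts_by_class[c], t)
            ap_per_thr[t].append(ap)
            if t == 0.5:
                per_class_ap50[c] = ap
    map50 = float(np.mean(ap_per_thr[0.5])) if active else 0.0
    map5095 = float(np.mean([np.mean(ap_per_thr[t]) for t in IOU_THRESHOLDS])) if active else 0.0
    p, r = _pooled_pr_max_f1(dets_by_class, gts_by_class)
    return MetricsReport(precision=p, recall=r, per_class_ap50=per_class_ap50,
                         map50=map50, map50_95=map5095)


def confusion_matrix(detections, ground_truths, num_classes, iou_thr=0.45,
                     conf_thr=0.25):
    """(num_classes+1)^2 counts; last row/column is background.

    IoU-matched detection/GT pairs increment (true, predicted); unmatched GT
    increments (true, background); unmatched detections (background, pred).
    """
    m = np.zeros((num_classes + 1, num_classes + 1), dtype=int)
    by_img = {}
    for img, cid, conf, box in detections:
        if conf >= conf_thr:
            by_img.setdefault(img, ([], []))[0].append((cid, conf, box))
    for img, cid, box in ground_truths:
        by_img.setdefault(img, ([], []))[1].append((cid, box))
    for img, (dets, gts) in by_img.items():
        dets = sorted(dets, key=lambda d: -d[1])
        used = set()
        matched_det = set()
        for i, (dcid, conf, dbox) in enumerate(dets):
            best, best_iou = -1, iou_thr
            for j, (gcid, gbox) in enumerate(gts):
                if j in used:
                    continue
                v = iou(dbox, gbox)
                if v >= best_iou:
                    best, best_iou = j, v
            if best >= 0:
                used.add(best)
                matched_det.add(i)
                m[gts[best][0], dcid] += 1
        for j, (gcid, _) in enumerate(gts):
            if j not in used:
                m[gcid, num_classes] += 1
        for i, (dcid, _, _) in enumerate(dets):
            if i not in matched_det:
                m[num_classes, dcid] += 1
    return m


def normalize_confusion(m):
    """Row-normalised view (rows = true classes); zero rows stay zero."""
    sums = m.sum(axis=1, keepdims=True)
    return np.divide(m, np.maximum(sums, 1), dtype=float)
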