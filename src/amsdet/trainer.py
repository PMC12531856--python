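"""Training harness: task-aligned assignment, composite detection loss, AdamW.

The loss follows the anchor-free YOLOv8 recipe: binary cross-entropy on class
logits (targets are the assigner's soft alignment scores), complete-IoU on
decoded boxes of positive cells, and distribution-focal loss on the per-side
distance distributions; term weights 7.5 (box) / 0.5 (cls) / 1.5 (dfl).

Positive cells are chosen by the task-aligned rule: among cells whose centre
lies inside a ground-truth box, the top-k=10 by the alignment metric
``s^alpha * u^beta`` (s = predicted probability of the true class, u = IoU of
the decoded box, alpha=0.5, beta=6).  A cell claimed by several boxes goes to
the one with the highest alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assembly import DetectionModel, decode_predictions, iou_xyxy, nms
from .errors import InputError
from .evalx import map_suite
from .nn import F, AdamW, Tensor, clip_grad_norm, no_grad


@dataclass
class TrainConfig:
    image_size: int = 640
    epochs: int = 200
    batch_size: int = 16
    workers: int = 4            # kept for config parity; loading is in-process
    optimizer: str = "AdamW"
    learning_rate: float = 0.002
    momentum: float = 0.937     # maps to AdamW beta1
    weight_decay: float = 0.0005
    seed: int = 0
    warmup_epochs: int = 3
    final_lr_frac: float = 0.1
    box_gain: float = 7.5
    cls_gain: float = 0.5
    dfl_gain: float = 1.5
    assigner_topk: int = 10
    assigner_alpha: float = 0.5
    assigner_beta: float = 6.0
    eval_interval: int = 10

    def __post_init__(self):
        for name in ("image_size", "epochs", "batch_size", "learning_rate",
                     "momentum"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise InputError("weight_decay must be nonnegative")


def make_anchors(level_hw, strides):
    """Cell centres ((x+0.5)*s, (y+0.5)*s) in pixels and per-cell strides."""
    pts, strs = [], []
    for (h, w), s in zip(level_hw, strides):
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts.append(np.stack([(gx.ravel() + 0.5) * s, (gy.ravel() + 0.5) * s], axis=1))
        strs.append(np.full(h * w, s, dtype=np.float32))
    return np.concatenate(pts).astype(np.float32), np.concatenate(strs)


def _flatten_head(raw_levels, reg_max, nc):
    """Per-level (B, 4*reg_max+nc, H, W) -> (B, A, 4, reg_max) and (B, A, nc)."""
    dists, scores = [], []
    for raw in raw_levels:
        b, c, h, w = raw.data.shape
        flat = F.transpose(F.reshape(raw, (b, c, h * w)), (0, 2, 1))
        dists.append(F.narrow(flat, 2, 0, 4 * reg_max))
        scores.append(F.narrow(flat, 2, 4 * reg_max, nc))
    dist = F.concat(dists, axis=1)
    a = dist.data.shape[1]
    return F.reshape(dist, (dist.data.shape[0], a, 4, reg_max)), F.concat(scores, axis=1)


def _decode_boxes(pred_dist, anchors, strides, reg_max):
    """Expected distances (softmax over bins) -> xyxy boxes in pixels."""
    probs = F.softmax(pred_dist, axis=-1)
    bins = np.arange(reg_max, dtype=np.float32).reshape(1, 1, 1, reg_max)
    ltrb = F.sum_(F.mul(probs, bins), axis=-1)           # (B, A, 4)
    s = strides.reshape(1, -1, 1)
    ax = anchors[:, 0].reshape(1, -1)
    ay = anchors[:, 1].reshape(1, -1)
    l = F.mul(F.narrow(ltrb, 2, 0, 1), s)
    t = F.mul(F.narrow(ltrb, 2, 1, 1), s)
    r = F.mul(F.narrow(ltrb, 2, 2, 1), s)
    b_ = F.mul(F.narrow(ltrb, 2, 3, 1), s)
    x1 = F.add(F.mul(l, -1.0), ax[..., None])
    y1 = F.add(F.mul(t, -1.0), ay[..., None])
    x2 = F.add(r, ax[..., None])
    y2 = F.add(b_, ay[..., None])
    return F.concat([x1, y1, x2, y2], axis=2)            # (B, A, 4)


def ciou(pred, target, eps=1e-7):
    """Complete IoU between (n,4) predicted boxes (Tensor) and numpy targets.

    CIoU = IoU - rho^2/c^2 - alpha*v, with rho the centre distance, c the
    enclosing-box diagonal and v the aspect-ratio consistency term.
    """
    tx1, ty1, tx2, ty2 = (target[:, i] for i in range(4))
    px1 = F.narrow(pred, 1, 0, 1).reshape(-1)
    py1 = F.narrow(pred, 1, 1, 1).reshape(-1)
    px2 = F.narrow(pred, 1, 2, 1).reshape(-1)
    py2 = F.narrow(pred, 1, 3, 1).reshape(-1)
    iw = F.maximum(F.add(F.minimum(px2, tx2), F.mul(F.maximum(px1, tx1), -1.0)), 0.0)
    ih = F.maximum(F.add(F.minimum(py2, ty2), F.mul(F.maximum(py1, ty1), -1.0)), 0.0)
    inter = F.mul(iw, ih)
    pw = F.maximum(F.add(px2, F.mul(px1, -1.0)), eps)
    ph = F.maximum(F.add(py2, F.mul(py1, -1.0)), eps)
    tw = np.maximum(tx2 - tx1, eps)
    th = np.maximum(ty2 - ty1, eps)
    union = F.add(F.add(F.mul(pw, ph), tw * th), F.mul(inter, -1.0))
    iou = F.mul(inter, F.pow_(F.add(union, eps), -1.0))
    # centre distance over enclosing diagonal
    pcx = F.mul(F.add(px1, px2), 0.5)
    pcy = F.mul(F.add(py1, py2), 0.5)
    tcx, tcy = (tx1 + tx2) / 2, (ty1 + ty2) / 2
    rho2 = F.add(F.pow_(F.add(pcx, -tcx), 2.0), F.pow_(F.add(pcy, -tcy), 2.0))
    cw = F.add(F.maximum(px2, tx2), F.mul(F.minimum(px1, tx1), -1.0))
    ch = F.add(F.maximum(py2, ty2), F.mul(F.minimum(py1, ty1), -1.0))
    c2 = F.add(F.add(F.pow_(cw, 2.0), F.pow_(ch, 2.0)), eps)
    v = F.mul(F.pow_(F.add(F.atan(F.mul(pw, F.pow_(ph, -1.0))),
                           -np.arctan(tw / th)), 2.0), 4.0 / math.pi ** 2)
    with no_grad():
        alpha = v.data / (1.0 - iou.data + v.data + eps)
    return F.add(iou, F.mul(F.add(F.mul(rho2, F.pow_(c2, -1.0)), F.mul(v, alpha)), -1.0))


def task_aligned_assign(scores, boxes, anchors, gt_boxes, gt_classes,
                        topk=10, alpha=0.5, beta=6.0):
    """Assign cells to ground-truth boxes for one image (pure numpy, no grad).

    Returns (fg_mask (A,), gt_index (A,), target_scores (A, nc)).
    """
    a = anchors.shape[0]
    nc = scores.shape[1]
    fg = np.zeros(a, dtype=bool)
    gt_idx = np.full(a, -1)
    tgt = np.zeros((a, nc), dtype=np.float32)
    if len(gt_boxes) == 0:
        return fg, gt_idx, tgt
    inside = ((anchors[:, 0:1] > gt_boxes[:, 0]) & (anchors[:, 0:1] < gt_boxes[:, 2]) &
              (anchors[:, 1:2] > gt_boxes[:, 1]) & (anchors[:, 1:2] < gt_boxes[:, 3]))
    ious = iou_xyxy(boxes, gt_boxes)                    # (A, n_gt)
    probs = 1.0 / (1.0 + np.exp(-scores))
    align = (probs[:, gt_classes] ** alpha) * (np.clip(ious, 0, 1) ** beta)
    align = np.where(inside, align, 0.0)
    mask = np.zeros_like(align, dtype=bool)
    for j in range(gt_boxes.shape[0]):
        cand = np.nonzero(inside[:, j])[0]
        if cand.size == 0:
            continue
        k = min(topk, cand.size)
        top = cand[np.argsort(-align[cand, j], kind="stable")[:k]]
        top = top[align[top, j] > 0]
        if top.size == 0:  # degenerate predictions: fall back to best IoU inside
            top = cand[np.argsort(-ious[cand, j], kind="stable")[:1]]
        mask[top, j] = True
    # resolve multi-box conflicts by highest alignment
    claimed = mask.any(axis=1)
    best_gt = np.argmax(np.where(mask, align, -1.0), axis=1)
    fg[claimed] = True
    gt_idx[claimed] = best_gt[claimed]
    # normalised soft targets: per gt, t_hat = t / max_t * max_iou
    for j in range(gt_boxes.shape[0]):
        cells = np.nonzero(fg & (gt_idx == j))[0]
        if cells.size == 0:
            continue
        t = align[cells, j]
        u = ious[cells, j]
        denom = t.max() + 1e-9
        tgt[cells, gt_classes[j]] = t / denom * max(u.max(), 1e-3)
    return fg, gt_idx, tgt


class DetectionLoss:
    """Composite loss bound to a model's head geometry."""

    def __init__(self, num_classes, reg_max=16, strides=(8, 16, 32), cfg=None):
        self.nc = num_classes
        self.reg_max = reg_max
        self.strides = strides
        self.cfg = cfg or TrainConfig(epochs=1)

    def __call__(self, raw_levels, targets, image_size):
        """``targets``: per-image arrays (n, 5) of (class, cx, cy, w, h)
        normalised.  Returns (total loss Tensor, components dict)."""
        cfg = self.cfg
        level_hw = [r.data.shape[2:] for r in raw_levels]
        anchors, strides = make_anchors(level_hw, self.strides)
        pred_dist, pred_scores = _flatten_head(raw_levels, self.reg_max, self.nc)
        pred_boxes = _decode_boxes(pred_dist, anchors, strides, self.reg_max)
        bsz = pred_scores.data.shape[0]
        a = anchors.shape[0]
        fg_all = np.zeros((bsz, a), dtype=bool)
        tgt_scores = np.zeros((bsz, a, self.nc), dtype=np.float32)
        tgt_boxes = np.zeros((bsz, a, 4), dtype=np.float32)
        for b in range(bsz):
            t = np.asarray(targets[b], dtype=np.float32).reshape(-1, 5)
            if np.any(~np.isfinite(t)):
                raise InputError("non-finite target values")
            if t.shape[0] and (t[:, 1:].min() < 0 or t[:, 1:].max() > 1.001):
                raise InputError("targets must be normalised to [0, 1]")
            gt_cls = t[:, 0].astype(int)
            cx, cy, w, h = (t[:, i] * image_size for i in range(1, 5))
            gt_xyxy = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)
            fg, gt_idx, tgt = task_aligned_assign(
                pred_scores.data[b], pred_boxes.data[b], anchors, gt_xyxy, gt_cls,
                cfg.assigner_topk, cfg.assigner_alpha, cfg.assigner_beta)
            fg_all[b] = fg
            tgt_scores[b] = tgt
            if fg.any():
                tgt_boxes[b, fg] = gt_xyxy[gt_idx[fg]]
        score_sum = max(float(tgt_scores.sum()), 1.0)
        # classification: BCE with logits against soft alignment targets
        probs = F.sigmoid(pred_scores)
        eps = 1e-7
        bce = F.mul(F.add(F.mul(Tensor(tgt_scores), F.log(probs, eps)),
                          F.mul(Tensor(1.0 - tgt_scores), F.log(F.add(F.mul(probs, -1.0), 1.0), eps))),
                    -1.0)
        cls_loss = F.mul(bce.sum(), 1.0 / score_sum)
        n_fg = int(fg_all.sum())
        if n_fg:
            flat_idx = np.nonzero(fg_all.reshape(-1))[0]
            pb = gather_flat(pred_boxes, flat_idx, 4)
            tb = tgt_boxes.reshape(-1, 4)[flat_idx]
            weight = tgt_scores.reshape(-1, self.nc)[flat_idx].sum(axis=1)
            iou_t = ciou(pb, tb)
            box_loss = F.mul(F.sum_(F.mul(F.add(F.mul(iou_t, -1.0), 1.0), weight)),
                             1.0 / score_sum)
            # distribution focal loss on the four per-side bin distributions
            pd = gather_flat(F.reshape(pred_dist, (bsz * a, 4 * self.reg_max)),
                             flat_idx, 4 * self.reg_max)
            pd = F.reshape(pd, (n_fg, 4, self.reg_max))
            anchor_rep = np.tile(anchors, (bsz, 1))[flat_idx]
            stride_rep = np.tile(strides, bsz)[flat_idx]
            ltrb = np.stack([
                anchor_rep[:, 0] - tb[:, 0], anchor_rep[:, 1] - tb[:, 1],
                tb[:, 2] - anchor_rep[:, 0], tb[:, 3] - anchor_rep[:, 1]], axis=1)
            ltrb = np.clip(ltrb / stride_rep[:, None], 0, self.reg_max - 1 - 0.01)
            tl = np.floor(ltrb).astype(int)
            wr = ltrb - tl
            wl = 1.0 - wr
            logp = F.add(F.log(F.softmax(pd, axis=-1), 1e-9), 0.0)
            onehot_l = np.zeros((n_fg, 4, self.reg_max), np.float32)
            onehot_r = np.zeros((n_fg, 4, self.reg_max), np.float32)
            rows = np.arange(n_fg)[:, None]
            cols = np.arange(4)[None, :]
            onehot_l[rows, cols, tl] = wl
            onehot_r[rows, cols, np.minimum(tl + 1, self.reg_max - 1)] += wr
            dfl_per = F.mul(F.sum_(F.mul(logp, Tensor(onehot_l + onehot_r)), axis=(1, 2)),
                            -1.0 / 4.0)
            dfl_loss = F.mul(F.sum_(F.mul(dfl_per, weight)), 1.0 / score_sum)
        else:
            box_loss = Tensor(0.0)
            dfl_loss = Tensor(0.0)
        total = F.add(F.add(F.mul(box_loss, cfg.box_gain), F.mul(cls_loss, cfg.cls_gain)),
                      F.mul(dfl_loss, cfg.dfl_gain))
        comps = {"box": float(box_loss.data) * cfg.box_gain,
                 "cls": float(cls_loss.data) * cfg.cls_gain,
                 "dfl": float(dfl_loss.data) * cfg.dfl_gain,
                 "n_pos": n_fg}
        return total, comps


def gather_flat(t, idx, width):
    """Row-gather on a (N, width)-viewable tensor."""
    flat = F.reshape(t, (-1, width))
    return F.gather_rows(flat, idx)


def compute_loss(raw_outputs, targets, num_classes, image_size, reg_max=16, cfg=None):
    """Convenience wrapper: loss for one forward pass."""
    return DetectionLoss(num_classes, reg_max, cfg=cfg)(raw_outputs, targets, image_size)


# -- fitting ------------------------------------------------------------------

def _prep_images(samples):
    imgs = np.stack([np.asarray(s, dtype=np.float32) for s in samples])
    if imgs.max() > 1.5:
        imgs /= 255.0
    return imgs.transpose(0, 3, 1, 2)


def _lr_at(cfg, epoch):
    """Linear warmup then cosine decay to final_lr_frac * lr."""
    if cfg.warmup_epochs > 0 and epoch < cfg.warmup_epochs:
        return cfg.learning_rate * (epoch + 1) / cfg.warmup_epochs
    span = max(cfg.epochs - cfg.warmup_epochs, 1)
    t = (epoch - cfg.warmup_epochs) / span
    lo = cfg.final_lr_frac
    return cfg.learning_rate * (lo + (1 - lo) * 0.5 * (1 + math.cos(math.pi * t)))


def evaluate_model(model, dataset, conf_thres=0.25, iou_thres=0.45, batch_size=16):
    """mAP suite of a model over (image, labels) pairs; labels may be
    BoxLabel objects or (class, cx, cy, w, h) rows."""
    model.eval()
    dets, gts = [], []
    n = len(dataset)
    for start in range(0, n, batch_size):
        chunk = dataset[start:start + batch_size]
        imgs = _prep_images([c[0] for c in chunk])
        with no_grad():
            raw = model.forward(Tensor(imgs))
        decoded = decode_predictions(raw, model.spec.num_classes,
                                     model.spec.reg_max, conf_thres=conf_thres)
        for bi, (boxes, scores, classes) in enumerate(decoded):
            img_id = start + bi
            h, w = chunk[bi][0].shape[:2]
            for cid in np.unique(classes):
                m = classes == cid
                for i in nms(boxes[m], scores[m], iou_thres):
                    dets.append((img_id, int(cid), float(scores[m][i]),
                                 tuple(boxes[m][i])))
            for l in chunk[bi][1]:
                row = l.as_tuple() if hasattr(l, "as_tuple") else tuple(l)
                cid, cx, cy, bw, bh = row
                gts.append((img_id, int(cid),
                            ((cx - bw / 2) * w, (cy - bh / 2) * h,
                             (cx + bw / 2) * w, (cy + bh / 2) * h)))
    return map_suite(dets, gts, model.spec.num_classes)


def fit(model: DetectionModel, dataset, cfg: TrainConfig, log_path=None,
        verbose=False):
    """Train ``model`` on (image, labels) pairs; returns the per-epoch log.

    Deterministic for a fixed config seed.  The metric log holds one row per
    evaluated epoch: epoch, loss and components, P, R, mAP50, mAP50:95.
    """
    if len(dataset) == 0:
        raise InputError("empty dataset")
    h, w = np.asarray(dataset[0][0]).shape[:2]
    loss_fn = DetectionLoss(model.spec.num_classes, model.spec.reg_max, cfg=cfg)
    params = model.parameters()
    decay_mask = [p.data.ndim > 1 for p in params]  # norms/biases exempt
    opt = AdamW(params, lr=cfg.learning_rate, betas=(cfg.momentum, 0.999),
                weight_decay=cfg.weight_decay, decay_mask=decay_mask)
    rng = np.random.default_rng(cfg.seed)
    targets_all = [_labels_to_rows(lbls) for _, lbls in dataset]
    images_all = [img for img, _ in dataset]
    log = []
    for epoch in range(cfg.epochs):
        model.train()
        opt.lr = _lr_at(cfg, epoch)
        order = rng.permutation(len(dataset))
        epoch_loss, comps_sum, n_batches = 0.0, {}, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs = _prep_images([images_all[i] for i in idx])
            raw = model.forward(Tensor(imgs))
            loss, comps = loss_fn(raw, [targets_all[i] for i in idx], max(h, w))
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, 10.0)
            opt.step()
            epoch_loss += float(loss.data)
            for k, v in comps.items():
                comps_sum[k] = comps_sum.get(k, 0.0) + v
            n_batches += 1
        row = {"epoch": epoch, "loss": epoch_loss / n_batches,
               "lr": opt.lr}
        for k, v in comps_sum.items():
            row[k] = v / n_batches
        if (epoch + 1) % cfg.eval_interval == 0 or epoch == cfg.epochs - 1:
            rep = evaluate_model(model, dataset)
            row.update(precision=rep.precision, recall=rep.recall,
                       mAP50=rep.map50, mAP50_95=rep.map50_95)
        log.append(row)
        if verbose:
            print({k: (round(v, 4) if isinstance(v, float) else v)
                   for k, v in row.items()}, flush=True)
        if log_path:
            _write_log(log_path, log)
    return log


def _labels_to_rows(labels):
    rows = []
    for l in labels:
        rows.append(l.as_tuple() if hasattr(l, "as_tuple") else tuple(l))
    return np.asarray(rows, dtype=np.float32).reshape(-1, 5)


def _write_log(path, log):
    keys = ["epoch", "loss", "box", "cls", "dfl", "n_pos", "lr",
            "precision", "recall", "mAP50", "mAP50_95"]
    with open(path, "w") as fh:
        fh.write(",".join(keys) + "\n")
        for row in log:
            fh.write(",".join(str(row.get(k, "")) for k in keys) + "\n")
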