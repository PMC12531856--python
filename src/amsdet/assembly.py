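"""Declarative assembly of the YOLOv8n-style baseline and AMS-YOLO.

A model is an ordered list of :class:`LayerSpec` entries forming a DAG
(``from_layers`` reference earlier indices only).  The same table drives
instantiation, the exact parameter audit and the analytic multiply-accumulate
count, so the three can never drift apart.

AMS-YOLO differs from the baseline by three substitution sets:

* the two deepest backbone C2f blocks become C2f_SMCA (spatial self-attention
  at the 160-token-and-under levels plus local/global channel gating attached
  to each bottleneck);
* every stride-2 downsampling Conv after the stem (backbone and neck) becomes
  an AMConv dual-path downsampler;
* the neck C2f blocks producing the P3/P4/P5 outputs become C2f_MSBlock.

The head is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import blocks
from .amconv import AMConv, AMConvConfig
from .errors import ConfigurationError, InputError
from .msblock import make_c2f_msblock
from .nn import F, Module, ModuleList, no_grad
from .smca import make_c2f_smca

KINDS = {"ConvBnAct", "C2f", "C2f_SMCA", "AMConv", "SPPF", "Upsample",
         "Concat", "C2f_MSBlock", "DetectHead"}


@dataclass
class LayerSpec:
    index: int
    kind: str
    from_layers: list
    args: dict = field(default_factory=dict)


@dataclass
class ModelSpec:
    layers: list
    num_classes: int = 13
    depth_multiple: float = 1 / 3
    width_multiple: float = 1 / 4
    max_channels: int = 1024
    reg_max: int = 16

    def validate(self):
        heads = 0
        for layer in self.layers:
            if layer.kind not in KINDS:
                raise ConfigurationError(f"unknown layer kind {layer.kind!r}")
            for src in layer.from_layers:
                if src >= layer.index or src < -1:
                    raise ConfigurationError(
                        f"layer {layer.index} references {src}: not a DAG")
            if layer.kind == "DetectHead":
                heads += 1
                if len(layer.from_layers) != 3:
                    raise ConfigurationError("DetectHead must consume three levels")
        if heads != 1:
            raise ConfigurationError("exactly one DetectHead required")
        self._check_channels()
        return self

    def _check_channels(self):
        out_ch = {-1: 3}
        for layer in self.layers:
            a = layer.args
            if layer.kind == "Concat":
                out_ch[layer.index] = sum(out_ch[s] for s in layer.from_layers)
                continue
            if layer.kind == "Upsample":
                out_ch[layer.index] = out_ch[layer.from_layers[0]]
                continue
            if layer.kind == "DetectHead":
                expect = [out_ch[s] for s in layer.from_layers]
                if a.get("ch") and list(a["ch"]) != expect:
                    raise ConfigurationError("DetectHead channel mismatch")
                continue
            ci = out_ch[layer.from_layers[0]]
            if a["ci"] != ci:
                raise ConfigurationError(
                    f"layer {layer.index} expects {a['ci']} channels, gets {ci}")
            out_ch[layer.index] = a["co"]


def _backbone_neck_table():
    """(kind, from, args) rows for the n-scale baseline; head appended later."""
    L = [
        ("ConvBnAct", [-1], dict(ci=3, co=16, k=3, s=2)),            # 0 stem, P1
        ("ConvBnAct", [-1], dict(ci=16, co=32, k=3, s=2, ds=True)),  # 1 P2
        ("C2f", [-1], dict(ci=32, co=32, n=1, shortcut=True)),       # 2
        ("ConvBnAct", [-1], dict(ci=32, co=64, k=3, s=2, ds=True)),  # 3 P3
        ("C2f", [-1], dict(ci=64, co=64, n=2, shortcut=True)),       # 4
        ("ConvBnAct", [-1], dict(ci=64, co=128, k=3, s=2, ds=True)),  # 5 P4
        ("C2f", [-1], dict(ci=128, co=128, n=2, shortcut=True, deep=True)),  # 6
        ("ConvBnAct", [-1], dict(ci=128, co=256, k=3, s=2, ds=True)),  # 7 P5
        ("C2f", [-1], dict(ci=256, co=256, n=1, shortcut=True, deep=True)),  # 8
        ("SPPF", [-1], dict(ci=256, co=256, k=5)),                    # 9
        ("Upsample", [-1], dict()),                                   # 10
        ("Concat", [-1, 6], dict()),                                  # 11
        ("C2f", [-1], dict(ci=384, co=128, n=1, shortcut=False)),     # 12
        ("Upsample", [-1], dict()),                                   # 13
        ("Concat", [-1, 4], dict()),                                  # 14
        ("C2f", [-1], dict(ci=192, co=64, n=1, shortcut=False, pyramid="P3")),  # 15
        ("ConvBnAct", [-1], dict(ci=64, co=64, k=3, s=2, ds=True)),   # 16
        ("Concat", [-1, 12], dict()),                                 # 17
        ("C2f", [-1], dict(ci=192, co=128, n=1, shortcut=False, pyramid="P4")),  # 18
        ("ConvBnAct", [-1], dict(ci=128, co=128, k=3, s=2, ds=True)),  # 19
        ("Concat", [-1, 9], dict()),                                  # 20
        ("C2f", [-1], dict(ci=384, co=256, n=1, shortcut=False, pyramid="P5")),  # 21
    ]
    return L


def _resolve(rows, num_classes, reg_max):
    layers = []
    for i, (kind, frm, args) in enumerate(rows):
        frm = [i - 1 if f == -1 else f for f in frm]
        layers.append(LayerSpec(i, kind, frm, dict(args)))
    layers.append(LayerSpec(len(rows), "DetectHead", [15, 18, 21],
                            dict(nc=num_classes, reg_max=reg_max, ch=[64, 128, 256])))
    return ModelSpec(layers=layers, num_classes=num_classes, reg_max=reg_max).validate()


def build_baseline(num_classes=13, reg_max=16):
    """Unmodified YOLOv8n-equivalent spec (n-scale multipliers)."""
    if num_classes < 1:
        raise ConfigurationError("num_classes must be >= 1")
    return _resolve(_backbone_neck_table(), num_classes, reg_max)


def build_ams_yolo(num_classes=13, reg_max=16, smca=True, amconv=True, msblock=True):
    """AMS-YOLO spec, or any ablation subset of its three substitutions."""
    if num_classes < 1:
        raise ConfigurationError("num_classes must be >= 1")
    rows = _backbone_neck_table()
    out = []
    for kind, frm, args in rows:
        args = dict(args)
        if smca and kind == "C2f" and args.pop("deep", False):
            kind = "C2f_SMCA"
        else:
            args.pop("deep", None)
        if amconv and kind == "ConvBnAct" and args.pop("ds", False):
            kind = "AMConv"
            args = dict(ci=args["ci"], co=args["co"])
        else:
            args.pop("ds", None)
        if msblock and kind == "C2f" and args.pop("pyramid", None):
            kind = "C2f_MSBlock"
        else:
            args.pop("pyramid", None)
        out.append((kind, frm, args))
    return _resolve(out, num_classes, reg_max)


MODEL_BUILDERS = {
    "baseline": lambda nc: build_baseline(nc),
    "ams": lambda nc: build_ams_yolo(nc),
    "ams_smca_only": lambda nc: build_ams_yolo(nc, smca=True, amconv=False, msblock=False),
    "ams_amconv_only": lambda nc: build_ams_yolo(nc, smca=False, amconv=True, msblock=False),
    "ams_msblock_only": lambda nc: build_ams_yolo(nc, smca=False, amconv=False, msblock=True),
    "ams_amconv_msblock": lambda nc: build_ams_yolo(nc, smca=False, amconv=True, msblock=True),
}


# -- instantiation ------------------------------------------------------------

def _make_layer(rng, spec: LayerSpec):
    a = dict(spec.args)
    a.pop("deep", None)
    a.pop("ds", None)
    a.pop("pyramid", None)
    kind = spec.kind
    if kind == "ConvBnAct":
        return blocks.ConvBnAct(rng, a["ci"], a["co"], a.get("k", 1), a.get("s", 1))
    if kind == "C2f":
        return blocks.C2f(rng, a["ci"], a["co"], a.get("n", 1), a.get("shortcut", False))
    if kind == "C2f_SMCA":
        return make_c2f_smca(rng, a["ci"], a["co"], a.get("n", 1), a.get("shortcut", True))
    if kind == "AMConv":
        return AMConv(rng, AMConvConfig(a["ci"], a["co"]))
    if kind == "SPPF":
        return blocks.SPPF(rng, a["ci"], a["co"], a.get("k", 5))
    if kind == "Upsample":
        return blocks.Upsample()
    if kind == "Concat":
        return blocks.Concat()
    if kind == "C2f_MSBlock":
        return make_c2f_msblock(rng, a["ci"], a["co"], a.get("n", 1))
    if kind == "DetectHead":
        return blocks.Detect(rng, a["nc"], a["ch"], a.get("reg_max", 16))
    raise ConfigurationError(f"unknown layer kind {kind!r}")


class DetectionModel(Module):
    """Executable model built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed=0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers = ModuleList([_make_layer(rng, ls) for ls in spec.layers])
        self.strides = [8, 16, 32]

    def forward(self, x):
        """x: Tensor (B, 3, H, W) with H, W divisible by 32.  Returns the three
        raw per-level maps (B, 4*reg_max + nc, H/s, W/s) for s = 8, 16, 32."""
        cache = {}
        out = None
        for ls, mod in zip(self.spec.layers, self.layers):
            srcs = [x if s == -1 else cache[s] for s in ls.from_layers]
            if ls.kind == "Concat":
                y = mod(srcs)
            elif ls.kind == "DetectHead":
                y = mod(srcs)
            else:
                y = mod(srcs[0])
            cache[ls.index] = y
            out = y
        return out


# -- audits -------------------------------------------------------------------

@dataclass
class ParamAudit:
    total_params: int
    per_layer: list
    total_macs_at_640: int = 0

    def millions(self):
        return round(self.total_params / 1e6, 2)


def count_parameters(spec: ModelSpec, seed=0, model=None) -> ParamAudit:
    """Exact learnable-scalar count by enumerating the instantiated arrays."""
    model = model or DetectionModel(spec, seed=seed)
    per_layer = [(ls.index, m.num_params())
                 for ls, m in zip(spec.layers, model.layers)]
    total = sum(c for _, c in per_layer)
    assert total == model.num_params()
    return ParamAudit(total_params=total, per_layer=per_layer)


def _conv_macs(ci, co, k, ho, wo):
    return k * k * ci * co * ho * wo


def _module_macs(mod, h, w):
    """MACs for one module at spatial input h x w, mirroring its forward.

    Convention: convolutions cost k^2*Cin*Cout*Hout*Wout; attention costs
    N^2*d per head for the score matrix and the same for the weighted value
    sum; norms, activations, pooling and resampling are free.
    """
    from .msblock import MSBlock, InvertedBottleneck
    from .smca import SMCA
    from .nn import Sequential
    if isinstance(mod, blocks.ConvBnAct) or isinstance(mod, blocks.Conv2dRaw):
        ho = (h + 2 * mod.padding - mod.k) // mod.stride + 1
        wo = (w + 2 * mod.padding - mod.k) // mod.stride + 1
        return _conv_macs(mod.ci, mod.co, mod.k, ho, wo), ho, wo
    if isinstance(mod, blocks.Bottleneck):
        m1, _, _ = _module_macs(mod.cv1, h, w)
        m2, _, _ = _module_macs(mod.cv2, h, w)
        return m1 + m2, h, w
    if isinstance(mod, SMCA):
        c = mod.cfg.channels
        n = h * w
        qkv = c * 3 * c * n
        proj = c * c * n
        attn = 2 * n * n * mod.cfg.head_dim * mod.cfg.num_heads
        conv1d = mod.k1d * c * (mod.cfg.local_pool_size ** 2 + 1)
        return qkv + proj + attn + conv1d, h, w
    if isinstance(mod, InvertedBottleneck):
        if mod.k == 1:
            return 0, h, w
        total, _, _ = _module_macs(mod.expand, h, w)
        mid = mod.expand.co
        total += mod.k * mod.k * mid * h * w  # depthwise
        total += _module_macs(mod.compress, h, w)[0]
        return total, h, w
    if isinstance(mod, MSBlock):
        total, _, _ = _module_macs(mod.inconv, h, w)
        for br in mod.branches:
            total += _module_macs(br, h, w)[0]
        total += _module_macs(mod.outconv, h, w)[0]
        return total, h, w
    if isinstance(mod, Sequential):
        total = 0
        for sub in mod:
            m, h, w = _module_macs(sub, h, w)
            total += m
        return total, h, w
    if isinstance(mod, blocks.C2f):
        total, _, _ = _module_macs(mod.cv1, h, w)
        for unit in mod.m:
            total += _module_macs(unit, h, w)[0]
        total += _module_macs(mod.cv2, h, w)[0]
        return total, h, w
    if isinstance(mod, AMConv):
        m_a, ho, wo = _module_macs(mod.conv_a, h, w)
        m_b = _module_macs(mod.conv_b, (h + 1) // 2, (w + 1) // 2)[0]
        return m_a + m_b, ho, wo
    if isinstance(mod, blocks.SPPF):
        total, _, _ = _module_macs(mod.cv1, h, w)
        total += _module_macs(mod.cv2, h, w)[0]
        return total, h, w
    if isinstance(mod, blocks._Branch):
        total, _, _ = _module_macs(mod.a, h, w)
        total += _module_macs(mod.b, h, w)[0]
        total += _module_macs(mod.out, h, w)[0]
        return total, h, w
    if isinstance(mod, blocks.Upsample):
        return 0, h * 2, w * 2
    raise ConfigurationError(f"no MAC rule for {type(mod).__name__}")


def count_macs(spec: ModelSpec, input_hw=(640, 640), seed=0, model=None):
    """Total multiply-accumulates for one forward pass at ``input_hw``."""
    h, w = input_hw
    if h % 32 or w % 32:
        raise InputError("input dims must be divisible by 32")
    model = model or DetectionModel(spec, seed=seed)
    hw = {-1: (h, w)}
    total = 0
    for ls, mod in zip(spec.layers, model.layers):
        if ls.kind == "Concat":
            hw[ls.index] = hw[ls.from_layers[0]]
            continue
        if ls.kind == "DetectHead":
            for src, bb, cb in zip(ls.from_layers, mod.box_branches, mod.cls_branches):
                sh, sw = hw[src]
                total += _module_macs(bb, sh, sw)[0]
                total += _module_macs(cb, sh, sw)[0]
            continue
        sh, sw = hw[ls.from_layers[0]]
        m, oh, ow = _module_macs(mod, sh, sw)
        total += m
        hw[ls.index] = (oh, ow)
    return int(total)


# -- decode / NMS -------------------------------------------------------------

@dataclass
class Detection:
    class_id: int
    confidence: float
    box: tuple  # (x1, y1, x2, y2), absolute pixels


def iou_xyxy(a, b):
    """IoU matrix between (n,4) and (m,4) xyxy boxes."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes, scores, iou_thres=0.45):
    """Greedy NMS; returns kept indices sorted by descending score."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        ious = iou_xyxy(boxes[i:i + 1], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thres]
    return keep


def decode_predictions(raw_levels, num_classes, reg_max=16, strides=(8, 16, 32),
                       conf_thres=0.25):
    """Raw head maps -> per-image (boxes xyxy, scores, classes) before NMS.

    Box decode: softmax over the reg_max distribution bins per side gives the
    expected left/top/right/bottom distances in stride units from the cell
    centre (cx + 0.5, cy + 0.5); class scores are sigmoid logits.
    """
    from .nn import Tensor as _T
    raw_arrays = [r.data if isinstance(r, _T) else np.asarray(r) for r in raw_levels]
    outs = []
    batch = raw_arrays[0].shape[0]
    for b in range(batch):
        boxes, scores, classes = [], [], []
        for arr, stride in zip(raw_arrays, strides):
            _, c, h, w = arr.shape
            box_logits = arr[b, :4 * reg_max].reshape(4, reg_max, h * w)
            z = box_logits - box_logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            dist = (e / e.sum(axis=1, keepdims=True) *
                    np.arange(reg_max, dtype=np.float32)[None, :, None]).sum(axis=1)
            cls_logits = arr[b, 4 * reg_max:4 * reg_max + num_classes].reshape(num_classes, h * w)
            cls_prob = 1.0 / (1.0 + np.exp(-cls_logits))
            gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            cx = (gx.ravel() + 0.5) * stride
            cy = (gy.ravel() + 0.5) * stride
            x1 = cx - dist[0] * stride
            y1 = cy - dist[1] * stride
            x2 = cx + dist[2] * stride
            y2 = cy + dist[3] * stride
            cls_id = cls_prob.argmax(axis=0)
            conf = cls_prob.max(axis=0)
            m = conf >= conf_thres
            boxes.append(np.stack([x1, y1, x2, y2], axis=1)[m])
            scores.append(conf[m])
            classes.append(cls_id[m])
        outs.append((np.concatenate(boxes) if boxes else np.zeros((0, 4)),
                     np.concatenate(scores), np.concatenate(classes)))
    return outs


def detect_forward(model: DetectionModel, image, conf_thres=0.25, iou_thres=0.45,
                   max_det=300):
    """Run inference on one image (H, W, 3) uint8 or float; returns Detections."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InputError("expected an (H, W, 3) image")
    h, w = img.shape[:2]
    if h % 32 or w % 32:
        raise InputError("image dims must be divisible by 32")
    x = img.astype(np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    x = x.transpose(2, 0, 1)[None]
    model.eval()
    with no_grad():
        raw = model.forward(F.Tensor(x))
    nc = model.spec.num_classes
    boxes, scores, classes = decode_predictions(raw, nc, model.spec.reg_max,
                                                conf_thres=conf_thres)[0]
    detections = []
    for cid in np.unique(classes):
        m = classes == cid
        keep = nms(boxes[m], scores[m], iou_thres)
        for i in keep:
            bx = boxes[m][i]
            x1, y1 = float(np.clip(bx[0], 0, w)), float(np.clip(bx[1], 0, h))
            x2, y2 = float(np.clip(bx[2], 0, w)), float(np.clip(bx[3], 0, h))
            if x2 > x1 and y2 > y1:
                detections.append(Detection(int(cid), float(scores[m][i]),
                                            (x1, y1, x2, y2)))
    detections.sort(key=lambda d: -d.confidence)
    return detections[:max_det]


# -- (de)serialisation --------------------------------------------------------

def spec_to_yaml(spec: ModelSpec, path=None):
    doc = {
        "num_classes": spec.num_classes,
        "depth_multiple": spec.depth_multiple,
        "width_multiple": spec.width_multiple,
        "max_channels": spec.max_channels,
        "reg_max": spec.reg_max,
        "layers": [dict(index=l.index, kind=l.kind, from_layers=list(l.from_layers),
                        args=dict(l.args)) for l in spec.layers],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def spec_from_yaml(source):
    doc = yaml.safe_load(source)
    layers = [LayerSpec(d["index"], d["kind"], list(d["from_layers"]), dict(d["args"]))
              for d in doc["layers"]]
    return ModelSpec(layers=layers, num_classes=doc["num_classes"],
                     depth_multiple=doc.get("depth_multiple", 1 / 3),
                     width_multiple=doc.get("width_multiple", 1 / 4),
                     max_channels=doc.get("max_channels", 1024),
                     reg_max=doc.get("reg_max", 16)).validate()


def save_checkpoint(path, model: DetectionModel):
    state = model.state_dict()
    np.savez(path, __spec__=spec_to_yaml(model.spec), **state)


def load_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    spec = spec_from_yaml(str(data["__spec__"]))
    model = DetectionModel(spec)
    state = {k: data[k] for k in data.files if k != "__spec__"}
    model.load_state_dict(state)
    return model
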