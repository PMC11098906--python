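"""The two plaque predictors and their training machinery.

* A two-branch dense encoder--decoder **segmenter** operating on
  Cartesian 128 x 128 x 7 blocks.  Each branch (lipid, calcified) emits an
  independent sigmoid probability map for the center frame and is trained
  with a distance-weighted binary cross entropy: the pixel-wise sample
  weight decays with distance from the lumen center, plus an l2 penalty on
  every convolution kernel.

* A polar-domain angle-interval **detector** operating on 45 x 360 x 7
  polar blocks.  Anchor intervals tile the angle axis only (every proposal
  spans the full radial extent, since angular labels carry no depth), and
  the loss has four terms: foreground/background classification (BCE) and
  angle regression (L1) from the proposal head, plus per-class
  classification (BCE) and refined angle regression (L1).  There is no
  mask head.

Training uses Adam (lr 1e-4 by default, 50 epochs, batch 32) with a
class-balanced batch sampler drawing lipid : calcified : mixed : normal
frames at 3 : 1 : 1 : 5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import angles, geometry, nn
from .labels import (
    CHEMOGRAM_THRESHOLD,
    AngleBox,
    filter_training_frames,
    frame_tissue_class,
    gradient_weight_map,
    profile_to_angle_boxes,
)
from .phantom import PLAQUE_CLASSES, GroundTruth, VesselStack

TISSUE_CLASSES = ("lipid", "calcified", "mixed", "normal")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegModelConfig:
    """Segmenter hyperparameters (desk-scale defaults)."""

    in_depth: int = 7
    image_size: int = 128
    base_channels: int = 8
    growth_rate: int = 4
    dense_block_layers: int = 2
    dropout_rate: float = 0.5  # final encoder layer only
    l2_lambda: float = 1e-5
    n_branches: int = 2
    hu_shift: float = 60.0  # input normalization: (HU - shift) / scale
    hu_scale: float = 400.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be nonnegative")


@dataclass(frozen=True)
class DetModelConfig:
    """Detector hyperparameters."""

    in_shape: tuple[int, int, int] = (45, 360, 7)
    base_channels: int = 8
    anchor_widths_deg: tuple[float, ...] = (20.0, 60.0, 120.0, 240.0, 360.0)
    n_anchor_positions: int = 45
    score_thresholds: dict = field(default_factory=lambda: {"lipid": 0.3, "calcified": 0.5})
    nms_iou: float = 0.3
    match_iou: tuple[float, float] = (0.5, 0.3)  # (positive, negative)
    hu_shift: float = 60.0
    hu_scale: float = 400.0

    def __post_init__(self) -> None:
        if min(self.anchor_widths_deg) < 10.0 or max(self.anchor_widths_deg) > 360.0:
            raise ValueError("anchor widths must span the 10 to 360 degree range")


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 32
    class_batch_ratio: tuple[float, float, float, float] = (3.0, 1.0, 1.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if any(r < 0 for r in self.class_batch_ratio) or sum(self.class_batch_ratio) <= 0:
            raise ValueError("class_batch_ratio entries must be nonnegative with positive sum")


@dataclass
class SegmentationPrediction:
    """Per-branch probability maps for one block's center frame."""

    maps: dict[str, np.ndarray]  # class -> (H, W) in [0, 1]
    frame_index: int


# ---------------------------------------------------------------------------
# Losses (pure-numpy reference forms of the training objectives)
# ---------------------------------------------------------------------------


def _bce_np(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), nn.EPS, 1.0 - nn.EPS)
    t = np.asarray(t, dtype=float)
    return -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))


def weighted_bce_loss(predict, target, weight, kernel_l2: float = 0.0) -> float:
    """Distance-weighted binary cross entropy.

    ``mean(weight * BCE(predict, target)) + kernel_l2`` where ``kernel_l2``
    is the (already reduced) l2 kernel penalty.  ``target`` may be a
    :class:`~plaqueangle.labels.PieMask` or an array; ``weight`` a
    :class:`~plaqueangle.labels.WeightMap` or an array.
    """
    t = getattr(target, "values", target)
    w = getattr(weight, "values", weight)
    p = np.asarray(predict, dtype=float)
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"predict shape {p.shape} != target shape {t.shape}")
    val = float(np.mean(np.broadcast_to(w, p.shape) * _bce_np(p, t)) + kernel_l2)
    if not np.isfinite(val):
        raise FloatingPointError("weighted BCE loss is not finite")
    return val


@dataclass
class DetectionTrainingRecord:
    """Per-anchor operands of the four-term detector loss.

    Probabilities are post-sigmoid; regression values are normalized
    (degrees / 360).  ``valid_mask`` excludes anchors in the ignore zone
    between the negative and positive matching thresholds.
    """

    pred_obj: np.ndarray  # (A,) foreground probability
    target_obj: np.ndarray  # (A,) {0, 1}
    valid_mask: np.ndarray  # (A,) bool
    fg_mask: np.ndarray  # (A,) bool
    pred_reg_bf: np.ndarray  # (A, 2) proposal-stage angle regression
    pred_cls: np.ndarray  # (A, n_classes) class probabilities
    target_cls: np.ndarray  # (A, n_classes) one-hot
    pred_reg: np.ndarray  # (A, 2) refined angle regression
    target_reg: np.ndarray  # (A, 2)


def detector_loss(record: DetectionTrainingRecord) -> tuple[float, dict[str, float]]:
    """Four-term detector loss; returns (total, per-term components).

    ``loss_cls_bf``: BCE of foreground/background over valid anchors.
    ``loss_reg_bf``: mean L1 of proposal angle regression over foreground.
    ``loss_cls``:    BCE of per-class scores over foreground anchors.
    ``loss_reg``:    mean L1 of refined angle regression over foreground.
    With no foreground anchors the regression and class terms are zero.
    """
    valid = record.valid_mask.astype(bool)
    fg = record.fg_mask.astype(bool)
    comp = {
        "loss_cls_bf": float(_bce_np(record.pred_obj[valid], record.target_obj[valid]).mean())
        if valid.any()
        else 0.0,
        "loss_reg_bf": float(np.abs(record.pred_reg_bf[fg] - record.target_reg[fg]).mean())
        if fg.any()
        else 0.0,
        "loss_cls": float(_bce_np(record.pred_cls[fg], record.target_cls[fg]).mean())
        if fg.any()
        else 0.0,
        "loss_reg": float(np.abs(record.pred_reg[fg] - record.target_reg[fg]).mean())
        if fg.any()
        else 0.0,
    }
    return sum(comp.values()), comp


# ---------------------------------------------------------------------------
# Anchors, matching, NMS
# ---------------------------------------------------------------------------


def make_anchors(config: DetModelConfig) -> list[tuple[float, float]]:
    """Anchor intervals ``(center_deg, width_deg)`` tiling the angle axis:
    ``n_anchor_positions`` evenly spaced centers, one anchor per width."""
    step = 360.0 / config.n_anchor_positions
    return [
        ((i + 0.5) * step, w)
        for i in range(config.n_anchor_positions)
        for w in config.anchor_widths_deg
    ]


def _interval_of(center: float, width: float) -> tuple[float, float]:
    if width >= 360.0:
        return (0.0, 360.0)
    start = (center - width / 2.0) % 360.0
    end = (start + width) % 360.0
    return (start, end if end > 0 or width == 0 else 360.0)


def angle_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Circular IoU of two ``(start, end)`` angular intervals."""
    return angles.circular_iou(a, b)


@dataclass
class AnchorMatches:
    """Result of matching anchors against ground-truth angle boxes."""

    fg_mask: np.ndarray  # (A,) anchor is positive
    valid_mask: np.ndarray  # (A,) anchor contributes to fg/bg loss
    matched_gt: np.ndarray  # (A,) index into gt list, -1 if unmatched
    ious: np.ndarray  # (A,) best IoU per anchor


def match_anchors(
    anchors: Sequence[tuple[float, float]],
    gt_boxes: Sequence[AngleBox],
    iou_thresholds: tuple[float, float] = (0.5, 0.3),
) -> AnchorMatches:
    """Wrap-aware 1-D anchor matching.

    Anchors with best IoU at or above the positive threshold become
    foreground and take their best ground-truth box; anchors below the
    negative threshold are background; the zone between is ignored.  Every
    ground-truth box additionally claims its best-IoU anchor, so no target
    goes unmatched.
    """
    pos_thr, neg_thr = iou_thresholds
    a = len(anchors)
    fg = np.zeros(a, dtype=bool)
    matched = np.full(a, -1, dtype=int)
    best_iou = np.zeros(a)
    if gt_boxes:
        iou = np.array(
            [
                [angle_iou(_interval_of(c, w), g.interval) for g in gt_boxes]
                for (c, w) in anchors
            ]
        )  # (A, G)
        best_gt = iou.argmax(axis=1)
        best_iou = iou.max(axis=1)
        fg = best_iou >= pos_thr
        matched[fg] = best_gt[fg]
        for g in range(len(gt_boxes)):
            i = int(iou[:, g].argmax())
            fg[i] = True
            matched[i] = g
            best_iou[i] = iou[i, g]
    valid = fg | (best_iou < neg_thr)
    return AnchorMatches(fg_mask=fg, valid_mask=valid, matched_gt=matched, ious=best_iou)


def nms_1d(boxes: Sequence[AngleBox], iou_threshold: float = 0.3) -> list[AngleBox]:
    """Greedy circular non-maximum suppression of angle boxes.

    Boxes suppress each other only within the same plaque class.  Order is
    descending score, ties broken by wider box then lower start angle.
    """
    order = sorted(
        boxes, key=lambda b: (-b.score, -b.width_deg, b.start_angle_deg % 360.0)
    )
    kept: list[AngleBox] = []
    for b in order:
        if all(
            b.plaque_class != k.plaque_class or angle_iou(b.interval, k.interval) <= iou_threshold
            for k in kept
        ):
            kept.append(b)
    return kept


# ---------------------------------------------------------------------------
# Balanced batch sampling
# ---------------------------------------------------------------------------


def balanced_batch_sampler(
    frame_classes: Sequence[str],
    ratio: Sequence[float] = (3.0, 1.0, 1.0, 5.0),
    batch_size: int = 32,
    seed: int = 0,
    n_batches: int | None = None,
):
    """Yield batches of frame indices with expected class proportions
    ``ratio`` over ``(lipid, calcified, mixed, normal)``.

    Each batch slot draws a tissue class with probability proportional to
    its ratio entry (i.i.d. with replacement), then a uniform frame of
    that class.  Classes absent from the data are dropped and the ratio
    renormalized (with a warning).  Deterministic for a fixed seed.
    """
    frame_classes = list(frame_classes)
    if not frame_classes:
        raise ValueError("empty dataset")
    by_class = {c: np.flatnonzero([fc == c for fc in frame_classes]) for c in TISSUE_CLASSES}
    probs = np.asarray(ratio, dtype=float)
    present = np.array([len(by_class[c]) > 0 and probs[i] > 0 for i, c in enumerate(TISSUE_CLASSES)])
    if not present.any():
        raise ValueError("no samples in any class with positive ratio")
    if (~present & (probs > 0)).any():
        missing = [c for i, c in enumerate(TISSUE_CLASSES) if probs[i] > 0 and not present[i]]
        warnings.warn(f"classes {missing} absent; renormalizing batch ratio", stacklevel=2)
    probs = np.where(present, probs, 0.0)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    produced = 0
    while n_batches is None or produced < n_batches:
        cls_draw = rng.choice(len(TISSUE_CLASSES), size=batch_size, p=probs)
        batch = np.array(
            [by_class[TISSUE_CLASSES[c]][rng.integers(len(by_class[TISSUE_CLASSES[c]]))] for c in cls_draw]
        )
        yield batch
        produced += 1


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


class _DenseBlock:
    """DenseNet-style block: each 3x3 conv sees the concatenation of the
    block input and all previous layer outputs; output keeps them all."""

    def __init__(self, cin: int, growth: int, n_layers: int, rng: np.random.Generator):
        self.convs = [
            nn.Conv2dLayer(cin + i * growth, growth, 3, rng) for i in range(n_layers)
        ]
        self.out_channels = cin + n_layers * growth

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        feats = [x]
        for conv in self.convs:
            inp = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
            feats.append(nn.relu(conv(inp)))
        return nn.concat(feats, axis=1)

    @property
    def params(self) -> list[nn.Tensor]:
        return [p for c in self.convs for p in c.params]


class DenseUNet:
    """Two-branch dense encoder--decoder for pie-mask segmentation.

    Encoder: full-resolution stem conv, then dense blocks at 1/2, 1/4 and
    1/8 resolution with dropout on the bottleneck output (the final
    encoder layer).  Decoder: two nearest-upsample + skip-concatenation +
    conv stages back to 1/2 resolution.  Head: 1x1 conv upsampled to full
    resolution with ``n_branches`` independent sigmoid channels (channel 0
    lipid, channel 1 calcified) — sigmoid rather than softmax because the
    tissues co-occur on mixed frames.  Keeping the dense blocks off the
    full-resolution grid is what makes CPU training of the phantom-scale
    model practical; angular labels are insensitive to the residual 2-px
    blockiness.
    """

    branch_order = PLAQUE_CLASSES

    def __init__(self, config: SegModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c, g, nl = config.base_channels, config.growth_rate, config.dense_block_layers
        self.stem = nn.Conv2dLayer(config.in_depth, c, 3, rng)
        self.db1 = _DenseBlock(c, g, nl, rng)
        self.db2 = _DenseBlock(self.db1.out_channels, g, nl, rng)
        self.db3 = _DenseBlock(self.db2.out_channels, g, nl, rng)
        self.up2 = nn.Conv2dLayer(self.db3.out_channels + self.db2.out_channels, self.db2.out_channels, 3, rng)
        self.up1 = nn.Conv2dLayer(self.db2.out_channels + self.db1.out_channels, c, 3, rng)
        self.head = nn.Conv2dLayer(c, config.n_branches, 1, rng)
        self._out_stride = 2  # head operates at 1/2 resolution
        self._layers = [self.stem, self.db1, self.db2, self.db3, self.up2, self.up1, self.head]

    @property
    def params(self) -> list[nn.Tensor]:
        return [p for layer in self._layers for p in layer.params]

    def kernel_sq_norm(self) -> nn.Tensor:
        """Sum of squared convolution-kernel entries (the l2 penalty)."""
        total = None
        for layer in self._layers:
            convs = layer.convs if isinstance(layer, _DenseBlock) else [layer]
            for c in convs:
                s = nn.tsum(nn.square(c.w))
                total = s if total is None else total + s
        return total

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> nn.Tensor:
        """(N, 7, H, W) HU block -> (N, n_branches, H, W) probabilities."""
        if x.ndim != 4 or x.shape[1] != self.config.in_depth:
            raise ValueError(f"expected (N, {self.config.in_depth}, H, W), got {x.shape}")
        t = nn.Tensor((np.asarray(x, dtype=nn.DTYPE) - self.config.hu_shift) / self.config.hu_scale)
        s = nn.relu(self.stem(t))
        e1 = self.db1(nn.avgpool2d(s, (2, 2)))  # 1/2 res
        e2 = self.db2(nn.avgpool2d(e1, (2, 2)))  # 1/4 res
        b = self.db3(nn.avgpool2d(e2, (2, 2)))  # 1/8 res
        if training:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            b = nn.dropout(b, self.config.dropout_rate, rng, training=True)
        d2 = nn.relu(self.up2(nn.concat([nn.upsample2d(b, (2, 2)), e2], axis=1)))
        d1 = nn.relu(self.up1(nn.concat([nn.upsample2d(d2, (2, 2)), e1], axis=1)))
        return nn.sigmoid(nn.upsample2d(self.head(d1), (2, 2)))

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(self.params)})
        (path / "config.json").write_text(json.dumps({"kind": "segmenter", **self.config.__dict__}))

    @classmethod
    def load(cls, path: str | Path) -> "DenseUNet":
        path = Path(path)
        cfg = json.loads((path / "config.json").read_text())
        cfg.pop("kind", None)
        model = cls(SegModelConfig(**cfg))
        with np.load(path / "weights.npz") as z:
            for i, p in enumerate(model.params):
                p.data = z[f"p{i}"]
        return model


class AngleDetector:
    """Polar-domain angle-interval detector.

    A small convolutional backbone over the (radius, angle) plane is
    collapsed along the radial axis (anchors carry no depth), leaving a
    1-D feature map over angle.  Two 1x1-conv heads follow: a *proposal*
    head with a foreground/background logit and a coarse angle regression
    per anchor, and a *refinement* head with per-class logits and a
    refined angle regression.  No mask head exists.

    Angle regression is normalized: targets are
    ``(circular center offset / 360, width offset / 360)`` relative to the
    anchor.
    """

    heads = ("classification", "angle_regression")  # no mask head

    def __init__(self, config: DetModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        nw = len(config.anchor_widths_deg)
        self.conv1 = nn.Conv2dLayer(config.in_shape[2], c, 3, rng)
        self.conv2 = nn.Conv2dLayer(c, 2 * c, 3, rng)
        self.conv3 = nn.Conv2dLayer(2 * c, 2 * c, 3, rng)
        self.conv4 = nn.Conv2dLayer(2 * c, 4 * c, 3, rng)
        self.proposal_head = nn.Conv2dLayer(4 * c, nw * 3, 1, rng)
        self.refine_head = nn.Conv2dLayer(4 * c, nw * (len(PLAQUE_CLASSES) + 2), 1, rng)
        self._layers = [self.conv1, self.conv2, self.conv3, self.conv4, self.proposal_head, self.refine_head]
        self.anchors = make_anchors(config)

    @property
    def params(self) -> list[nn.Tensor]:
        return [p for layer in self._layers for p in layer.params]

    def forward(self, x: np.ndarray) -> dict[str, nn.Tensor]:
        """(N, 7, 45, 360) polar HU block -> per-anchor output tensors.

        Returns ``obj`` (N, A) fg/bg probability, ``reg_bf`` (N, A, 2),
        ``cls`` (N, A, n_classes) probabilities, ``reg`` (N, A, 2); anchor
        index runs position-major then width.
        """
        n_r, n_a, depth = self.config.in_shape
        if x.ndim != 4 or x.shape[1:] != (depth, n_r, n_a):
            raise ValueError(f"expected (N, {depth}, {n_r}, {n_a}), got {x.shape}")
        nw = len(self.config.anchor_widths_deg)
        npos = self.config.n_anchor_positions
        t = nn.Tensor((np.asarray(x, dtype=nn.DTYPE) - self.config.hu_shift) / self.config.hu_scale)
        h = nn.avgpool2d(nn.relu(self.conv1(t)), (1, 2))  # (45, 180)
        h = nn.avgpool2d(nn.relu(self.conv2(h)), (3, 2))  # (15, 90)
        h = nn.avgpool2d(nn.relu(self.conv3(h)), (3, 2))  # (5, 45)
        h = nn.relu(self.conv4(h))
        h = nn.tmean(h, axis=2, keepdims=True)  # collapse radius -> (N, C, 1, 45)
        n = x.shape[0]
        prop = reshape_head(self.proposal_head(h), n, npos, nw, 3)
        refn = reshape_head(self.refine_head(h), n, npos, nw, len(PLAQUE_CLASSES) + 2)
        return {
            "obj": nn.sigmoid(reshape_last(prop, 0)),
            "reg_bf": slice_last(prop, 1, 3),
            "cls": nn.sigmoid(slice_last(refn, 0, len(PLAQUE_CLASSES))),
            "reg": slice_last(refn, len(PLAQUE_CLASSES), len(PLAQUE_CLASSES) + 2),
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(self.params)})
        cfg = dict(self.config.__dict__)
        cfg["kind"] = "detector"
        (path / "config.json").write_text(json.dumps(cfg))

    @classmethod
    def load(cls, path: str | Path) -> "AngleDetector":
        path = Path(path)
        cfg = json.loads((path / "config.json").read_text())
        cfg.pop("kind", None)
        cfg["in_shape"] = tuple(cfg["in_shape"])
        cfg["anchor_widths_deg"] = tuple(cfg["anchor_widths_deg"])
        cfg["match_iou"] = tuple(cfg["match_iou"])
        model = cls(DetModelConfig(**cfg))
        with np.load(path / "weights.npz") as z:
            for i, p in enumerate(model.params):
                p.data = z[f"p{i}"]
        return model


def reshape_head(h: nn.Tensor, n: int, npos: int, nw: int, per_anchor: int) -> nn.Tensor:
    """(N, nw*per_anchor, 1, npos) head output -> (N, npos*nw, per_anchor)."""
    t = nn.reshape(h, (n, nw, per_anchor, npos))
    # to (N, npos, nw, per_anchor): transpose via reshape trickery is not
    # supported by the engine, so move axes with matmul-free gather:
    return _moveaxes(t, (0, 3, 1, 2), (n, npos, nw, per_anchor), flatten_mid=True)


def _moveaxes(t: nn.Tensor, order: tuple[int, ...], out_shape: tuple[int, ...], flatten_mid: bool) -> nn.Tensor:
    data = np.transpose(t.data, order)
    out = nn.Tensor(data, requires_grad=t.requires_grad)
    if out.requires_grad:
        out._parents = (t,)
        inv = np.argsort(order)

        def bwd(g):
            t._accumulate(np.transpose(g, inv))

        out._backward = bwd
    if flatten_mid:
        n, npos, nw, pa = out_shape
        out = nn.reshape(out, (n, npos * nw, pa))
    return out


def reshape_last(t: nn.Tensor, idx: int) -> nn.Tensor:
    return slice_last(t, idx, idx + 1, squeeze=True)


def slice_last(t: nn.Tensor, lo: int, hi: int, squeeze: bool = False) -> nn.Tensor:
    data = t.data[..., lo:hi]
    out = nn.Tensor(data, requires_grad=t.requires_grad)
    if out.requires_grad:
        out._parents = (t,)

        def bwd(g):
            full = np.zeros_like(t.data)
            full[..., lo:hi] = g.reshape(data.shape)
            t._accumulate(full)

        out._backward = bwd
    if squeeze:
        out = nn.reshape(out, data.shape[:-1])
    return out


# ---------------------------------------------------------------------------
# Training harness
# ---------------------------------------------------------------------------


def _signed_circular_diff(a: float, b: float) -> float:
    """Signed smallest rotation taking ``b`` to ``a``, in (-180, 180]."""
    return (a - b + 180.0) % 360.0 - 180.0


def regression_targets(
    anchors: Sequence[tuple[float, float]], matches: AnchorMatches, gt_boxes: Sequence[AngleBox]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor normalized regression and one-hot class targets."""
    a = len(anchors)
    reg = np.zeros((a, 2))
    cls = np.zeros((a, len(PLAQUE_CLASSES)))
    for i in np.flatnonzero(matches.fg_mask):
        g = gt_boxes[matches.matched_gt[i]]
        ac, aw = anchors[i]
        g_w = g.width_deg
        g_c = (g.start_angle_deg + g_w / 2.0) % 360.0
        reg[i, 0] = _signed_circular_diff(g_c, ac) / 360.0
        reg[i, 1] = (g_w - aw) / 360.0
        cls[i, PLAQUE_CLASSES.index(g.plaque_class)] = 1.0
    return reg, cls


def _masked_mean(t: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
    m = np.asarray(mask, dtype=float)
    count = m.sum()
    if count == 0:
        return nn.Tensor(0.0)
    return nn.tsum(t * nn.Tensor(m)) / count


def _detector_loss_tensor(out: dict[str, nn.Tensor], targets: dict[str, np.ndarray]) -> nn.Tensor:
    """Autograd form of the four-term loss; mirrors :func:`detector_loss`."""
    fg = targets["fg_mask"].astype(float)
    valid = targets["valid_mask"].astype(float)
    fg2 = np.repeat(fg[..., None], 2, axis=-1)
    fgc = np.repeat(fg[..., None], len(PLAQUE_CLASSES), axis=-1)
    loss = _masked_mean(nn.bce(out["obj"], targets["target_obj"]), valid)
    loss = loss + _masked_mean(nn.absolute(out["reg_bf"] - nn.Tensor(targets["target_reg"])), fg2)
    loss = loss + _masked_mean(nn.bce(out["cls"], targets["target_cls"]), fgc)
    loss = loss + _masked_mean(nn.absolute(out["reg"] - nn.Tensor(targets["target_reg"])), fg2)
    return loss


def _check_finite(loss: float, step: int, context: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(f"{context}: non-finite loss {loss} at step {step}; aborting")


def prepare_segmentation_data(
    stack: VesselStack,
    ground_truth: GroundTruth,
    config: SegModelConfig,
    threshold: float = CHEMOGRAM_THRESHOLD,
    max_radius_mm: float = geometry.DEFAULT_RADIAL_EXTENT_MM,
) -> dict:
    """Precompute Cartesian blocks, binary angular labels and the shared
    weight map for segmenter training on one stack."""
    size = config.image_size
    frames = sorted(filter_training_frames(ground_truth, "segmentation"))
    blocks = np.stack(
        [
            geometry.build_block(stack, f, "cartesian", block_size=size).values.transpose(2, 0, 1)
            for f in frames
        ]
    )
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    bins = angles.pixel_angle_bins((size, size), center)
    r_mm = angles.pixel_radii((size, size), center) * stack.pixel_spacing_mm
    in_disc = r_mm <= max_radius_mm
    occ = np.stack(
        [
            np.stack([np.asarray(ground_truth[cls][f].values) > threshold for cls in PLAQUE_CLASSES])
            for f in frames
        ]
    )  # (F, n_classes, 360) binary
    classes = [frame_tissue_class(ground_truth, f, threshold) for f in frames]
    weight = gradient_weight_map((size, size), center, w_max=10.0, d0_px=size / 8.0).values
    return {
        "frames": frames,
        "blocks": blocks,
        "occupancy": occ,
        "classes": classes,
        "bins": bins,
        "in_disc": in_disc,
        "weight": weight,
    }


def _rasterize_occupancy(occ: np.ndarray, bins: np.ndarray, in_disc: np.ndarray) -> np.ndarray:
    """(n_classes, 360) binary occupancy -> (n_classes, H, W) pie masks."""
    return occ[:, bins] & in_disc


def train_segmenter(
    stack: VesselStack,
    ground_truth: GroundTruth,
    seg_config: SegModelConfig | None = None,
    train_config: TrainConfig | None = None,
    augment: bool = True,
    threshold: float = CHEMOGRAM_THRESHOLD,
) -> tuple[DenseUNet, list[float]]:
    """Train the dense U-Net segmenter on a stack with angular labels.

    Labels are pie masks rasterized from the thresholded profiles in the
    lumen-centered 128-window; the loss is the distance-weighted BCE plus
    the l2 kernel penalty.  Batches are class-balanced at 3:1:1:5 and each
    sample may be rotated by a random integer angle (labels roll exactly).
    Returns the model and the per-epoch mean loss curve.
    """
    seg_config = seg_config or SegModelConfig()
    train_config = train_config or TrainConfig()
    data = prepare_segmentation_data(stack, ground_truth, seg_config, threshold)
    model = DenseUNet(seg_config, seed=train_config.seed)
    opt = nn.Adam(model.params, lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed + 1)
    n = len(data["frames"])
    steps_per_epoch = max(1, int(np.ceil(n / train_config.batch_size)))
    sampler = balanced_batch_sampler(
        data["classes"],
        ratio=train_config.class_batch_ratio,
        batch_size=train_config.batch_size,
        seed=train_config.seed + 2,
    )
    weight = data["weight"]
    curve: list[float] = []
    step = 0
    for _epoch in range(train_config.epochs):
        epoch_losses = []
        for _ in range(steps_per_epoch):
            idx = next(sampler)
            xs, ts = [], []
            for i in idx:
                block = data["blocks"][i]
                occ = data["occupancy"][i]
                if augment:
                    ang = int(rng.integers(0, 360))
                    if ang:
                        block = np.stack(
                            [geometry.rotate_frame(block[k], ang) for k in range(block.shape[0])]
                        )
                        occ = np.roll(occ, ang, axis=1)
                xs.append(block)
                ts.append(_rasterize_occupancy(occ, data["bins"], data["in_disc"]))
            x = np.stack(xs)
            t = np.stack(ts).astype(float)
            pred = model.forward(x, training=True, rng=rng)
            loss = nn.tsum(nn.bce(pred, t) * nn.Tensor(weight)) / t.size
            if seg_config.l2_lambda > 0:
                loss = loss + model.kernel_sq_norm() * seg_config.l2_lambda
            _check_finite(loss.item(), step, "train_segmenter")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            step += 1
        curve.append(float(np.mean(epoch_losses)))
    return model, curve


def predict_segmenter(model: DenseUNet, block: geometry.Block25D) -> SegmentationPrediction:
    """Per-branch probability maps for a Cartesian block's center frame."""
    if block.domain != "cartesian":
        raise ValueError("segmenter expects a Cartesian block")
    x = block.values.transpose(2, 0, 1)[None]
    out = model.forward(x, training=False).data[0]
    maps = {cls: out[i] for i, cls in enumerate(model.branch_order)}
    return SegmentationPrediction(maps=maps, frame_index=block.center_frame_index)


def prepare_detection_data(
    stack: VesselStack,
    ground_truth: GroundTruth,
    config: DetModelConfig,
    threshold: float = CHEMOGRAM_THRESHOLD,
) -> dict:
    """Polar blocks, ground-truth boxes and anchor targets for detector
    training (detection-mode frame filter applied)."""
    frames = sorted(filter_training_frames(ground_truth, "detection", threshold))
    n_r, n_a, _ = config.in_shape
    blocks = np.stack(
        [
            geometry.build_block(stack, f, "polar", n_radius=n_r, n_angle=n_a).values.transpose(2, 0, 1)
            for f in frames
        ]
    )
    anchors = make_anchors(config)
    targets = []
    for f in frames:
        gt_boxes = [
            b
            for cls in PLAQUE_CLASSES
            for b in profile_to_angle_boxes(ground_truth[cls][f], threshold)
        ]
        gt_boxes = [
            AngleBox(b.plaque_class, b.start_angle_deg, b.end_angle_deg, 1.0, b.frame_index)
            for b in gt_boxes
        ]
        m = match_anchors(anchors, gt_boxes, config.match_iou)
        reg, cls = regression_targets(anchors, m, gt_boxes)
        targets.append(
            {
                "target_obj": m.fg_mask.astype(float),
                "fg_mask": m.fg_mask,
                "valid_mask": m.valid_mask,
                "target_reg": reg,
                "target_cls": cls,
            }
        )
    classes = [frame_tissue_class(ground_truth, f, threshold) for f in frames]
    return {"frames": frames, "blocks": blocks, "targets": targets, "classes": classes}


def train_detector(
    stack: VesselStack,
    ground_truth: GroundTruth,
    det_config: DetModelConfig | None = None,
    train_config: TrainConfig | None = None,
    threshold: float = CHEMOGRAM_THRESHOLD,
) -> tuple[AngleDetector, list[float]]:
    """Train the polar angle-interval detector; returns (model, per-epoch
    mean loss curve)."""
    det_config = det_config or DetModelConfig()
    train_config = train_config or TrainConfig()
    data = prepare_detection_data(stack, ground_truth, det_config, threshold)
    if not data["frames"]:
        raise ValueError("no frames survive the detection-mode filter")
    model = AngleDetector(det_config, seed=train_config.seed)
    opt = nn.Adam(model.params, lr=train_config.learning_rate)
    n = len(data["frames"])
    steps_per_epoch = max(1, int(np.ceil(n / train_config.batch_size)))
    sampler = balanced_batch_sampler(
        data["classes"],
        ratio=train_config.class_batch_ratio,
        batch_size=train_config.batch_size,
        seed=train_config.seed + 3,
    )
    curve: list[float] = []
    step = 0
    for _epoch in range(train_config.epochs):
        epoch_losses = []
        for _ in range(steps_per_epoch):
            idx = next(sampler)
            x = data["blocks"][idx]
            tgt = {
                key: np.stack([data["targets"][i][key] for i in idx])
                for key in ("target_obj", "fg_mask", "valid_mask", "target_reg", "target_cls")
            }
            out = model.forward(x)
            loss = _detector_loss_tensor(out, tgt)
            _check_finite(loss.item(), step, "train_detector")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            step += 1
        curve.append(float(np.mean(epoch_losses)))
    return model, curve


def predict_detector(
    model: AngleDetector,
    block: geometry.Block25D,
    score_thresholds: dict[str, float] | None = None,
    nms_iou: float | None = None,
) -> list[AngleBox]:
    """Decode, threshold and NMS-filter detector output for one polar block.

    A box's score for a class is (foreground probability) x (class
    probability); boxes below the per-class score threshold are dropped,
    the survivors pass through circular NMS.
    """
    if block.domain != "polar":
        raise ValueError("detector expects a polar block")
    thresholds = score_thresholds or model.config.score_thresholds
    nms_thr = model.config.nms_iou if nms_iou is None else nms_iou
    out = model.forward(block.values.transpose(2, 0, 1)[None])
    obj = out["obj"].data[0]
    cls = out["cls"].data[0]
    reg = out["reg"].data[0]
    boxes: list[AngleBox] = []
    for i, (ac, aw) in enumerate(model.anchors):
        center = (ac + reg[i, 0] * 360.0) % 360.0
        width = float(np.clip(aw + reg[i, 1] * 360.0, 1.0, 360.0))
        start, end = _interval_of(center, width)
        for ci, cname in enumerate(PLAQUE_CLASSES):
            score = float(obj[i] * cls[i, ci])
            if score >= thresholds[cname]:
                boxes.append(
                    AngleBox(cname, start, end, min(score, 1.0), block.center_frame_index)
                )
    return nms_1d(boxes, nms_thr)
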