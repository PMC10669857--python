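"""Detector building blocks as self-contained array operations.

The improved feature pyramid fuses a 4-level backbone pyramid C2..C5
(spatial size halving per level) into maps with a shared channel count:

* lateral 1x1 projections bring every level to ``fused_channels``;
* squeeze-excitation channel attention reweights C5 before the top-down
  pass (global average pool -> bottleneck -> sigmoid gate per channel);
* the top-down pathway upsamples bilinearly by 2x and adds element-wise
  down to C2, producing T2..T5;
* an extra high-resolution map P0 = L2 + up2(L3) + up4(L4) + up8(L5')
  aggregates every level at C2 resolution (L5' carries the attention gate);
* a bottom-up path-enhancement pass (stride-2 3x3 conv + add) feeds
  shallow position information back into the deeper maps, yielding the
  final P2..P5.

Everything operates on (channels, height, width) numpy arrays with
deterministic, seed-initialised weights; a 4-stage toy backbone and a
linear box-refinement head are provided so a full detector round
(features -> boxes -> GIoU loss -> one gradient step) runs on a desk CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import giou_loss

__all__ = [
    "FeatureMapSet",
    "bilinear_upsample",
    "ChannelAttention",
    "ImprovedFPN",
    "ToyBackbone",
    "BoxRefinementHead",
    "refinement_step",
]


@dataclass
class FeatureMapSet:
    """Backbone pyramid C2..C5 and (after fusion) outputs P0, P2..P5."""

    C2: np.ndarray
    C3: np.ndarray
    C4: np.ndarray
    C5: np.ndarray
    P0: np.ndarray | None = None
    P2: np.ndarray | None = None
    P3: np.ndarray | None = None
    P4: np.ndarray | None = None
    P5: np.ndarray | None = None

    def __post_init__(self) -> None:
        h2, w2 = self.C2.shape[-2:]
        for k, c in enumerate((self.C3, self.C4, self.C5), start=1):
            expect = (h2 // 2**k, w2 // 2**k)
            if c.shape[-2:] != expect:
                raise ValueError(
                    f"pyramid geometry broken: C{k + 2} has spatial {c.shape[-2:]}, "
                    f"expected {expect}"
                )

    @property
    def levels(self) -> tuple[np.ndarray, ...]:
        return (self.C2, self.C3, self.C4, self.C5)


def bilinear_upsample(feature: np.ndarray, factor: int) -> np.ndarray:
    """Upsample the spatial dimensions by an integer factor.

    Corner-aligned bilinear interpolation: each output sample is the
    four-point weighted average of its surrounding input grid points, so a
    factor of 1 is the identity and a constant map stays constant.
    """
    if factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    feature = np.asarray(feature, dtype=float)
    if factor == 1:
        return feature.copy()
    h, w = feature.shape[-2:]
    out_h, out_w = h * factor, w * factor
    ys = np.linspace(0.0, h - 1.0, out_h) if h > 1 else np.zeros(out_h)
    xs = np.linspace(0.0, w - 1.0, out_w) if w > 1 else np.zeros(out_w)
    return bilinear_sample(feature, xs, ys)


def bilinear_sample(feature: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Sample a (…, H, W) array on the grid ``ys x xs`` (pixel coordinates).

    The value at (x, y) between grid points (x1, y1), (x2, y2) is the
    area-weighted average of the four neighbours — the standard bilinear
    form f(x,y) = sum_ij f(xi, yj) * wx_i * wy_j.
    """
    feature = np.asarray(feature, dtype=float)
    h, w = feature.shape[-2:]
    y0 = np.clip(np.floor(ys).astype(int), 0, max(h - 2, 0))
    x0 = np.clip(np.floor(xs).astype(int), 0, max(w - 2, 0))
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = (ys - y0)[..., :, None]
    wx = (xs - x0)[..., None, :]
    f00 = feature[..., y0[:, None], x0[None, :]]
    f01 = feature[..., y0[:, None], x1[None, :]]
    f10 = feature[..., y1[:, None], x0[None, :]]
    f11 = feature[..., y1[:, None], x1[None, :]]
    return (
        f00 * (1 - wy) * (1 - wx)
        + f01 * (1 - wy) * wx
        + f10 * wy * (1 - wx)
        + f11 * wy * wx
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class ChannelAttention:
    """Squeeze-excitation channel gate.

    Per-channel descriptors from global average pooling pass through a
    two-layer bottleneck (reduction ratio ``reduction``) and a sigmoid,
    giving one weight in (0, 1) per channel; the input is rescaled
    channel-wise by these weights.
    """

    def __init__(self, channels: int, reduction: int = 16, seed: int = 0):
        if channels < 1:
            raise ValueError("need at least one channel")
        hidden = max(channels // max(reduction, 1), 1)
        rng = np.random.default_rng(seed)
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / channels), size=(hidden, channels))
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=(channels, hidden))
        self.channels = channels

    def weights(self, feature: np.ndarray) -> np.ndarray:
        if feature.shape[0] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {feature.shape[0]}"
            )
        z = feature.mean(axis=(-2, -1))  # squeeze
        h = np.maximum(self.w1 @ z, 0.0)  # excite: bottleneck + ReLU
        return _sigmoid(self.w2 @ h)

    def __call__(self, feature: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = self.weights(feature)
        return s, feature * s[:, None, None]


def conv2d(x: np.ndarray, weight: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """Plain 2-D cross-correlation: (C_in,H,W) x (C_out,C_in,kh,kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    c_out, c_in, kh, kw = weight.shape
    windows = np.lib.stride_tricks.sliding_window_view(x, (c_in, kh, kw))[0]
    windows = windows[::stride, ::stride]
    return np.einsum("hwcij,ocij->ohw", windows, weight)


class ImprovedFPN:
    """Attention-augmented feature pyramid with a path-enhancement pass.

    Parameters are seed-initialised linear maps (no bias), so all fusion
    arithmetic is exactly linear in the inputs when attention is bypassed.
    ``attention='c5'`` (default) gates only the deepest level before the
    top-down pass; ``'all'`` gates every lateral; ``'none'`` bypasses
    gating entirely.
    """

    def __init__(
        self,
        in_channels: tuple[int, int, int, int],
        fused_channels: int = 32,
        attention: str = "c5",
        attention_reduction: int = 16,
        use_p0: bool = True,
        seed: int = 0,
    ):
        if attention not in ("c5", "all", "none"):
            raise ValueError("attention must be 'c5', 'all' or 'none'")
        rng = np.random.default_rng(seed)
        self.laterals = [
            rng.normal(0.0, np.sqrt(1.0 / c), size=(fused_channels, c))
            for c in in_channels
        ]
        self.attention_mode = attention
        self.attn = [
            ChannelAttention(fused_channels, attention_reduction, seed=seed + 1 + i)
            for i in range(4)
        ]
        # stride-2 3x3 convs for the bottom-up path-enhancement pass
        self.pe_convs = [
            rng.normal(
                0.0,
                np.sqrt(1.0 / (fused_channels * 9)),
                size=(fused_channels, fused_channels, 3, 3),
            )
            for _ in range(3)
        ]
        self.fused_channels = fused_channels
        self.use_p0 = use_p0

    def _project(self, level: int, c: np.ndarray) -> np.ndarray:
        return np.einsum("oc,chw->ohw", self.laterals[level], c)

    def _gate(self, level: int, x: np.ndarray) -> np.ndarray:
        if self.attention_mode == "none":
            return x
        if self.attention_mode == "c5" and level != 3:
            return x
        _, gated = self.attn[level](x)
        return gated

    def __call__(self, c: FeatureMapSet) -> FeatureMapSet:
        laterals = [self._project(i, lvl) for i, lvl in enumerate(c.levels)]
        # top-down: gate the deepest level, upsample 2x, add
        tops = [None] * 4
        tops[3] = self._gate(3, laterals[3])
        for k in (2, 1, 0):
            tops[k] = self._gate(k, laterals[k]) + bilinear_upsample(tops[k + 1], 2)
        # high-resolution aggregate of all levels at C2 scale
        p0 = None
        if self.use_p0:
            p0 = (
                laterals[0]
                + bilinear_upsample(laterals[1], 2)
                + bilinear_upsample(laterals[2], 4)
                + bilinear_upsample(self._gate(3, laterals[3]), 8)
            )
        # bottom-up path enhancement: stride-2 conv + add
        outs = [tops[0]]
        for k in (1, 2, 3):
            down = conv2d(outs[-1], self.pe_convs[k - 1], stride=2, pad=1)
            outs.append(tops[k] + down)
        return FeatureMapSet(
            C2=c.C2, C3=c.C3, C4=c.C4, C5=c.C5,
            P0=p0, P2=outs[0], P3=outs[1], P4=outs[2], P5=outs[3],
        )


class ToyBackbone:
    """4-stage random-weight CNN producing a C2..C5 pyramid for tests.

    Stage k: stride-2 3x3 conv + ReLU. Stands in for the full
    group-convolution backbone behind the same pyramid interface; it is not
    trained.
    """

    def __init__(self, channels: tuple[int, int, int, int] = (8, 12, 16, 24), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.channels = channels
        ins = (3,) + channels[:-1]
        self.convs = [
            rng.normal(0.0, np.sqrt(2.0 / (c_in * 9)), size=(c_out, c_in, 3, 3))
            for c_in, c_out in zip(ins, channels)
        ]

    def __call__(self, image: np.ndarray) -> FeatureMapSet:
        """image: (H, W, 3) uint8/float -> pyramid with C2 at H/2 x W/2."""
        x = np.asarray(image, dtype=float)
        if x.ndim == 2:
            x = np.stack([x] * 3, axis=-1)
        x = np.moveaxis(x, -1, 0) / 255.0
        levels = []
        for w in self.convs:
            x = np.maximum(conv2d(x, w, stride=2, pad=1), 0.0)
            levels.append(x)
        return FeatureMapSet(*levels)


def roi_pool(feature: np.ndarray, box, scale: float) -> np.ndarray:
    """Mean-pool a feature map over a box given the feature/image scale."""
    c, h, w = feature.shape
    x0 = int(np.clip(np.floor(box[0] * scale), 0, w - 1))
    x1 = int(np.clip(np.ceil(box[2] * scale), x0 + 1, w))
    y0 = int(np.clip(np.floor(box[1] * scale), 0, h - 1))
    y1 = int(np.clip(np.ceil(box[3] * scale), y0 + 1, h))
    return feature[:, y0:y1, x0:x1].mean(axis=(-2, -1))


@dataclass
class BoxRefinementHead:
    """Linear head mapping a pooled feature vector to box deltas.

    Predicted box = prior + W @ features (deltas on the four corners); the
    regression target is trained with the GIoU loss.
    """

    weights: np.ndarray  # (4, feat_dim)

    @classmethod
    def zeros(cls, feat_dim: int) -> "BoxRefinementHead":
        return cls(weights=np.zeros((4, feat_dim)))

    def predict(self, features: np.ndarray, priors: np.ndarray) -> np.ndarray:
        """features: (N, feat_dim); priors: (N, 4) -> (N, 4) boxes."""
        deltas = features @ self.weights.T
        return np.asarray(priors, dtype=float) + deltas


def refinement_step(
    head: BoxRefinementHead,
    features: np.ndarray,
    priors: np.ndarray,
    targets: np.ndarray,
    lr: float = 1.0,
    eps: float = 1e-4,
) -> tuple[BoxRefinementHead, float, float]:
    """One gradient-descent step on the GIoU loss of the refinement head.

    The gradient is taken by central finite differences over the head
    weights (the head is tiny by construction). Returns the updated head
    and the loss before and after the step.
    """

    def loss_of(w: np.ndarray) -> float:
        pred = np.asarray(priors, dtype=float) + features @ w.T
        return giou_loss(pred, targets, reduction="mean")

    w = head.weights.copy()
    base = loss_of(w)
    grad = np.zeros_like(w)
    it = np.nditer(w, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        wp = w.copy()
        wp[i] += eps
        wm = w.copy()
        wm[i] -= eps
        grad[i] = (loss_of(wp) - loss_of(wm)) / (2 * eps)
    norm = np.linalg.norm(grad)
    if norm > 0:
        step = lr * grad / norm
        # backtracking so the step is guaranteed non-increasing
        for _ in range(20):
            candidate = w - step
            if loss_of(candidate) < base:
                w = candidate
                break
            step = step / 2
    return BoxRefinementHead(weights=w), base, loss_of(w)
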