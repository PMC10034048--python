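"""The SE-Unet graph: encoder/decoder wiring, softmax head, Dice loss.

The network is a symmetric U of ``depth`` levels. Each level applies two 3x3
conv -> BN -> ReLU stages with a dropout between the convolutions, followed
by a squeeze-and-excitation block (omitted in the plain U-net variant); the
encoder halves the spatial size with 2x2 max pooling and doubles the channel
count per level, the decoder mirrors this with learned 2x2 up-convolutions
and skip concatenations. A 1x1 two-channel head with a channel softmax
produces the per-position class distribution. The multi-feature fusion
variant prepends one conv -> BN -> ReLU stem per input feature tensor and
concatenates the stem outputs before the first level.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError, DimensionError
from .layers import (
    F32,
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    Dropout,
    MaxPool2x2,
    ReLU,
    SEBlock,
)

__all__ = ["SEUnet", "dice_loss", "dice_loss_and_grad", "softmax_channels"]


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over the channel axis of an NCHW tensor."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=1, keepdims=True)).astype(F32)


def dice_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray | None = None, eps: float = 1.0) -> float:
    """Soft Dice loss 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps).

    ``pred`` holds foreground probabilities in [0, 1]; ``mask`` (1 = real
    vertex slot, 0 = padding) excludes padded slots from every sum.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise DimensionError(f"pred shape {pred.shape} != target shape {target.shape}")
    if mask is None:
        mask = np.ones_like(pred)
    else:
        mask = np.asarray(mask, dtype=np.float64)
        if mask.shape != pred.shape:
            raise DimensionError(f"mask shape {mask.shape} != pred shape {pred.shape}")
    inter = float((pred * target * mask).sum())
    den = float((pred * mask).sum() + (target * mask).sum())
    return 1.0 - (2.0 * inter + eps) / (den + eps)


def dice_loss_and_grad(pred, target, mask=None, eps: float = 1.0):
    """Dice loss and its gradient w.r.t. the foreground probabilities."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mask = np.ones_like(pred) if mask is None else np.asarray(mask, dtype=np.float64)
    inter = (pred * target * mask).sum()
    num = 2.0 * inter + eps
    den = (pred * mask).sum() + (target * mask).sum() + eps
    loss = 1.0 - num / den
    grad = -(2.0 * target * den - num) / den**2 * mask
    return float(loss), grad.astype(F32)


class _DoubleConv:
    """conv3x3 -> BN -> ReLU -> dropout -> conv3x3 -> BN -> ReLU [-> SE]."""

    def __init__(self, cin, cout, dropout, bn_momentum, use_se, r, rng, drop_rng, name):
        self.seq = [
            Conv2D(cin, cout, 3, rng, f"{name}.conv1"),
            BatchNorm2D(cout, bn_momentum, name=f"{name}.bn1"),
            ReLU(),
            Dropout(dropout, drop_rng),
            Conv2D(cout, cout, 3, rng, f"{name}.conv2"),
            BatchNorm2D(cout, bn_momentum, name=f"{name}.bn2"),
            ReLU(),
        ]
        if use_se:
            self.seq.append(SEBlock(cout, r, rng, f"{name}.se"))

    def forward(self, x, training):
        for layer in self.seq:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.seq):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.seq for p in layer.params()]


class _Stem:
    """Per-feature scaling block for pre-fusion: conv3x3 -> BN -> ReLU."""

    def __init__(self, cin, cout, bn_momentum, rng, name):
        self.seq = [
            Conv2D(cin, cout, 3, rng, f"{name}.conv"),
            BatchNorm2D(cout, bn_momentum, name=f"{name}.bn"),
            ReLU(),
        ]

    def forward(self, x, training):
        for layer in self.seq:
            x = layer.forward(x, training)
        return x

    def backward(self, g):
        for layer in reversed(self.seq):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.seq for p in layer.params()]


class SEUnet:
    """The (SE-)U-net computation graph with manual forward/backward."""

    def __init__(
        self,
        in_channels: int = 16,
        depth: int = 5,
        base_channels: int = 64,
        se_reduction: int = 24,
        dropout: float = 0.2,
        bn_momentum: float = 0.6,
        variant: str = "se_unet",
        n_features: int = 1,
        seed: int = 0,
    ):
        if variant not in ("unet", "se_unet", "se_unet_fusion"):
            raise ConfigError(f"unknown variant {variant!r}")
        if depth < 2:
            raise ConfigError("depth must be >= 2")
        if n_features < 1:
            raise ConfigError("n_features must be >= 1")
        use_se = variant in ("se_unet", "se_unet_fusion")
        if use_se and base_channels < se_reduction:
            raise ConfigError(
                f"se_reduction r={se_reduction} must not exceed base_channels={base_channels}"
            )
        self.variant = variant
        self.depth = depth
        self.n_features = n_features
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(seed + 1)
        self._drop_rng_seed = seed + 1
        self._drop_rng = drop_rng

        self.stems: list[_Stem] = []
        enc_in = in_channels
        if variant == "se_unet_fusion":
            self.stems = [
                _Stem(in_channels, in_channels, bn_momentum, rng, f"stem{i}")
                for i in range(n_features)
            ]
            enc_in = in_channels * n_features

        ch = [base_channels * 2**i for i in range(depth)]
        self.enc: list[_DoubleConv] = []
        self.pools: list[MaxPool2x2] = []
        cin = enc_in
        for i in range(depth - 1):
            self.enc.append(
                _DoubleConv(cin, ch[i], dropout, bn_momentum, use_se, se_reduction, rng, drop_rng, f"enc{i}")
            )
            self.pools.append(MaxPool2x2())
            cin = ch[i]
        self.bottleneck = _DoubleConv(
            ch[depth - 2], ch[depth - 1], dropout, bn_momentum, use_se, se_reduction, rng, drop_rng, "bottleneck"
        )
        self.upconvs: list[ConvTranspose2D] = []
        self.dec: list[_DoubleConv] = []
        for i in range(depth - 2, -1, -1):
            self.upconvs.append(ConvTranspose2D(ch[i + 1], ch[i], rng, f"up{i}"))
            self.dec.append(
                _DoubleConv(2 * ch[i], ch[i], dropout, bn_momentum, use_se, se_reduction, rng, drop_rng, f"dec{i}")
            )
        self.head = Conv2D(ch[0], 2, 1, rng, "head")
        self.se_channel_counts = (
            ch[: depth - 1] + [ch[depth - 1]] + ch[depth - 2 :: -1] if use_se else []
        )

    # -- parameters ---------------------------------------------------------
    def params(self):
        out = []
        for stem in self.stems:
            out += stem.params()
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for up, blk in zip(self.upconvs, self.dec):
            out += up.params() + blk.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def reseed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for blk in [*self.enc, self.bottleneck, *self.dec]:
            for layer in blk.seq:
                if isinstance(layer, Dropout):
                    layer.rng = rng

    # -- forward / backward -------------------------------------------------
    def forward(self, x, training: bool = False) -> np.ndarray:
        """Class probabilities (N, 2, H, W); softmax over the channel axis."""
        if self.variant == "se_unet_fusion":
            if not isinstance(x, (list, tuple)) or len(x) != self.n_features:
                raise DimensionError(
                    f"fusion variant expects a list of {self.n_features} NCHW tensors"
                )
            outs = [stem.forward(xi.astype(F32), training) for stem, xi in zip(self.stems, x)]
            h = np.concatenate(outs, axis=1)
        else:
            h = np.asarray(x, dtype=F32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, blk, skip in zip(self.upconvs, self.dec, reversed(skips)):
            h = up.forward(h, training)
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, training)
        logits = self.head.forward(h, training)
        self._probs = softmax_channels(logits)
        return self._probs

    def backward(self, grad_fg: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the foreground probability map."""
        p = self._probs
        p0, p1 = p[:, 0], p[:, 1]
        glog = np.empty_like(p)
        glog[:, 1] = grad_fg * p1 * (1.0 - p1)
        glog[:, 0] = -grad_fg * p0 * p1
        g = self.head.backward(glog.astype(F32))
        # dec[i] was paired with encoder level depth-2-i in the forward pass;
        # walking dec from its end therefore emits skip gradients for encoder
        # levels 0, 1, ..., depth-2 in that order
        skip_grads = []
        for i in range(len(self.dec) - 1, -1, -1):
            g = self.dec[i].backward(g)
            c_skip = self._skip_channels[len(self.dec) - 1 - i]
            gskip, gup = g[:, :c_skip], g[:, c_skip:]
            skip_grads.append(gskip)
            g = self.upconvs[i].backward(gup)
        g = self.bottleneck.backward(g)
        for i in range(len(self.enc) - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        if self.variant == "se_unet_fusion":
            c = self.in_channels
            for i, stem in enumerate(self.stems):
                stem.backward(g[:, i * c : (i + 1) * c])

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # -- serialization ------------------------------------------------------
    def _all_layers(self):
        blocks = [*self.stems, *self.enc, self.bottleneck, *self.dec]
        layers = [layer for blk in blocks for layer in blk.seq]
        layers += list(self.upconvs) + list(self.pools) + [self.head]
        return layers

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2D):
                prefix = layer.gamma.name.rsplit(".", 1)[0]
                state[f"{prefix}.running_mean"] = layer.running_mean.copy()
                state[f"{prefix}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value = np.asarray(state[p.name], dtype=F32)
            p.grad = np.zeros_like(p.value)
        for layer in self._all_layers():
            if isinstance(layer, BatchNorm2D):
                prefix = layer.gamma.name.rsplit(".", 1)[0]
                layer.running_mean = np.asarray(state[f"{prefix}.running_mean"], dtype=F32)
                layer.running_var = np.asarray(state[f"{prefix}.running_var"], dtype=F32)
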