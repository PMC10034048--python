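"""SE-Unet training and inference for 3-hinge region segmentation.

:class:`SEUnetSegmenter` is a scikit-learn-style estimator over blocked
feature tensors: ``fit`` trains the network with RMSprop on the soft Dice
loss (padding slots masked out), ``predict_proba``/``predict`` apply it.
Module-level ``build_model``/``train_model``/``predict_regions`` are thin
functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, DimensionError
from .features import FeatureBlocks, unblock
from .nn import RMSprop, SEUnet, dice_loss_and_grad
from .nn.optim import exponential_lr

__all__ = [
    "ModelConfig",
    "SEUnetSegmenter",
    "build_model",
    "train_model",
    "predict_regions",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings of the segmentation network.

    The defaults are the full-scale settings: a 5-level U with 64 first-level
    channels, SE reduction r = 24, dropout 0.2 between the paired
    convolutions, batch-norm momentum 0.6, RMSprop at lr0 = 0.05 decayed
    exponentially per epoch, batch size 40, 150 epochs.
    """

    depth: int = 5
    base_channels: int = 64
    se_reduction: int = 24
    dropout: float = 0.2
    bn_momentum: float = 0.6
    lr0: float = 0.05
    lr_decay: float = 0.96
    batch_size: int = 40
    epochs: int = 150
    n_features: int = 1
    variant: str = "se_unet"
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in ("unet", "se_unet", "se_unet_fusion"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        if self.variant != "se_unet_fusion" and self.n_features != 1:
            raise ConfigError("only the fusion variant takes more than one feature")
        if self.variant != "unet":
            if self.se_reduction < 1 or self.base_channels // self.se_reduction < 1:
                raise ConfigError(
                    f"se_reduction r={self.se_reduction} must floor-divide "
                    f"base_channels={self.base_channels} to >= 1"
                )
        if self.depth < 2 or self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("depth >= 2, epochs >= 1 and batch_size >= 1 required")


class SEUnetSegmenter(BaseEstimator):
    """Two-class SE-Unet segmenter over (N, H, W, C) feature blocks.

    ``X`` is a single blocked tensor, or a list of ``n_features`` tensors for
    the pre-fusion variant; ``y`` is the (N, H, W) binary region mask and
    ``sample_mask`` (1 = real vertex, 0 = padding) keeps padded slots out of
    the loss. Fitted attributes: ``net_``, ``training_log_``, ``n_params_``.
    """

    def __init__(
        self,
        depth: int = 5,
        base_channels: int = 64,
        se_reduction: int = 24,
        dropout: float = 0.2,
        bn_momentum: float = 0.6,
        lr0: float = 0.05,
        lr_decay: float = 0.96,
        batch_size: int = 40,
        epochs: int = 150,
        n_features: int = 1,
        variant: str = "se_unet",
        seed: int = 0,
    ):
        self.depth = depth
        self.base_channels = base_channels
        self.se_reduction = se_reduction
        self.dropout = dropout
        self.bn_momentum = bn_momentum
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.n_features = n_features
        self.variant = variant
        self.seed = seed

    # -- plumbing -----------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(**{k: getattr(self, k) for k in ModelConfig.__dataclass_fields__})

    def _build(self, in_channels: int) -> SEUnet:
        cfg = self._config()
        cfg.validate()
        return SEUnet(
            in_channels=in_channels,
            depth=cfg.depth,
            base_channels=cfg.base_channels,
            se_reduction=cfg.se_reduction,
            dropout=cfg.dropout,
            bn_momentum=cfg.bn_momentum,
            variant=cfg.variant,
            n_features=cfg.n_features,
            seed=cfg.seed,
        )

    @staticmethod
    def _to_nchw(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4:
            raise DimensionError(f"expected (N, H, W, C) blocks, got shape {x.shape}")
        return x.transpose(0, 3, 1, 2)

    def _prepare_x(self, X):
        if self.variant == "se_unet_fusion":
            if not isinstance(X, (list, tuple)):
                raise DimensionError("fusion variant expects a list of block tensors")
            if len(X) != self.n_features:
                raise ConfigError(
                    f"model expects {self.n_features} feature tensors, got {len(X)}"
                )
            return [self._to_nchw(x) for x in X]
        if isinstance(X, (list, tuple)):
            if len(X) != 1:
                raise ConfigError("single-feature variants take exactly one tensor")
            X = X[0]
        return self._to_nchw(X)

    @staticmethod
    def _n_samples(X):
        return X[0].shape[0] if isinstance(X, list) else X.shape[0]

    @staticmethod
    def _take(X, sel):
        return [x[sel] for x in X] if isinstance(X, list) else X[sel]

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y, sample_mask=None, feature_names=None):
        Xp = self._prepare_x(X)
        n = self._n_samples(Xp)
        if n < 1:
            raise ConfigError("training set is empty")
        y = np.asarray(y, dtype=np.float32)
        hw = Xp[0].shape[2:] if isinstance(Xp, list) else Xp.shape[2:]
        if y.shape != (n, *hw):
            raise DimensionError(f"labels shape {y.shape} does not match blocks {(n, *hw)}")
        mask = np.ones_like(y) if sample_mask is None else np.asarray(sample_mask, np.float32)
        if mask.shape != y.shape:
            raise DimensionError("sample_mask shape must match labels")

        in_channels = (Xp[0] if isinstance(Xp, list) else Xp).shape[1]
        self.net_ = self._build(in_channels)
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        opt = RMSprop(self.net_.params())
        rng = np.random.default_rng(self.seed + 9973)
        log = []
        for epoch in range(self.epochs):
            lr = exponential_lr(self.lr0, self.lr_decay, epoch)
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = perm[start : start + self.batch_size]
                xb = self._take(Xp, sel)
                probs = self.net_.forward(xb, training=True)
                loss, grad = dice_loss_and_grad(probs[:, 1], y[sel], mask[sel])
                opt.zero_grad()
                self.net_.backward(grad)
                opt.step(lr)
                losses.append(loss)
            log.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
        self.training_log_ = pd.DataFrame(log)
        self.n_params_ = self.net_.n_parameters()
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-slot class probabilities, shape (N, H, W, 2)."""
        Xp = self._prepare_x(X)
        probs = self.net_.forward(Xp, training=False)
        return probs.transpose(0, 2, 3, 1)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Binary foreground mask; threshold 0.5 equals the softmax argmax."""
        proba = self.predict_proba(X)
        return (proba[..., 1] > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def build_model(cfg: ModelConfig, in_channels: int = 16) -> SEUnetSegmenter:
    """Instantiate an untrained segmenter (the network is built lazily but the
    configuration is validated eagerly)."""
    cfg.validate()
    est = SEUnetSegmenter(**asdict(cfg))
    est.net_ = est._build(in_channels)
    est.n_params_ = est.net_.n_parameters()
    return est


def _blocks_xym(blocks: FeatureBlocks, label_blocks: np.ndarray):
    tensors = blocks.stacked()
    X = tensors if len(tensors) > 1 else tensors[0]
    mask = (~blocks.pad_mask).astype(np.float32)
    return X, np.asarray(label_blocks, np.float32), mask


def train_model(blocks: FeatureBlocks, label_blocks: np.ndarray, cfg: ModelConfig) -> SEUnetSegmenter:
    """Train on one subject's blocks; labels must be blocked with the same map."""
    cfg.validate()
    X, y, mask = _blocks_xym(blocks, label_blocks)
    est = SEUnetSegmenter(**asdict(cfg))
    return est.fit(X, y, sample_mask=mask, feature_names=blocks.feature_names)


def save_model(model: SEUnetSegmenter, path) -> None:
    """Checkpoint: weights + BN running stats as npz, config as JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.net_.state_dict()
    np.savez_compressed(path, **state)
    meta = {
        "config": asdict(model._config()),
        "in_channels": model.net_.in_channels,
        "feature_names": getattr(model, "feature_names_", None),
        "n_params": model.n_params_,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_model(path) -> SEUnetSegmenter:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**meta["config"])
    est = SEUnetSegmenter(**asdict(cfg))
    est.net_ = est._build(meta["in_channels"])
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz) as data:
        est.net_.load_state_dict({k: data[k] for k in data.files})
    est.feature_names_ = meta.get("feature_names")
    est.n_params_ = est.net_.n_parameters()
    est.classes_ = np.array([0, 1])
    est.training_log_ = pd.DataFrame()
    return est


def predict_regions(model: SEUnetSegmenter, blocks: FeatureBlocks, threshold: float = 0.5) -> np.ndarray:
    """Apply a trained model to blocks and return per-vertex binary labels."""
    if getattr(model, "feature_names_", None) is not None:
        if list(blocks.feature_names) != list(model.feature_names_):
            raise ConfigError(
                f"feature order mismatch: model was fit on {model.feature_names_}, "
                f"blocks carry {blocks.feature_names}"
            )
    tensors = blocks.stacked()
    X = tensors if len(tensors) > 1 else tensors[0]
    pred = model.predict(X, threshold=threshold)
    return unblock(blocks, pred).astype(np.uint8)
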