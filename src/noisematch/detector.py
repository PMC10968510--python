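"""Lesion-detection network: residual encoder-decoder with a combined
binary-cross-entropy + Dice objective.

The network maps an SUV image to a per-voxel lesion logit map.  The
encoder and decoder each hold four residual blocks; the decoder
upsamples with two strided transposed convolutions and merges encoder
features through additive skip connections.  The final layer is linear,
so prediction maps are binarized at logit 0, followed by a connected-
component noise filter that discards predictions smaller than 20
pixels.  The combined loss counteracts the extreme foreground/
background imbalance of lesion masks.

:class:`LesionDetector` wraps training and inference in a
scikit-learn-style estimator (``fit`` / ``predict`` /  ``get_params``),
fully seeded and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from skimage.measure import label as _cc_label

from . import nn
from .core import LesionMask, SUVImage, connectivity_for
from .evaluation import detection_metrics, match_lesions

__all__ = [
    "NetworkConfig",
    "LossConfig",
    "TrainConfig",
    "combined_loss",
    "combined_loss_grad",
    "build_network",
    "DetectionNet",
    "LesionDetector",
    "train",
    "predict",
    "postprocess_logits",
    "save_checkpoint",
    "load_checkpoint",
]

#: SUV values are divided by this constant before entering the network,
#: bringing normal liver background to ~0.5.  A fixed constant (rather
#: than per-image statistics) deliberately preserves inter-domain
#: intensity/noise differences, which are the object of study.
INPUT_SCALE = 10.0


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Four residual blocks per path with two downsampling / two
    transposed-convolution upsampling stages; channel width doubles at
    each downsampling.  The input grid must be divisible by the total
    downsampling factor (4).
    """

    n_down_blocks: int = 4
    n_up_blocks: int = 4
    n_transposed_layers: int = 2
    base_channels: int = 16

    def __post_init__(self) -> None:
        if self.n_down_blocks != self.n_up_blocks:
            raise ValueError("encoder and decoder must have equal block counts")
        if self.n_down_blocks % self.n_transposed_layers:
            raise ValueError(
                "block count must be a multiple of the up/downsampling stages"
            )

    @property
    def downsample_factor(self) -> int:
        return 2**self.n_transposed_layers


@dataclass(frozen=True)
class LossConfig:
    """Weights of the combined objective; smooth_eps stabilizes the
    Dice ratio on empty masks (empty gold + empty prediction -> Dice
    term 0)."""

    bce_weight: float = 1.0
    dice_weight: float = 1.0
    smooth_eps: float = 1.0

    def __post_init__(self) -> None:
        if self.bce_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.bce_weight == 0 and self.dice_weight == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  ``binarize_threshold`` (0) and
    ``min_component_size`` (20 pixels) are the fixed post-processing
    conventions of the detection pipeline."""

    seed: int = 0
    max_epochs: int = 50
    learning_rate: float = 3e-3
    batch_size: int = 8
    early_stop_patience: int = 10
    early_stop_min_epochs: int = 10
    lr_decay_factor: float = 0.3
    lr_decay_at: float = 2.0 / 3.0  # fraction of max_epochs
    binarize_threshold: float = 0.0
    min_component_size: int = 20


def combined_loss(
    prediction_map: np.ndarray, gold: np.ndarray, cfg: LossConfig | None = None
) -> float:
    """Weighted BCE + Dice loss of a pre-sigmoid prediction map.

    BCE is averaged over voxels; the Dice term is global over the
    array, ``1 - (2 sum(p g) + eps) / (sum(p) + sum(g) + eps)`` with
    ``p = sigmoid(prediction_map)``.  Nonnegative, and 0 only in the
    perfect-prediction limit.
    """
    cfg = cfg or LossConfig()
    z = np.asarray(prediction_map, dtype=np.float64)
    g = np.asarray(gold, dtype=np.float64)
    if z.shape != g.shape:
        raise ValueError("prediction and gold shapes differ")
    p = nn.sigmoid(z)
    loss = 0.0
    if cfg.bce_weight:
        loss += cfg.bce_weight * nn.bce_with_logits(z, g)
    if cfg.dice_weight:
        num = 2.0 * float((p * g).sum()) + cfg.smooth_eps
        den = float(p.sum() + g.sum()) + cfg.smooth_eps
        loss += cfg.dice_weight * (1.0 - num / den)
    return float(loss)


def combined_loss_grad(
    prediction_map: np.ndarray, gold: np.ndarray, cfg: LossConfig | None = None
) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient w.r.t. the logits."""
    cfg = cfg or LossConfig()
    z = np.asarray(prediction_map, dtype=np.float32)
    g = np.asarray(gold, dtype=np.float32)
    if z.shape != g.shape:
        raise ValueError("prediction and gold shapes differ")
    p = nn.sigmoid(z)
    grad = np.zeros_like(z)
    loss = 0.0
    if cfg.bce_weight:
        loss += cfg.bce_weight * nn.bce_with_logits(z, g)
        grad += cfg.bce_weight * (p - g) / z.size
    if cfg.dice_weight:
        num = 2.0 * float((p * g).sum()) + cfg.smooth_eps
        den = float(p.sum() + g.sum()) + cfg.smooth_eps
        loss += cfg.dice_weight * (1.0 - num / den)
        ddice_dp = -(2.0 * g * den - num) / den**2
        grad += cfg.dice_weight * ddice_dp * p * (1.0 - p)
    return float(loss), grad


class DetectionNet:
    """The residual encoder-decoder, assembled from the NumPy backend."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.base_channels
        per_stage = cfg.n_down_blocks // cfg.n_transposed_layers
        self.stem = nn.Conv2d(1, c, 3, rng=rng, name="stem")
        self.enc: list[nn.ResBlock] = []
        self.skip_at: list[int] = []  # encoder indices feeding skips
        ch = c
        for s in range(cfg.n_transposed_layers):
            for b in range(per_stage):
                if b == per_stage - 1:
                    # last block of the stage records the skip, then the
                    # next stage downsamples
                    pass
                self.enc.append(
                    nn.ResBlock(ch, ch, 1, rng=rng, name=f"enc{s}{b}")
                    if b < per_stage - 1
                    else nn.ResBlock(ch, 2 * ch, 2, rng=rng, name=f"enc{s}{b}")
                )
                if b == per_stage - 2 or per_stage == 1:
                    self.skip_at.append(len(self.enc) - 1)
            ch *= 2
        # decoder: per stage, one transposed-conv upsampler then blocks
        self.ups: list[nn.ConvTranspose2d] = []
        self.dec: list[nn.ResBlock] = []
        for s in range(cfg.n_transposed_layers):
            self.ups.append(nn.ConvTranspose2d(ch, ch // 2, rng=rng, name=f"up{s}"))
            ch //= 2
            for b in range(per_stage):
                self.dec.append(nn.ResBlock(ch, ch, 1, rng=rng, name=f"dec{s}{b}"))
        self.head = nn.Conv2d(c, 1, 1, pad=0, rng=rng, name="head")

    def params(self) -> list[nn.Param]:
        out = self.stem.params()
        for blk in self.enc:
            out += blk.params()
        for up in self.ups:
            out += up.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    def norm_layers(self) -> list[nn.BatchNorm]:
        out = []
        for blk in self.enc + self.dec:
            out += blk.norms()
        return out

    def set_training(self, training: bool) -> None:
        """Switch batch-norm layers between batch statistics (training)
        and frozen running statistics (inference)."""
        for norm in self.norm_layers():
            norm.training = training

    def state_arrays(self) -> list[np.ndarray]:
        """Copies of all learnable parameters and running statistics."""
        out = [p.value.copy() for p in self.params()]
        for norm in self.norm_layers():
            out += [b.copy() for b in norm.buffers()]
        return out

    def load_state_arrays(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, s in zip(params, state):
            p.value[...] = s
        i = len(params)
        for norm in self.norm_layers():
            for b in norm.buffers():
                b[...] = state[i]
                i += 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W) float32 -> logits (N, H, W)."""
        if x.ndim == 3:
            x = x[..., None]  # NHWC with a single input channel
        f = self.cfg.downsample_factor
        if x.shape[1] % f or x.shape[2] % f:
            raise ValueError(
                f"input grid must be divisible by the downsampling factor {f}"
            )
        h = self.stem.forward(np.ascontiguousarray(x, dtype=nn.F32))
        skips = []
        for i, blk in enumerate(self.enc):
            if i in self.skip_at:
                skips.append(h)
            h = blk.forward(h)
        per_stage = self.cfg.n_down_blocks // self.cfg.n_transposed_layers
        di = 0
        for s, up in enumerate(self.ups):
            h = up.forward(h) + skips[-(s + 1)]
            for _ in range(per_stage):
                h = self.dec[di].forward(h)
                di += 1
        return self.head.forward(h)[..., 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[..., None])
        per_stage = self.cfg.n_down_blocks // self.cfg.n_transposed_layers
        dskips: list[np.ndarray] = []
        di = len(self.dec)
        for s in range(len(self.ups) - 1, -1, -1):
            for _ in range(per_stage):
                di -= 1
                d = self.dec[di].backward(d)
            dskips.append(d)  # gradient into the additive skip
            d = self.ups[s].backward(d)
        # dskips[k] pairs with skips[k]; the reversed encoder traversal
        # meets the later skips first, so index by skip position
        for i, blk in enumerate(reversed(self.enc)):
            d = blk.backward(d)
            idx = len(self.enc) - 1 - i
            if idx in self.skip_at:
                d = d + dskips[self.skip_at.index(idx)]
        self.stem.backward(d)


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> DetectionNet:
    """Construct an untrained detector network (deterministic in seed)."""
    return DetectionNet(cfg or NetworkConfig(), seed=seed)


def postprocess_logits(
    logits: np.ndarray,
    threshold: float = 0.0,
    min_component_size: int = 20,
    spacing=None,
) -> LesionMask:
    """Binarize a logit map at ``threshold``, label connected
    components and drop those smaller than ``min_component_size``
    pixels, relabeling survivors contiguously."""
    binary = np.asarray(logits) > threshold
    labels = _cc_label(binary, connectivity=connectivity_for(binary.ndim))
    if labels.max():
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_component_size)
        keep = keep[keep > 0]
        remap = np.zeros(counts.size, dtype=np.int32)
        remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
        labels = remap[labels]
    return LesionMask(
        labels.astype(np.int32),
        spacing=tuple(spacing) if spacing is not None else (1.0,) * binary.ndim,
    )


def _as_array(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        return images.astype(nn.F32)
    return np.stack(
        [
            img.voxels if isinstance(img, SUVImage) else np.asarray(img)
            for img in images
        ]
    ).astype(nn.F32)


class LesionDetector(BaseEstimator):
    """Seeded lesion-detection estimator.

    Parameters
    ----------
    network, loss, train:
        Configuration dataclasses (see :class:`NetworkConfig`,
        :class:`LossConfig`, :class:`TrainConfig`).

    Attributes (after ``fit``)
    --------------------------
    net_ : DetectionNet
        Trained network (best-validation checkpoint if validation data
        were supplied, else final epoch).
    history_ : pandas.DataFrame
        Per-epoch training loss and validation F1.
    best_val_f1_ : float
        Highest pooled validation F1 observed.
    n_epochs_ : int
        Number of epochs actually run.
    """

    def __init__(
        self,
        network: NetworkConfig = NetworkConfig(),
        loss: LossConfig = LossConfig(),
        train: TrainConfig = TrainConfig(),
    ):
        self.network = network
        self.loss = loss
        self.train = train

    # -- core API ---------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Optimize the combined loss on (X, y) with Adam.

        X : (N, H, W) SUV images (raw SUV; scaled internally).
        y : (N, H, W) binary gold masks.
        Validation images, if given, drive best-F1 checkpoint selection
        and early stopping.
        """
        cfg = self.train
        X = _as_array(X) / INPUT_SCALE
        y = np.asarray(
            np.stack([np.asarray(m.labels if isinstance(m, LesionMask) else m) for m in y])
            > 0,
            dtype=nn.F32,
        )
        if X.shape != y.shape:
            raise ValueError("image and mask stacks must have equal shapes")
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        net = build_network(self.network, seed=cfg.seed)
        params = net.params()
        opt = nn.Adam(params, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        best_state = net.state_arrays()
        best_f1 = -np.inf
        since_best = 0
        rows = []
        n = X.shape[0]
        decay_epoch = int(np.floor(cfg.max_epochs * cfg.lr_decay_at))
        for epoch in range(cfg.max_epochs):
            if epoch == decay_epoch and 0 < cfg.lr_decay_factor < 1:
                opt.lr *= cfg.lr_decay_factor
            net.set_training(True)
            order = rng.permutation(n)
            losses = []
            # pad a trailing fragment batch by wrapping around the
            # shuffled order: batch-norm statistics from 1-2 images are
            # degenerate and destabilize small-dataset training
            for start in range(0, n, cfg.batch_size):
                if start + cfg.batch_size <= n or n < cfg.batch_size:
                    idx = order[start : start + cfg.batch_size]
                else:
                    idx = np.concatenate(
                        [order[start:], order[: cfg.batch_size - (n - start)]]
                    )
                logits = net.forward(X[idx])
                loss, dlog = combined_loss_grad(logits, y[idx], self.loss)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (loss={loss}) at epoch {epoch}"
                    )
                opt.zero_grad()
                net.backward(dlog)
                opt.step()
                losses.append(loss)
            val_f1 = np.nan
            if X_val is not None:
                self.net_ = net
                val_f1 = self._pooled_f1(X_val, y_val)
                # pre-burn-in scores are trusted neither for stopping
                # nor for checkpoint selection: a near-initialization
                # network can post a lucky validation score that a
                # converging run needs many epochs to beat
                eligible = epoch + 1 >= min(
                    cfg.early_stop_min_epochs, cfg.max_epochs
                )
                if not eligible:
                    pass
                elif val_f1 > best_f1:
                    best_f1 = val_f1
                    best_state = net.state_arrays()
                    since_best = 0
                else:
                    if val_f1 == best_f1:
                        # pooled F1 over a small validation set is a
                        # coarse, quantized metric: on an exact tie keep
                        # the later (further-trained) checkpoint
                        best_state = net.state_arrays()
                    since_best += 1
            rows.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_f1": val_f1}
            )
            # early stopping only after a burn-in: at small data scales
            # a near-initialization network can post a lucky validation
            # score while the loss is still falling steeply
            if (
                X_val is not None
                and epoch + 1 >= cfg.early_stop_min_epochs
                and since_best >= cfg.early_stop_patience
            ):
                break
        if X_val is not None and np.isfinite(best_f1):
            net.load_state_arrays(best_state)
        net.set_training(False)
        self.net_ = net
        self.history_ = pd.DataFrame(rows)
        self.best_val_f1_ = float(best_f1) if np.isfinite(best_f1) else np.nan
        self.n_epochs_ = len(rows)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw logit maps, (N, H, W); inference uses frozen statistics."""
        self._check_fitted()
        self.net_.set_training(False)
        X = _as_array(X) / INPUT_SCALE
        # chunked inference to bound memory
        out = [self.net_.forward(X[i : i + 16]) for i in range(0, X.shape[0], 16)]
        return np.concatenate(out, axis=0)

    def predict(self, X) -> list[LesionMask]:
        """Binarized (logit > 0), 20-pixel-filtered prediction masks."""
        logits = self.decision_function(X)
        return [
            postprocess_logits(
                lm, self.train.binarize_threshold, self.train.min_component_size
            )
            for lm in logits
        ]

    # -- helpers ----------------------------------------------------------
    def _pooled_f1(self, X_val, y_val) -> float:
        preds = self.predict(X_val)
        tp = fp = fn = 0
        for pred, gold in zip(preds, y_val):
            gold_mask = (
                gold
                if isinstance(gold, LesionMask)
                else LesionMask.from_binary(np.asarray(gold) > 0)
            )
            _, (t, f, m) = match_lesions(pred, gold_mask)
            tp, fp, fn = tp + t, fp + f, fn + m
        return detection_metrics(tp, fp, fn).f1

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("detector is not fitted; call fit() first")


# -- module-level wrappers (thin) ----------------------------------------


def train(
    dataset: dict,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> LesionDetector:
    """Train a detector from a ``{"train": (X, y), "val": (X, y)}``
    dataset mapping and return the fitted estimator."""
    if "train" not in dataset or len(dataset["train"][0]) == 0:
        raise ValueError("dataset must contain a nonempty training subset")
    det = LesionDetector(
        network=net_cfg or NetworkConfig(),
        loss=loss_cfg or LossConfig(),
        train=train_cfg or TrainConfig(),
    )
    X, y = dataset["train"]
    X_val, y_val = dataset.get("val", (None, None))
    if train_cfg is not None and train_cfg.max_epochs == 0:
        # zero-epoch budget: return the seeded initialization unchanged
        det.net_ = build_network(det.network, seed=det.train.seed)
        det.net_.set_training(False)
        det.history_ = pd.DataFrame(columns=["epoch", "train_loss", "val_f1"])
        det.best_val_f1_ = np.nan
        det.n_epochs_ = 0
        return det
    return det.fit(X, y, X_val=X_val, y_val=y_val)


def predict(model: LesionDetector, image: SUVImage | np.ndarray) -> LesionMask:
    """Prediction mask for a single image."""
    arr = image.voxels if isinstance(image, SUVImage) else np.asarray(image)
    mask = model.predict(arr[None])[0]
    if isinstance(image, SUVImage):
        mask.spacing = image.spacing
    return mask


def save_checkpoint(model: LesionDetector, path) -> None:
    """Serialize parameters + configs + seed into a single .npz file."""
    model._check_fitted()
    meta = {
        "network": asdict(model.network),
        "loss": asdict(model.loss),
        "train": asdict(model.train),
    }
    arrays = {
        f"p{i:04d}": a for i, a in enumerate(model.net_.state_arrays())
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> LesionDetector:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        det = LesionDetector(
            network=NetworkConfig(**meta["network"]),
            loss=LossConfig(**meta["loss"]),
            train=TrainConfig(**meta["train"]),
        )
        det.net_ = build_network(det.network, seed=det.train.seed)
        n_arrays = len([k for k in data.files if k.startswith("p")])
        det.net_.load_state_arrays([data[f"p{i:04d}"] for i in range(n_arrays)])
        det.net_.set_training(False)
    det.history_ = pd.DataFrame(columns=["epoch", "train_loss", "val_f1"])
    det.best_val_f1_ = np.nan
    det.n_epochs_ = 0
    return det
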