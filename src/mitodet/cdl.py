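"""The CDL mitosis detector: a VGG-16-style fully convolutional network.

Thirteen 3x3 convolutional layers in five pooled blocks, the three
fully-connected layers realized as 1x1 convolutions (the classification
head's final layer replaced by a 1-channel mitosis score), three skip
connections (1x1 projections of the pool4/pool3/pool2 feature maps) fused
into a staged transposed-convolution upsampling path, and a sigmoid
per-pixel output. Trained with focal loss, Adam with a two-rate schedule
(transferred layers vs new layers), L2 regularization, dropout on the
FC-equivalent layers, plateau learning-rate reduction and early stopping.

``width_scale`` scales channel counts only — never the layer structure —
so the full architecture is trainable at desk scale on CPU. Inputs whose
side is not a multiple of 32 are reflect-padded before the stride schedule
and the output is cropped back, so the probability map always matches the
input spatially.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from skimage import measure

from .nn import (
    Adam, Conv1x1, Conv2d, ConvTransposeBlock, Dropout, MaxPool2, ReLU,
)
from .tile import HistologyTile

__all__ = [
    "CDLConfig", "CDLNetwork", "TrainState", "EarlyStopper",
    "build_cdl", "focal_loss", "transfer_weights", "augment",
    "train", "predict_segmentation", "postprocess_detections",
    "match_detections", "detection_f1",
    "save_checkpoint", "load_checkpoint",
]

_VGG_CHANNELS = (64, 128, 256, 512, 512)
_BLOCK_CONVS = (2, 2, 3, 3, 3)  # 13 convolutional layers
_FC_CHANNELS = 4096


@dataclass
class CDLConfig:
    input_side: int = 227
    width_scale: float = 1.0
    n_skips: int = 3
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    lr_pretrained: float = 1e-5
    lr_new: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 5
    plateau_patience: int = 3
    dropout: float = 0.3
    l2: float = 1e-4
    seed: int = 0
    pretrained_source: str = "vgg"

    def __post_init__(self) -> None:
        if not (0 < self.width_scale <= 1):
            raise ValueError("width_scale must be in (0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.pretrained_source not in ("vgg", "alexnet", "none"):
            raise ValueError("pretrained_source must be vgg|alexnet|none")
        if self.n_skips != 3:
            raise ValueError("the architecture defines exactly 3 skip fusions")


class CDLNetwork:
    """Built network: layers, skip taps, and the upsampling schedule."""

    def __init__(self, config: CDLConfig):
        self.config = config
        self.trained = False
        rng = np.random.default_rng([config.seed, 91])
        self._dropout_rng = np.random.default_rng([config.seed, 92])
        ws = config.width_scale
        ch = [max(1, int(round(c * ws))) for c in _VGG_CHANNELS]
        fc_ch = max(8, int(round(_FC_CHANNELS * ws)))

        self.conv_layers: List[Conv2d] = []
        self.backbone = []  # sequence of (layer, tag)
        c_prev = 3
        for b, (c_out, reps) in enumerate(zip(ch, _BLOCK_CONVS)):
            for r in range(reps):
                conv = Conv2d(c_prev, c_out, 3, rng)
                self.conv_layers.append(conv)
                self.backbone.append((conv, f"conv{b + 1}_{r + 1}"))
                self.backbone.append((ReLU(), "relu"))
                c_prev = c_out
            self.backbone.append((MaxPool2(), f"pool{b + 1}"))

        # FC layers realized as 1x1 convolutions (FCN conversion); the final
        # one is the new 1-channel mitosis score head.
        self.fc_layers = [
            Conv1x1(ch[4], fc_ch, rng),
            Conv1x1(fc_ch, fc_ch, rng),
            Conv1x1(fc_ch, 1, rng, scale=0.1),
        ]
        self.fc_relu = [ReLU(), ReLU()]
        self.fc_drop = [
            Dropout(config.dropout, self._dropout_rng),
            Dropout(config.dropout, self._dropout_rng),
        ]
        # Skip projections: SKIP1 <- pool4, SKIP2 <- pool3, SKIP3 <- pool2.
        # Small initial scale so fusion starts near the coarse prediction.
        self.skip_convs = [
            Conv1x1(ch[3], 1, rng, scale=0.01),
            Conv1x1(ch[2], 1, rng, scale=0.01),
            Conv1x1(ch[1], 1, rng, scale=0.01),
        ]
        self.up_layers = [
            ConvTransposeBlock(1, 1, 2, rng),  # /32 -> /16
            ConvTransposeBlock(1, 1, 2, rng),  # /16 -> /8
            ConvTransposeBlock(1, 1, 2, rng),  # /8  -> /4
            ConvTransposeBlock(1, 1, 4, rng),  # /4  -> /1
        ]
        self._pretrained_tags: list = []

    # -- structural description -------------------------------------------

    def describe(self) -> dict:
        return {
            "n_conv_layers": len(self.conv_layers),
            "n_fc_equivalent": len(self.fc_layers),
            "skips": [
                {"name": f"SKIP{i + 1}", "source": src, "kernel": [1, 1]}
                for i, src in enumerate(("pool4", "pool3", "pool2"))
            ],
            "upsampling": [
                {"factor": up.factor} for up in self.up_layers
            ],
            "width_scale": self.config.width_scale,
            "pretrained_layers": list(self._pretrained_tags),
        }

    def all_layers(self):
        return (
            [l for l, _ in self.backbone]
            + self.fc_layers + self.fc_relu + self.fc_drop
            + self.skip_convs + self.up_layers
        )

    def param_layers(self):
        return [l for l in self.all_layers() if l.params]

    # -- forward / backward ------------------------------------------------

    def _pad(self, x: np.ndarray):
        h, w = x.shape[2], x.shape[3]
        ph = (-h) % 32
        pw = (-w) % 32
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (h, w)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """RGB batch (N, 3, H, W) in [0, 1] -> per-pixel mitosis logits."""
        x = x.astype(np.float32) - 0.5
        x, (h0, w0) = self._pad(x)
        taps = {}
        for layer, tag in self.backbone:
            x = layer.forward(x, train=train)
            if tag in ("pool2", "pool3", "pool4"):
                taps[tag] = x
        x = self.fc_layers[0].forward(x, train=train)
        x = self.fc_relu[0].forward(x, train=train)
        x = self.fc_drop[0].forward(x, train=train)
        x = self.fc_layers[1].forward(x, train=train)
        x = self.fc_relu[1].forward(x, train=train)
        x = self.fc_drop[1].forward(x, train=train)
        score = self.fc_layers[2].forward(x, train=train)

        skips = []
        for conv, tag in zip(self.skip_convs, ("pool4", "pool3", "pool2")):
            skips.append(conv.forward(taps[tag], train=train))
        for up, skip in zip(self.up_layers[:3], skips):
            score = up.forward(score, train=train) + skip
        score = self.up_layers[3].forward(score, train=train)
        return score[:, :, :h0, :w0]

    def backward(self, grad: np.ndarray) -> None:
        n, c, h0, w0 = grad.shape
        ph, pw = (-h0) % 32, (-w0) % 32
        if ph or pw:
            g = np.zeros((n, c, h0 + ph, w0 + pw), dtype=grad.dtype)
            g[:, :, :h0, :w0] = grad
            grad = g
        grad = self.up_layers[3].backward(grad)
        skip_grads = []
        for up in reversed(self.up_layers[:3]):
            skip_grads.append(grad)  # additive fusion: gradient splits
            grad = up.backward(grad)
        skip_grads.reverse()
        tap_grads = {}
        for conv, tag, g in zip(
            self.skip_convs, ("pool4", "pool3", "pool2"), skip_grads
        ):
            tap_grads[tag] = conv.backward(g)

        grad = self.fc_layers[2].backward(grad)
        grad = self.fc_drop[1].backward(grad)
        grad = self.fc_relu[1].backward(grad)
        grad = self.fc_layers[1].backward(grad)
        grad = self.fc_drop[0].backward(grad)
        grad = self.fc_relu[0].backward(grad)
        grad = self.fc_layers[0].backward(grad)

        for layer, tag in reversed(self.backbone):
            if tag in tap_grads:
                grad = grad + tap_grads[tag]
            grad = layer.backward(grad)


def build_cdl(config: CDLConfig) -> CDLNetwork:
    """Construct the (seeded, randomly initialized) CDL network."""
    if config.input_side < 32:
        near = 32
        raise ValueError(
            f"input_side {config.input_side} below the stride schedule's "
            f"minimum; nearest valid side is {near}"
        )
    return CDLNetwork(config)


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

_CLAMP = 1e-7


def focal_loss(
    probabilities: np.ndarray,
    targets: np.ndarray,
    alpha: float = 0.25,
    gamma: float = 2.0,
) -> float:
    """Mean focal loss ``-alpha * (1 - p_t)^gamma * log(p_t)``.

    ``p_t`` is the probability assigned to the true class; probabilities are
    clamped to [1e-7, 1 - 1e-7]. With ``gamma=0, alpha=1`` this is exactly
    mean binary cross-entropy.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(targets)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    p_t = np.where(t == 1, p, 1.0 - p)
    return float(np.mean(-alpha * (1.0 - p_t) ** gamma * np.log(p_t)))


def _focal_loss_and_grad(logits: np.ndarray, targets: np.ndarray,
                         alpha: float, gamma: float):
    """Loss plus its gradient with respect to the logits."""
    z = logits.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    t = targets
    p_t = np.where(t == 1, p, 1.0 - p)
    one_m = 1.0 - p_t
    log_pt = np.log(p_t)
    loss = float(np.mean(-alpha * one_m ** gamma * log_pt))
    # dL/dp_t, with the gamma=0 case reducing to -alpha/p_t
    if gamma > 0:
        dl_dpt = alpha * (gamma * one_m ** (gamma - 1.0) * log_pt
                          - one_m ** gamma / p_t)
    else:
        dl_dpt = -alpha / p_t
    dpt_dz = np.where(t == 1, p * (1.0 - p), -p * (1.0 - p))
    grad = (dl_dpt * dpt_dz / z.size).astype(np.float32)
    return loss, grad


# ---------------------------------------------------------------------------
# Transfer learning
# ---------------------------------------------------------------------------

def transfer_weights(
    net: CDLNetwork,
    source: Optional[str] = None,
    n_layers: int = 2,
    weights_path=None,
) -> CDLNetwork:
    """Initialize the first ``n_layers`` convolutions from stored source
    weights and tag them for the reduced learning rate.

    ``source='none'`` leaves the seeded random initialization untouched.
    Weights must already exist on disk as an ``.npz`` of ``conv{i}_W`` /
    ``conv{i}_b`` arrays — a missing file is an error naming the expected
    path; nothing is ever downloaded. Kernels are shape-adapted by leading
    channel-slice truncation when the network is width-scaled.
    """
    source = source or net.config.pretrained_source
    if source == "none":
        return net
    path = Path(weights_path) if weights_path else (
        Path.home() / ".mitodet" / "weights" / f"{source}_conv.npz"
    )
    if not path.exists():
        raise FileNotFoundError(
            f"pretrained {source} weights not found at {path}; place an .npz "
            "with conv{i}_W/conv{i}_b arrays there (no automatic download)"
        )
    data = np.load(path)
    for i in range(n_layers):
        conv = net.conv_layers[i]
        W = data[f"conv{i + 1}_W"]
        b = data[f"conv{i + 1}_b"]
        f, c, k, _ = conv.params["W"].shape
        conv.params["W"] = W[:f, :c, :k, :k].astype(np.float32).copy()
        conv.params["b"] = b[:f].astype(np.float32).copy()
        conv.lr_group = "pretrained"
        net._pretrained_tags.append(f"conv_{i + 1}")
    return net


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(tile: HistologyTile, rng: np.random.Generator) -> HistologyTile:
    """Flip / brightness / contrast augmentation; mask flipped identically."""
    pixels = tile.pixels.astype(float)
    mask = tile.mask
    if rng.uniform() < 0.5:
        pixels = pixels[:, ::-1]
        mask = mask[:, ::-1] if mask is not None else None
    if rng.uniform() < 0.5:
        pixels = pixels[::-1]
        mask = mask[::-1] if mask is not None else None
    pixels = pixels + rng.uniform(-20.0, 20.0)
    gain = rng.uniform(0.8, 1.2)
    pixels = (pixels - pixels.mean()) * gain + pixels.mean()
    pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
    return tile.with_pixels(
        pixels, mask=mask.copy() if mask is not None else None
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without a validation-loss
    improvement of at least ``min_delta``."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.since = 0

    def update(self, val_loss: float) -> bool:
        """Record an epoch; returns True when training should stop."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.since = 0
        else:
            self.since += 1
        return self.since >= self.patience


@dataclass
class TrainState:
    epoch: int = 0
    best_val_loss: float = np.inf
    epochs_since_improvement: int = 0
    history: list = field(default_factory=list)
    stop_reason: str = ""


def _tiles_to_arrays(tiles: Sequence[HistologyTile]):
    x = np.stack([t.pixels for t in tiles]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = np.stack([
        t.mask if t.mask is not None else np.zeros(t.pixels.shape[:2], np.uint8)
        for t in tiles
    ])[:, None].astype(np.float32)
    return x, y


def train(
    net: CDLNetwork,
    train_tiles: Sequence[HistologyTile],
    val_tiles: Sequence[HistologyTile],
    config: Optional[CDLConfig] = None,
    augment_train: bool = True,
) -> TrainState:
    """Train with focal loss, Adam (two-rate schedule), plateau LR
    reduction, and early stopping on validation loss."""
    config = config or net.config
    if not train_tiles or not val_tiles:
        raise ValueError("need at least one tile per split")
    rng = np.random.default_rng([config.seed, 93])
    opt = Adam(
        net.param_layers(),
        lr_groups={"new": config.lr_new, "pretrained": config.lr_pretrained},
        weight_decay=config.l2,
    )
    stopper = EarlyStopper(config.patience)
    state = TrainState()
    xv, yv = _tiles_to_arrays(val_tiles)
    plateau_since, plateau_best = 0, np.inf

    for epoch in range(1, config.max_epochs + 1):
        state.epoch = epoch
        order = rng.permutation(len(train_tiles))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_tiles[i] for i in order[start:start + config.batch_size]]
            if augment_train:
                batch = [augment(t, rng) for t in batch]
            xb, yb = _tiles_to_arrays(batch)
            logits = net.forward(xb, train=True)
            loss, grad = _focal_loss_and_grad(
                logits, yb, config.focal_alpha, config.focal_gamma
            )
            if not np.isfinite(loss):
                state.stop_reason = "divergence"
                raise RuntimeError(
                    f"training diverged (non-finite loss at epoch {epoch}); "
                    f"state: {state}"
                )
            net.backward(grad)
            opt.step()
            losses.append(loss)

        val_logits = net.forward(xv, train=False)
        val_loss, _ = _focal_loss_and_grad(
            val_logits, yv, config.focal_alpha, config.focal_gamma
        )
        val_prob = 1.0 / (1.0 + np.exp(-val_logits))
        pred = val_prob > 0.5
        tp = np.sum(pred & (yv == 1))
        denom = 2 * tp + np.sum(pred & (yv == 0)) + np.sum(~pred & (yv == 1))
        val_f1 = float(2 * tp / denom) if denom > 0 else 0.0
        state.history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": float(val_loss),
            "val_f1": val_f1,
            "lr_scale": opt.scale,
        })

        if val_loss < state.best_val_loss:
            state.best_val_loss = float(val_loss)
            state.epochs_since_improvement = 0
        else:
            state.epochs_since_improvement += 1

        # plateau-based learning-rate reduction (relative threshold)
        if val_loss < plateau_best * (1.0 - 1e-3):
            plateau_best, plateau_since = val_loss, 0
        else:
            plateau_since += 1
            if plateau_since >= config.plateau_patience:
                opt.scale *= 0.5
                plateau_since = 0

        if stopper.update(val_loss):
            state.stop_reason = "early_stopping"
            break
    else:
        state.stop_reason = "max_epochs"
    net.trained = True
    return state


# ---------------------------------------------------------------------------
# Inference and detection post-processing
# ---------------------------------------------------------------------------

def predict_segmentation(net: CDLNetwork, tile: HistologyTile) -> np.ndarray:
    """Per-pixel mitosis probability map, same spatial shape as the tile."""
    if not net.trained:
        warnings.warn("predicting with an untrained network", stacklevel=2)
    x = tile.pixels.astype(np.float32)[None].transpose(0, 3, 1, 2) / 255.0
    logits = net.forward(x, train=False)
    return (1.0 / (1.0 + np.exp(-logits)))[0, 0]


def postprocess_detections(
    prob_map: np.ndarray, threshold: float = 0.5, min_area: int = 10
) -> list:
    """Threshold, label 8-connected components, drop those below
    ``min_area``, and return centroid/area/mean-score records sorted by
    score descending."""
    binary = np.asarray(prob_map) > threshold
    labeled = measure.label(binary, connectivity=2)
    detections = []
    for rp in measure.regionprops(labeled, intensity_image=prob_map):
        if rp.area < min_area:
            continue
        detections.append({
            "centroid": (float(rp.centroid[0]), float(rp.centroid[1])),
            "area": int(rp.area),
            "score": float(rp.intensity_mean),
        })
    detections.sort(key=lambda d: -d["score"])
    return detections


def match_detections(detections: list, truth_mask: np.ndarray):
    """Centroid-within-mask matching: a detection is a true positive when
    its centroid falls inside a not-yet-matched truth component. Returns
    (tp, fp, fn)."""
    labeled = measure.label(truth_mask, connectivity=2)
    n_truth = labeled.max()
    matched = set()
    tp = fp = 0
    for det in detections:
        r, c = (int(round(v)) for v in det["centroid"])
        lab = 0
        if 0 <= r < labeled.shape[0] and 0 <= c < labeled.shape[1]:
            lab = int(labeled[r, c])
        if lab > 0 and lab not in matched:
            matched.add(lab)
            tp += 1
        else:
            fp += 1
    return tp, fp, int(n_truth) - len(matched)


def detection_f1(pairs) -> float:
    """Pooled object-level F1 over (detections, truth_mask) pairs."""
    tp = fp = fn = 0
    for dets, mask in pairs:
        a, b, c = match_detections(dets, mask)
        tp, fp, fn = tp + a, fp + b, fn + c
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: CDLNetwork, path) -> None:
    """Single-file archive of named weight arrays plus the config echo."""
    arrays = {}
    for i, layer in enumerate(net.param_layers()):
        for name, p in layer.params.items():
            arrays[f"layer{i:03d}_{name}"] = p
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(net.config)).encode(), dtype=np.uint8
    )
    arrays["trained"] = np.array([int(net.trained)])
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> CDLNetwork:
    data = np.load(path)
    config = CDLConfig(**json.loads(bytes(data["config_json"]).decode()))
    net = build_cdl(config)
    for i, layer in enumerate(net.param_layers()):
        for name in layer.params:
            layer.params[name] = data[f"layer{i:03d}_{name}"].copy()
    net.trained = bool(data["trained"][0])
    return net
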