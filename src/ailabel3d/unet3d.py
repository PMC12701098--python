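"""Dual-modality 3D U-Net for supervised tumor segmentation.

The network takes stacked T1/T2 channels and returns a per-voxel tumor
probability.  It is trained twice in the label-reliability study — once on
expert labels (EL), once on AI-assisted labels (AI-L) — with Adam, Xavier
initialisation and the shared flip/rotation augmentation.  The training loss
is the soft Dice loss, the standard choice for heavily imbalanced tumor
masks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError
from .io_prep import CohortSplit, VolumePair
from .nn import Adam, ChannelNorm, Conv3d, MaxPool2x, ReLU, Sequential, UpsampleNearest2x

__all__ = [
    "UNetConfig",
    "TrainedSegmenter",
    "UNet3D",
    "build_unet",
    "soft_dice_loss",
    "train_supervised",
    "predict",
]


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 2
    depth: int = 4
    base_width: int = 16
    lr: float = 0.001
    batch_size: int = 4
    flip_prob: float = 0.3
    max_rot_deg: float = 15.0
    max_epochs: int = 50
    patience: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if self.in_channels != 2:
            raise ValueError("this model is two-modality by contract: in_channels must be 2")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


class _ConvBlock:
    """conv3d -> ReLU -> channel norm."""

    def __init__(self, c_in, c_out, rng):
        self.seq = Sequential([Conv3d(c_in, c_out, 3, rng), ReLU(), ChannelNorm(c_out)])

    def params(self):
        return self.seq.params()

    def forward(self, x, train=True):
        return self.seq.forward(x, train=train)

    def backward(self, dy):
        return self.seq.backward(dy)


class UNet3D:
    """Encoder-decoder with skip connections; single conv block per level,
    2x max pooling, nearest-neighbour upsampling, sigmoid output."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        widths = [config.base_width * 2 ** i for i in range(config.depth)]
        self.enc = []
        c_in = config.in_channels
        for w in widths:
            self.enc.append(_ConvBlock(c_in, w, rng))
            c_in = w
        self.pools = [MaxPool2x() for _ in range(config.depth - 1)]
        self.ups = [UpsampleNearest2x() for _ in range(config.depth - 1)]
        self.dec = []
        for i in range(config.depth - 2, -1, -1):
            # input: upsampled deeper features + skip at this level
            self.dec.append(_ConvBlock(widths[i + 1] + widths[i], widths[i], rng))
        self.head = Conv3d(widths[0], 1, 1, rng)

    def params(self):
        ps = []
        for block in self.enc + self.dec:
            ps.extend(block.params())
        ps.extend(self.head.params())
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (2, H, W, D) -> per-voxel tumor probability (1, H, W, D)."""
        if x.ndim != 4 or x.shape[0] != self.config.in_channels:
            raise ValueError(f"expected ({self.config.in_channels}, H, W, D) input, got {x.shape}")
        div = 2 ** (self.config.depth - 1)
        if any(s % div for s in x.shape[1:]):
            raise ValueError(f"spatial dims {x.shape[1:]} must be divisible by {div}")
        x = x.astype(np.float32)
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x, train=train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train=train)
        self._skip_channels = []
        for i, block in enumerate(self.dec):
            level = len(self.dec) - 1 - i
            x = self.ups[level].forward(x, train=train)
            skip = skips[level]
            x = np.concatenate([x, skip], axis=0)
            self._skip_channels.append(x.shape[0] - skip.shape[0])
            x = block.forward(x, train=train)
        logits = self.head.forward(x, train=train)
        prob = 1.0 / (1.0 + np.exp(-logits))
        if train:
            self._prob = prob
        return prob

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate a gradient with respect to the output probability."""
        dy = dprob * self._prob * (1.0 - self._prob)  # through the sigmoid
        dy = self.head.backward(dy.astype(np.float32))
        dskips = [None] * len(self.enc)
        for i in range(len(self.dec) - 1, -1, -1):
            level = len(self.dec) - 1 - i
            dcat = self.dec[i].backward(dy)
            c_up = self._skip_channels[i]
            dskips[level] = dcat[c_up:]
            dy = self.ups[level].backward(dcat[:c_up])
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
                dy = dy + dskips[i]
            dy = self.enc[i].backward(dy)


@dataclass
class TrainedSegmenter:
    net: UNet3D
    label_source: str  # "EL" or "AI-L"
    history: list[tuple[int, float, float]] = field(default_factory=list)


def build_unet(config: UNetConfig = UNetConfig()) -> UNet3D:
    """Xavier-initialised dual-input U-Net; deterministic given ``config.rng_seed``."""
    return UNet3D(config)


def soft_dice_loss(prob: np.ndarray, target: np.ndarray, smooth: float = 1.0):
    """1 − soft Dice between probabilities and a binary target, with its gradient."""
    p = prob.astype(np.float64)
    t = target.astype(np.float64)
    inter = (p * t).sum()
    denom = p.sum() + t.sum() + smooth
    num = 2.0 * inter + smooth
    loss = 1.0 - num / denom
    grad = num / denom ** 2 - 2.0 * t / denom
    return float(loss), grad


def _stack(pair: VolumePair) -> np.ndarray:
    return np.stack([pair.t1, pair.t2]).astype(np.float32)


def _augment_case(t1, t2, label, flip_prob, max_rot_deg, rng):
    if flip_prob > 0 and rng.random() < flip_prob:
        t1, t2, label = t1[:, ::-1, :], t2[:, ::-1, :], label[:, ::-1, :]
    if max_rot_deg > 0:
        angle = rng.uniform(-max_rot_deg, max_rot_deg)
        rot = dict(axes=(0, 1), reshape=False, mode="nearest")
        t1 = ndimage.rotate(t1, angle, order=1, **rot)
        t2 = ndimage.rotate(t2, angle, order=1, **rot)
        label = ndimage.rotate(label.astype(np.uint8), angle, order=0, **rot)
    return (np.ascontiguousarray(t1), np.ascontiguousarray(t2),
            np.ascontiguousarray(label))


def train_supervised(
    cohort: list[tuple[VolumePair, np.ndarray]],
    split: CohortSplit,
    config: UNetConfig = UNetConfig(),
    label_source: str = "EL",
) -> TrainedSegmenter:
    """Adam training of the U-Net on the split's train partition.

    Early stopping monitors the validation soft Dice loss (training loss when
    the validation partition is empty); the best-validation weights are
    restored at the end.  Deterministic given ``config.rng_seed``.
    """
    by_id = {pair.case_id: (pair, np.asarray(label)) for pair, label in cohort}
    for pair, label in cohort:
        if label.shape != pair.shape:
            raise ValueError(f"label shape {label.shape} != volume shape {pair.shape}")
    train_cases = [by_id[c] for c in split.train]
    val_cases = [by_id[c] for c in split.val]
    if not train_cases:
        raise ValueError("empty train partition")
    if not any(label.any() for _, label in train_cases):
        raise DegenerateInputError("all training labels are empty: nothing to learn")

    net = UNet3D(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    opt = Adam(net.params(), lr=config.lr)
    history: list[tuple[int, float, float]] = []
    best_val = np.inf
    best_params = None
    since_improvement = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_cases))
        losses = []
        for start in range(0, len(train_cases), config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            for idx in batch:
                pair, label = train_cases[idx]
                t1, t2, lab = _augment_case(pair.t1, pair.t2, label,
                                            config.flip_prob, config.max_rot_deg, rng)
                prob = net.forward(np.stack([t1, t2]).astype(np.float32), train=True)
                loss, dprob = soft_dice_loss(prob[0], lab)
                losses.append(loss)
                net.backward(dprob[None] / len(batch))
            opt.step()
        train_loss = float(np.mean(losses))

        if val_cases:
            val_losses = []
            for pair, label in val_cases:
                prob = net.forward(_stack(pair), train=False)
                val_losses.append(soft_dice_loss(prob[0], label)[0])
            val_loss = float(np.mean(val_losses))
        else:
            val_loss = train_loss
        history.append((epoch, train_loss, val_loss))

        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.value.copy() for p in net.params()]
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= config.patience:
                break

    if best_params is not None:
        for p, v in zip(net.params(), best_params):
            p.value[...] = v
    return TrainedSegmenter(net=net, label_source=label_source, history=history)


def predict(model: TrainedSegmenter, pair: VolumePair, threshold: float = 0.5) -> np.ndarray:
    """Binary tumor mask: voxel probability >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly in (0, 1)")
    prob = model.net.forward(_stack(pair), train=False)
    return (prob[0] >= threshold).astype(np.uint8)
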