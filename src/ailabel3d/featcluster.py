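"""Unsupervised multi-modal 3D segmentation by differentiable feature clustering.

Two parallel 3D CNN branches (no shared weights) extract modality-specific
features from the T1- and T2-weighted volumes; the concatenated per-voxel
embedding is normalised and treated as a response map.  Each voxel's cluster
is the argmax channel of its response.  Training minimises a self-labelling
cross-entropy between the response map and its own argmax labels plus an
L1 spatial-continuity penalty over the three spatial axes, weighted by ``mu``.
Clusters are merged adaptively in the sense that channels which stop winning
any voxel's argmax simply disappear from the label maps; the training history
tracks that count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, NumericError
from .io_prep import VolumePair
from .nn import ChannelNorm, Conv3d, ReLU, SGD, Sequential

__all__ = [
    "BranchConfig",
    "ClusterTrainConfig",
    "TrainState",
    "DualBranchNet",
    "build_model",
    "forward_embed",
    "assign_clusters",
    "similarity_loss",
    "continuity_loss",
    "total_loss",
    "train_unsupervised",
    "count_active_clusters",
    "EarlyStopper",
]


@dataclass(frozen=True)
class BranchConfig:
    """Architecture of one CNN branch; the two branches are structurally identical."""

    n_blocks: int = 3
    features_per_branch: int = 30
    kernel_size: int = 3
    q_total: int = 60

    def __post_init__(self):
        if self.features_per_branch < 1:
            raise ValueError("features_per_branch must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if 2 * self.features_per_branch != self.q_total:
            raise ValueError("q_total must equal 2 * features_per_branch")


@dataclass(frozen=True)
class ClusterTrainConfig:
    mu: float = 1.0
    lr: float = 0.001
    momentum: float = 0.9
    batch_size: int = 4
    patience: int = 10
    max_epochs: int = 200
    flip_prob: float = 0.3
    max_rot_deg: float = 15.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainState:
    epoch: int
    loss: float
    n_active_clusters: int
    best_loss: float
    epochs_since_improvement: int


class DualBranchNet:
    """Two independent conv branches followed by a normalised concatenated embedding.

    Each branch is ``n_blocks`` of (conv3d, same padding, stride 1) -> ReLU ->
    channel norm, except that the final block omits the ReLU so the embedding
    entering the clustering stage is not clipped at zero.
    """

    def __init__(self, config: BranchConfig, rng_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(rng_seed)
        self.branch_t1 = self._make_branch(config, rng)
        self.branch_t2 = self._make_branch(config, rng)
        self.final_norm = ChannelNorm(config.q_total)

    @staticmethod
    def _make_branch(config: BranchConfig, rng: np.random.Generator) -> Sequential:
        layers = []
        c_in = 1
        for block in range(config.n_blocks):
            layers.append(Conv3d(c_in, config.features_per_branch, config.kernel_size, rng))
            if block < config.n_blocks - 1:
                layers.append(ReLU())
            layers.append(ChannelNorm(config.features_per_branch))
            c_in = config.features_per_branch
        return Sequential(layers)

    def params(self):
        return self.branch_t1.params() + self.branch_t2.params() + self.final_norm.params()

    def forward(self, t1: np.ndarray, t2: np.ndarray, train: bool = True) -> np.ndarray:
        if t1.shape != t2.shape:
            raise ValueError(f"modality shape mismatch: {t1.shape} vs {t2.shape}")
        f1 = self.branch_t1.forward(t1[None].astype(np.float32), train=train)
        f2 = self.branch_t2.forward(t2[None].astype(np.float32), train=train)
        z = np.concatenate([f1, f2], axis=0)
        return self.final_norm.forward(z, train=train)

    def backward(self, dresponse: np.ndarray) -> None:
        dz = self.final_norm.backward(dresponse)
        half = self.config.features_per_branch
        self.branch_t1.backward(dz[:half])
        self.branch_t2.backward(dz[half:])


def build_model(config: BranchConfig = BranchConfig(), rng_seed: int = 0) -> DualBranchNet:
    """Xavier-initialised dual-branch model; deterministic given ``rng_seed``."""
    return DualBranchNet(config, rng_seed=rng_seed)


def forward_embed(pair: VolumePair, model: DualBranchNet) -> np.ndarray:
    """Evaluate the model on one case; returns the (q, H, W, D) response map."""
    return model.forward(pair.t1, pair.t2, train=False)


def assign_clusters(response: np.ndarray) -> np.ndarray:
    """Per-voxel argmax over the channel axis; ties break to the lowest channel."""
    if response.ndim != 4:
        raise ValueError(f"response must be (q, H, W, D), got rank {response.ndim}")
    if np.isnan(response).any():
        raise NumericError("NaN in response map")
    return response.argmax(axis=0).astype(np.int32)


def _check_labels(response: np.ndarray, labels: np.ndarray) -> None:
    q = response.shape[0]
    if labels.shape != response.shape[1:]:
        raise ValueError("labels shape must match response spatial shape")
    if labels.min() < 0 or labels.max() >= q:
        raise ValueError(f"labels must lie in [0, {q})")


def similarity_loss(response: np.ndarray, labels: np.ndarray) -> float:
    """Self-labelling cross-entropy: mean over voxels of −log softmax(response)[label]."""
    loss, _ = _similarity_loss_grad(response, labels, need_grad=False)
    return loss


def _similarity_loss_grad(response, labels, need_grad=True):
    _check_labels(response, labels)
    q = response.shape[0]
    flat = response.reshape(q, -1)  # computed in the response's dtype
    lab = labels.reshape(-1)
    n = lab.size
    idx = np.arange(n)
    m = flat.max(axis=0)
    ex = np.exp(flat - m)
    z = ex.sum(axis=0)
    loss = float((np.log(z) - (flat[lab, idx] - m)).mean())
    if not need_grad:
        return loss, None
    grad = ex
    grad /= z
    grad[lab, idx] -= 1.0
    grad /= n
    return loss, grad.reshape(response.shape)


def continuity_loss(response: np.ndarray) -> float:
    """Mean absolute forward difference of the response along the three spatial axes."""
    loss, _ = _continuity_loss_grad(response, need_grad=False)
    return loss


def _continuity_loss_grad(response, need_grad=True):
    if response.ndim != 4:
        raise ValueError(f"response must be (q, H, W, D), got rank {response.ndim}")
    q, h, w, d = response.shape
    n_pairs = q * ((h - 1) * w * d + h * (w - 1) * d + h * w * (d - 1))
    if n_pairs == 0:
        raise DegenerateInputError("all spatial dimensions < 2: no neighbor pairs")
    r = response
    total = 0.0
    grad = np.zeros_like(r) if need_grad else None
    for axis in (1, 2, 3):
        diff = np.diff(r, axis=axis)
        total += np.abs(diff).sum()
        if need_grad:
            s = np.sign(diff)
            sl_hi = [slice(None)] * 4
            sl_lo = [slice(None)] * 4
            sl_hi[axis] = slice(1, None)
            sl_lo[axis] = slice(None, -1)
            grad[tuple(sl_hi)] += s
            grad[tuple(sl_lo)] -= s
    loss = total / n_pairs
    if need_grad:
        grad /= n_pairs
    return loss, grad


def total_loss(response: np.ndarray, labels: np.ndarray, mu: float = 1.0) -> float:
    """Similarity loss plus ``mu`` times continuity loss."""
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return similarity_loss(response, labels) + mu * continuity_loss(response)


def count_active_clusters(cluster_maps) -> int:
    """Number of distinct cluster labels across all maps."""
    maps = list(cluster_maps)
    if not maps:
        raise ValueError("empty list of cluster maps")
    labels: set[int] = set()
    for m in maps:
        labels.update(np.unique(m).tolist())
    return len(labels)


class EarlyStopper:
    """Stops when the monitored loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.epochs_since_improvement = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; returns True when training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.epochs_since_improvement = 0
        else:
            self.epochs_since_improvement += 1
        return self.epochs_since_improvement >= self.patience


def _augment(t1: np.ndarray, t2: np.ndarray, flip_prob: float, max_rot_deg: float,
             rng: np.random.Generator):
    """Joint augmentation of both modalities: horizontal flip along the W axis
    and in-plane rotation about the depth axis."""
    if flip_prob > 0 and rng.random() < flip_prob:
        t1 = t1[:, ::-1, :]
        t2 = t2[:, ::-1, :]
    if max_rot_deg > 0:
        angle = rng.uniform(-max_rot_deg, max_rot_deg)
        t1 = ndimage.rotate(t1, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
        t2 = ndimage.rotate(t2, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
    return np.ascontiguousarray(t1), np.ascontiguousarray(t2)


def train_unsupervised(
    cohort: list[VolumePair],
    config: ClusterTrainConfig = ClusterTrainConfig(),
    model_config: BranchConfig = BranchConfig(),
) -> tuple[DualBranchNet, list[TrainState]]:
    """SGD training of the dual-branch clustering model on a cohort.

    Per sample: augment, forward, take the argmax labels of the same pass as
    constant cross-entropy targets, and backpropagate the combined loss.  The
    per-epoch history records the mean training loss and the number of active
    clusters over the (un-augmented) cohort; early stopping monitors the
    training loss with the configured patience.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    shapes = {pair.shape for pair in cohort}
    if len(shapes) != 1:
        raise ValueError(f"all volumes must share one shape, got {shapes}")

    model = build_model(model_config, rng_seed=config.rng_seed)
    root = np.random.SeedSequence(config.rng_seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    opt = SGD(model.params(), lr=config.lr, momentum=config.momentum)
    stopper = EarlyStopper(config.patience)
    history: list[TrainState] = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(cohort))
        epoch_losses = []
        for start in range(0, len(cohort), config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            for idx in batch:
                pair = cohort[idx]
                t1, t2 = _augment(pair.t1, pair.t2, config.flip_prob, config.max_rot_deg, rng)
                response = model.forward(t1, t2, train=True)
                labels = assign_clusters(response)
                sim, dsim = _similarity_loss_grad(response, labels)
                cont, dcont = _continuity_loss_grad(response)
                epoch_losses.append(sim + config.mu * cont)
                dresp = (dsim + config.mu * dcont) / len(batch)
                model.backward(dresp.astype(np.float32))
            opt.step()

        maps = [assign_clusters(forward_embed(pair, model)) for pair in cohort]
        n_active = count_active_clusters(maps)
        loss = float(np.mean(epoch_losses))
        stop = stopper.update(loss)
        history.append(TrainState(
            epoch=epoch,
            loss=loss,
            n_active_clusters=n_active,
            best_loss=float(stopper.best_loss),
            epochs_since_improvement=stopper.epochs_since_improvement,
        ))
        if stop:
            break
    return model, history
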