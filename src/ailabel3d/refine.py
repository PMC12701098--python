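"""Seed-driven, cluster-aware refinement of the unsupervised segmentation.

The per-modality expert masks are combined by element-wise addition and the
result is multiplied with the cluster map to isolate the tumor region.  Random
seeds placed in that region (stratified over the cluster labels it contains,
mimicking expert clicks) are grown into connected components of equal cluster
label; components larger than ``max_volume_factor`` times the estimated tumor
volume are discarded; the surviving masks are summed into the final
AI-assisted label (AI-L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError

__all__ = [
    "SeedSet",
    "GrownMask",
    "FilterCriteria",
    "OUTSIDE",
    "isolate_tumor_region",
    "place_seeds",
    "region_grow",
    "filter_masks",
    "compose_ai_label",
    "generate_ai_label",
]

#: Sentinel cluster value for voxels outside the isolated region.
OUTSIDE = -1


@dataclass
class SeedSet:
    seeds: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class GrownMask:
    mask: np.ndarray
    seed: tuple[int, int, int]
    cluster_label: int
    volume: int


@dataclass(frozen=True)
class FilterCriteria:
    max_volume_factor: float = 3.0
    tumor_volume_estimate: int = 1

    def __post_init__(self):
        if self.max_volume_factor <= 0:
            raise ValueError("max_volume_factor must be > 0")
        if self.tumor_volume_estimate < 1:
            raise ValueError("tumor_volume_estimate must be >= 1")


def _structure(connectivity: int):
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def isolate_tumor_region(el_t1: np.ndarray, el_t2: np.ndarray, clusters: np.ndarray):
    """Combine the expert masks (addition, then > 0) and mask the cluster map.

    Returns ``(masked_clusters, region)`` where voxels outside the region carry
    the sentinel value ``OUTSIDE``.
    """
    el_t1 = np.asarray(el_t1)
    el_t2 = np.asarray(el_t2)
    clusters = np.asarray(clusters)
    if not (el_t1.shape == el_t2.shape == clusters.shape):
        raise ValueError(f"shape mismatch: {el_t1.shape}, {el_t2.shape}, {clusters.shape}")
    region = (el_t1.astype(np.int64) + el_t2.astype(np.int64)) > 0
    if not region.any():
        raise DegenerateInputError("no expert label present: empty region")
    masked = np.where(region, clusters, OUTSIDE).astype(np.int64)
    return masked, region.astype(np.uint8)


def place_seeds(region: np.ndarray, clusters: np.ndarray, n_seeds: int = 5,
                rng_seed: int = 0) -> SeedSet:
    """Sample seed voxels inside the region without replacement, stratified so
    that every cluster label occurring in the region gets a seed when
    ``n_seeds`` permits."""
    region = np.asarray(region).astype(bool)
    clusters = np.asarray(clusters)
    if region.shape != clusters.shape:
        raise ValueError("region and clusters must share one shape")
    if not region.any():
        raise DegenerateInputError("empty region")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    coords = np.argwhere(region)
    if n_seeds > len(coords):
        raise ValueError(f"n_seeds={n_seeds} exceeds region size {len(coords)}")

    rng = np.random.default_rng(rng_seed)
    region_labels = clusters[region]
    labels = np.unique(region_labels)
    rng.shuffle(labels)

    chosen: list[int] = []
    taken = np.zeros(len(coords), dtype=bool)
    # one seed per cluster label, in shuffled label order, while seeds remain
    for lab in labels[:n_seeds]:
        candidates = np.flatnonzero((region_labels == lab) & ~taken)
        pick = int(rng.choice(candidates))
        chosen.append(pick)
        taken[pick] = True
    # fill any remainder uniformly over untaken region voxels
    remaining = n_seeds - len(chosen)
    if remaining > 0:
        free = np.flatnonzero(~taken)
        chosen.extend(int(i) for i in rng.choice(free, size=remaining, replace=False))
    return SeedSet(seeds=[tuple(int(c) for c in coords[i]) for i in chosen])


def region_grow(clusters: np.ndarray, seed: tuple[int, int, int],
                connectivity: int = 6) -> GrownMask:
    """The connected component of voxels sharing the seed's cluster label.

    Growth is driven purely by cluster labels (not intensity) and may extend
    beyond the isolated region; the volume filter handles over-growth.
    """
    clusters = np.asarray(clusters)
    seed = tuple(int(c) for c in seed)
    if len(seed) != 3 or any(c < 0 or c >= s for c, s in zip(seed, clusters.shape)):
        raise ValueError(f"seed {seed} out of bounds for shape {clusters.shape}")
    label = int(clusters[seed])
    same = clusters == label
    comp, _ = ndimage.label(same, structure=_structure(connectivity))
    mask = (comp == comp[seed]).astype(np.uint8)
    return GrownMask(mask=mask, seed=seed, cluster_label=label, volume=int(mask.sum()))


def filter_masks(masks: list[GrownMask], criteria: FilterCriteria) -> list[GrownMask]:
    """Drop duplicate components, then keep masks whose volume does not exceed
    ``max_volume_factor`` x the tumor volume estimate (inclusive)."""
    limit = criteria.max_volume_factor * criteria.tumor_volume_estimate
    unique: list[GrownMask] = []
    for m in masks:
        if any(u.cluster_label == m.cluster_label and u.mask[m.seed] for u in unique):
            continue  # same component already reached from an earlier seed
        unique.append(m)
    return [m for m in unique if m.volume <= limit]


def compose_ai_label(valid_masks: list[GrownMask]) -> np.ndarray:
    """Voxelwise union of the retained masks (sum, clipped to {0,1})."""
    if not valid_masks:
        raise DegenerateInputError("no valid mask to compose")
    shapes = {m.mask.shape for m in valid_masks}
    if len(shapes) != 1:
        raise ValueError(f"masks must share one shape, got {shapes}")
    total = np.zeros(valid_masks[0].mask.shape, dtype=np.int64)
    for m in valid_masks:
        total += m.mask
    return (total > 0).astype(np.uint8)


def generate_ai_label(
    clusters: np.ndarray,
    el_t1: np.ndarray,
    el_t2: np.ndarray,
    n_seeds: int = 5,
    max_volume_factor: float = 3.0,
    rng_seed: int = 0,
    connectivity: int = 6,
) -> tuple[np.ndarray, dict]:
    """Full refinement pipeline: isolate -> seed -> grow -> filter -> compose.

    The tumor volume estimate for the filter is the voxel count of the
    combined expert region.  If no grown mask survives the filter, the
    combined expert region itself is returned and flagged in the provenance.
    Returns ``(ai_label, provenance)``.
    """
    masked, region = isolate_tumor_region(el_t1, el_t2, clusters)
    region_volume = int(region.sum())
    n_seeds = min(n_seeds, region_volume)
    seed_set = place_seeds(region, clusters, n_seeds=n_seeds, rng_seed=rng_seed)
    grown = [region_grow(clusters, s, connectivity=connectivity) for s in seed_set.seeds]
    criteria = FilterCriteria(max_volume_factor=max_volume_factor,
                              tumor_volume_estimate=region_volume)
    retained = filter_masks(grown, criteria)
    retained_ids = {id(m) for m in retained}

    provenance = {
        "seeds": [list(s) for s in seed_set.seeds],
        "tumor_volume_estimate": region_volume,
        "max_volume_factor": max_volume_factor,
        "masks": [
            {
                "seed": list(m.seed),
                "cluster_label": m.cluster_label,
                "volume": m.volume,
                "retained": id(m) in retained_ids,
            }
            for m in grown
        ],
        "fallback_expert_region": False,
    }
    if retained:
        ai_label = compose_ai_label(retained)
    else:
        ai_label = region.astype(np.uint8)
        provenance["fallback_expert_region"] = True
    return ai_label, provenance
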