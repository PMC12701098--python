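from collections import deque

import numpy as np
import pytest

from ailabel3d.errors import DegenerateInputError
from ailabel3d.refine import (
    OUTSIDE,
    FilterCriteria,
    GrownMask,
    compose_ai_label,
    filter_masks,
    generate_ai_label,
    isolate_tumor_region,
    place_seeds,
    region_grow,
)


def bfs_component(clusters, seed):
    """Breadth-first-search oracle for the 6-connected equal-label component."""
    label = clusters[seed]
    mask = np.zeros(clusters.shape, dtype=np.uint8)
    mask[seed] = 1
    queue = deque([seed])
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < clusters.shape[0] and 0 <= ny < clusters.shape[1] \
                    and 0 <= nz < clusters.shape[2]:
                if not mask[nx, ny, nz] and clusters[nx, ny, nz] == label:
                    mask[nx, ny, nz] = 1
                    queue.append((nx, ny, nz))
    return mask


class TestIsolateTumorRegion:
    def test_single_voxel_region(self):
        clusters = np.arange(8).reshape(2, 2, 2)
        el = np.zeros((2, 2, 2), dtype=np.uint8)
        el[1, 0, 1] = 1
        masked, region = isolate_tumor_region(el, el, clusters)
        assert region.sum() == 1
        assert masked[1, 0, 1] == clusters[1, 0, 1]
        assert (masked[region == 0] == OUTSIDE).all()

    def test_disjoint_expert_masks_union(self):
        clusters = np.zeros((3, 3, 1), dtype=int)
        el1 = np.zeros_like(clusters, dtype=np.uint8)
        el2 = np.zeros_like(clusters, dtype=np.uint8)
        el1[0, 0, 0] = 1
        el2[2, 2, 0] = 1
        _, region = isolate_tumor_region(el1, el2, clusters)
        assert region.sum() == 2
        assert region[0, 0, 0] and region[2, 2, 0]

    def test_full_masks_keep_clusters_identical(self):
        clusters = np.arange(12).reshape(2, 3, 2)
        full = np.ones_like(clusters, dtype=np.uint8)
        masked, _ = isolate_tumor_region(full, full, clusters)
        np.testing.assert_array_equal(masked, clusters)

    def test_shape_mismatch_and_empty_region(self):
        clusters = np.zeros((2, 2, 2), dtype=int)
        with pytest.raises(ValueError):
            isolate_tumor_region(np.zeros((2, 2, 1)), np.zeros((2, 2, 2)), clusters)
        with pytest.raises(DegenerateInputError):
            isolate_tumor_region(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), clusters)


class TestPlaceSeeds:
    def test_forced_single_voxel(self):
        region = np.zeros((3, 3, 2), dtype=np.uint8)
        region[1, 2, 0] = 1
        seeds = place_seeds(region, np.zeros((3, 3, 2), dtype=int), n_seeds=1, rng_seed=0)
        assert seeds.seeds == [(1, 2, 0)]

    def test_stratified_across_cluster_labels(self):
        clusters = np.zeros((4, 4, 1), dtype=int)
        clusters[2:] = 4
        clusters[:2] = 1
        region = np.ones_like(clusters, dtype=np.uint8)
        seeds = place_seeds(region, clusters, n_seeds=2, rng_seed=3)
        labels = {clusters[s] for s in seeds.seeds}
        assert labels == {1, 4}

    def test_deterministic_and_without_replacement(self):
        rng = np.random.default_rng(0)
        clusters = rng.integers(0, 3, size=(6, 6, 3))
        region = (rng.random((6, 6, 3)) < 0.5).astype(np.uint8)
        region[0, 0, 0] = 1
        a = place_seeds(region, clusters, n_seeds=5, rng_seed=9)
        b = place_seeds(region, clusters, n_seeds=5, rng_seed=9)
        assert a.seeds == b.seeds
        assert len(set(a.seeds)) == 5
        assert all(region[s] for s in a.seeds)

    def test_too_many_seeds_rejected(self):
        region = np.zeros((2, 2, 2), dtype=np.uint8)
        region[0, 0, 0] = 1
        with pytest.raises(ValueError):
            place_seeds(region, np.zeros((2, 2, 2), dtype=int), n_seeds=2)


class TestRegionGrow:
    def test_uniform_map_grows_to_whole_volume(self):
        grown = region_grow(np.zeros((4, 4, 2), dtype=int), (1, 1, 1))
        assert grown.volume == 32
        assert grown.mask.all()

    def test_two_blobs_same_label_stay_separate(self):
        clusters = np.ones((7, 3, 1), dtype=int)
        clusters[0:2] = 5
        clusters[5:7] = 5
        grown = region_grow(clusters, (0, 0, 0))
        np.testing.assert_array_equal(grown.mask, bfs_component(clusters, (0, 0, 0)))
        assert grown.volume == 6

    def test_isolated_single_voxel_cluster(self):
        clusters = np.zeros((3, 3, 3), dtype=int)
        clusters[1, 1, 1] = 9
        grown = region_grow(clusters, (1, 1, 1))
        assert grown.volume == 1
        assert grown.cluster_label == 9

    def test_out_of_bounds_seed_rejected(self):
        with pytest.raises(ValueError):
            region_grow(np.zeros((2, 2, 2), dtype=int), (2, 0, 0))

    def test_matches_bfs_oracle_on_random_maps(self):
        """Exact mask equality against breadth-first search on 1000 random maps."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            clusters = rng.integers(0, 4, size=(8, 8, 4))
            seed = tuple(int(v) for v in (rng.integers(8), rng.integers(8), rng.integers(4)))
            grown = region_grow(clusters, seed)
            np.testing.assert_array_equal(grown.mask, bfs_component(clusters, seed))
            assert grown.volume == int(grown.mask.sum())
            assert grown.mask[seed]


def _mask_of_volume(volume, shape=(10, 10, 10), label=0, seed_at=None):
    mask = np.zeros(shape, dtype=np.uint8)
    flat = mask.reshape(-1)
    flat[:volume] = 1
    seed = seed_at or (0, 0, 0)
    return GrownMask(mask=mask, seed=seed, cluster_label=label, volume=volume)


class TestFilterMasks:
    def test_three_times_threshold_boundary_inclusive(self):
        masks = [_mask_of_volume(10, label=1), _mask_of_volume(29, label=2),
                 _mask_of_volume(31, label=3), _mask_of_volume(30, label=4)]
        out = filter_masks(masks, FilterCriteria(max_volume_factor=3.0, tumor_volume_estimate=10))
        assert [m.volume for m in out] == [10, 29, 30]

    def test_duplicate_components_deduplicated(self):
        clusters = np.zeros((4, 4, 2), dtype=int)
        a = region_grow(clusters, (0, 0, 0))
        b = region_grow(clusters, (3, 3, 1))
        out = filter_masks([a, b], FilterCriteria(max_volume_factor=3.0,
                                                  tumor_volume_estimate=32))
        assert len(out) == 1

    def test_empty_input(self):
        assert filter_masks([], FilterCriteria(tumor_volume_estimate=5)) == []


class TestComposeAiLabel:
    def test_identity_idempotence_and_disjoint_union(self):
        a = _mask_of_volume(5, label=1)
        b = np.zeros((10, 10, 10), dtype=np.uint8)
        b.reshape(-1)[5:12] = 1
        gb = GrownMask(mask=b, seed=(0, 0, 0), cluster_label=2, volume=7)
        assert compose_ai_label([a]).sum() == 5
        assert compose_ai_label([a, a]).sum() == 5
        assert compose_ai_label([a, gb]).sum() == 12

    def test_empty_list_rejected(self):
        with pytest.raises(DegenerateInputError):
            compose_ai_label([])


class TestGenerateAiLabel:
    def _clean_setup(self):
        """Tumor region is exactly one cluster component coinciding with the
        expert region; everything else is another cluster."""
        clusters = np.zeros((10, 10, 6), dtype=int)
        clusters[3:7, 3:7, 2:5] = 1
        el = (clusters == 1).astype(np.uint8)
        return clusters, el

    def test_single_clean_cluster_recovered_exactly(self):
        clusters, el = self._clean_setup()
        ail, prov = generate_ai_label(clusters, el, el, n_seeds=3, rng_seed=0)
        np.testing.assert_array_equal(ail, el)
        assert not prov["fallback_expert_region"]

    def test_oversized_component_excluded(self):
        clusters, el = self._clean_setup()
        # seeding also lands in cluster 0, whose component is the whole rest of
        # the volume (> 3x the expert region) and must be dropped
        el_wide = el.copy()
        el_wide[0, 0, 0] = 1  # a stray expert voxel in the huge background cluster
        ail, prov = generate_ai_label(clusters, el_wide, el_wide, n_seeds=5, rng_seed=1)
        dropped = [m for m in prov["masks"] if not m["retained"]]
        assert any(m["cluster_label"] == 0 for m in dropped)
        assert not ail[0, 0, 0]

    def test_ai_label_is_union_of_whole_components(self):
        rng = np.random.default_rng(5)
        clusters = rng.integers(0, 3, size=(8, 8, 4))
        el = np.zeros_like(clusters, dtype=np.uint8)
        el[2:6, 2:6, 1:3] = 1
        ail, prov = generate_ai_label(clusters, el, el, n_seeds=4, rng_seed=2)
        if not prov["fallback_expert_region"]:
            for m in prov["masks"]:
                if m["retained"]:
                    comp = region_grow(clusters, tuple(m["seed"])).mask.astype(bool)
                    assert (ail.astype(bool) >= comp).all()

    def test_factor_monotonicity_for_fixed_seeds(self):
        rng = np.random.default_rng(8)
        clusters = rng.integers(0, 3, size=(8, 8, 4))
        el = np.ones_like(clusters, dtype=np.uint8)
        small, ps = generate_ai_label(clusters, el, el, n_seeds=5, max_volume_factor=0.3,
                                      rng_seed=3)
        large, pl = generate_ai_label(clusters, el, el, n_seeds=5, max_volume_factor=5.0,
                                      rng_seed=3)
        assert ps["seeds"] == pl["seeds"]
        if not ps["fallback_expert_region"]:
            assert (large.astype(bool) >= small.astype(bool)).all()

    def test_fallback_when_nothing_survives(self):
        clusters = np.zeros((6, 6, 4), dtype=int)  # one giant component
        el = np.zeros_like(clusters, dtype=np.uint8)
        el[2, 2, 1] = 1  # estimate = 1 voxel, component = 144 voxels
        ail, prov = generate_ai_label(clusters, el, el, n_seeds=1, rng_seed=0)
        assert prov["fallback_expert_region"]
        np.testing.assert_array_equal(ail, el)
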