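import numpy as np
import pytest

from ishannot.bow import (
    Codebook,
    DescriptorSet,
    assign_intervals,
    build_codebook,
    build_global_bow,
    dense_descriptors,
    grid_count,
    quantize,
    sample_pool,
)


def _local_grid_count(h, w, bin_size, step, downsample):
    """Independent closed-form grid size on the downsampled image."""
    h2, w2 = h // downsample, w // downsample
    fp = 4 * bin_size
    ny = (h2 - fp) // step + 1 if h2 >= fp else 0
    nx = (w2 - fp) // step + 1 if w2 >= fp else 0
    return ny * nx


class TestDenseDescriptors:
    def test_flat_image_has_only_zero_descriptors(self):
        ds = dense_descriptors(np.full((128, 128), 0.5), scales=(4, 8), step=4,
                               downsample=2)
        for kept, zero, grid in zip(ds.descriptors, ds.zero_counts, ds.grid_counts):
            assert kept.shape[0] == 0
            assert zero == grid > 0

    def test_determinism(self, textured_image):
        a = dense_descriptors(textured_image)
        b = dense_descriptors(textured_image)
        for x, y in zip(a.descriptors, b.descriptors):
            np.testing.assert_array_equal(x, y)

    def test_counts_match_closed_form_grid_size(self):
        g = np.random.default_rng(3)
        img = g.random((512, 512))
        scales, step, down = (4, 8, 16), 4, 4
        ds = dense_descriptors(img, scales=scales, step=step, downsample=down)
        for s, (kept, zero) in enumerate(zip(ds.descriptors, ds.zero_counts)):
            expected = _local_grid_count(512, 512, scales[s], step, down)
            assert kept.shape[0] + zero == expected
            assert ds.grid_counts[s] == expected

    def test_footprint_larger_than_image_yields_empty_scale_not_error(self):
        ds = dense_descriptors(np.random.default_rng(0).random((40, 40)),
                               scales=(16,), step=4, downsample=1)
        assert ds.descriptors[0].shape[0] == 0
        assert ds.grid_counts[0] == 0

    def test_kept_descriptors_are_unit_norm(self, textured_image):
        ds = dense_descriptors(textured_image, scales=(4,), downsample=2)
        norms = np.linalg.norm(ds.descriptors[0], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-5)


class TestSamplePool:
    def _sets(self, n_images, n_desc, seed=0):
        g = np.random.default_rng(seed)
        out = []
        for _ in range(n_images):
            d = g.random((n_desc, 128)).astype(np.float32)
            out.append(DescriptorSet((4,), [d], [0], [n_desc]))
        return out

    def test_pool_cannot_exceed_supply(self):
        pools = sample_pool(self._sets(5, 10), pool_size=100_000)
        assert pools[4].shape[0] == 50

    def test_exact_pool_size_with_quota_spread_over_images(self):
        sets = self._sets(10, 1000)
        pools, prov = sample_pool(sets, pool_size=100, seed=1,
                                  return_provenance=True)
        assert pools[4].shape == (100, 128)
        contributing = np.unique(prov[4])
        assert len(contributing) == 10  # default quota spreads over all images

    def test_same_seed_identical_pool(self):
        sets = self._sets(4, 50)
        a = sample_pool(sets, pool_size=80, seed=9)
        b = sample_pool(sets, pool_size=80, seed=9)
        np.testing.assert_array_equal(a[4], b[4])

    def test_empty_corpus_names_the_scale(self):
        sets = [DescriptorSet((8,), [np.empty((0, 128), np.float32)], [5], [5])]
        with pytest.raises(ValueError, match="scale 8"):
            sample_pool(sets, pool_size=10)


class TestBuildCodebook:
    def test_pool_of_exactly_k_points_is_reproduced(self):
        g = np.random.default_rng(2)
        pool = g.random((6, 128))
        cb = build_codebook(pool, K=6, restarts=2, seed=0)
        assert cb.K == 6
        assert cb.within_cluster_distance == pytest.approx(0.0, abs=1e-9)
        # centroids are the points, up to permutation
        d = np.linalg.norm(cb.centroids[:, None] - pool[None], axis=2)
        assert np.allclose(d.min(axis=1), 0.0, atol=1e-9)

    def test_restart_selection_is_monotone(self):
        g = np.random.default_rng(4)
        pool = g.random((300, 128))
        dists = [build_codebook(pool, K=20, restarts=r, seed=7).within_cluster_distance
                 for r in (1, 2, 4)]
        assert dists[1] <= dists[0] and dists[2] <= dists[1]

    def test_recovers_well_separated_blob_means(self):
        g = np.random.default_rng(11)
        sigma, n_per = 0.05, 20
        means = np.zeros((4, 128))
        means[0, 0], means[1, 0], means[2, 1], means[3, 1] = 5, -5, 5, -5
        pool = np.concatenate(
            [m + sigma * g.standard_normal((n_per, 128)) for m in means]
        )
        cb = build_codebook(pool, K=4, restarts=5, seed=3)
        for m in means:
            nearest = cb.centroids[np.linalg.norm(cb.centroids - m, axis=1).argmin()]
            assert np.linalg.norm(nearest - m) < 3 * sigma  # > 3*sigma/sqrt(20)

    def test_pool_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="K=10"):
            build_codebook(np.zeros((5, 128)), K=10)


class TestQuantize:
    def _codebooks(self, scales, K, seed=0):
        g = np.random.default_rng(seed)
        return {s: Codebook(s, g.random((K, 128)), 0.0) for s in scales}

    def test_counts_match_exhaustive_nearest_centroid_loop(self):
        g = np.random.default_rng(5)
        desc = g.random((100, 128)).astype(np.float32)
        ds = DescriptorSet((4,), [desc], [7], [107])
        books = self._codebooks((4,), K=12, seed=1)
        vec = quantize(ds, books)
        expected = np.zeros(13)
        for d in desc:  # independent brute-force oracle
            dist = [np.sum((d - c) ** 2) for c in books[4].centroids]
            expected[int(np.argmin(dist))] += 1
        expected[12] = 7
        np.testing.assert_array_equal(vec, expected)

    def test_default_configuration_vector_length(self):
        g = np.random.default_rng(6)
        ds = DescriptorSet(
            (4, 8, 16),
            [g.random((10, 128)).astype(np.float32) for _ in range(3)],
            [1, 2, 3], [11, 12, 13],
        )
        vec = quantize(ds, self._codebooks((4, 8, 16), K=500))
        assert vec.shape == (1503,)  # (500 + 1) x 3 scales

    def test_mass_conservation_per_scale(self, textured_image):
        ds = dense_descriptors(textured_image, scales=(4, 8), downsample=2)
        books = self._codebooks((4, 8), K=30)
        vec = quantize(ds, books)
        for s in range(2):
            block = vec[s * 31:(s + 1) * 31]
            assert block.sum() == ds.grid_counts[s]

    def test_scale_mismatch_rejected(self):
        ds = DescriptorSet((4,), [np.empty((0, 128), np.float32)], [0], [0])
        with pytest.raises(ValueError, match="scales"):
            quantize(ds, self._codebooks((8,), K=5))


class TestAssignIntervals:
    def test_single_section_maps_to_interval_zero(self):
        np.testing.assert_array_equal(assign_intervals([0.3], 7), [0])

    def test_even_positions_align_with_intervals(self):
        idx = assign_intervals(np.linspace(0, 1, 7), 7)
        np.testing.assert_array_equal(idx, np.arange(7))

    def test_matches_direct_formula_with_max_edge_clamp(self):
        g = np.random.default_rng(8)
        pos = g.random(20)
        n = 7
        idx = assign_intervals(pos, n)
        lo, hi = pos.min(), pos.max()
        width = (hi - lo) / n
        expected = np.minimum(((pos - lo) // width).astype(int), n - 1)
        np.testing.assert_array_equal(idx, expected)

    def test_empty_positions_rejected(self):
        with pytest.raises(ValueError):
            assign_intervals([], 7)


class TestBuildGlobalBow:
    def test_default_global_length(self):
        vecs = [np.ones(1503) for _ in range(17)]
        idx = assign_intervals(np.linspace(0, 1, 17), 7)
        assert build_global_bow(vecs, idx, 7).shape == (10521,)

    def test_one_section_per_interval_is_plain_concatenation(self):
        g = np.random.default_rng(9)
        vecs = [g.random(5) for _ in range(3)]
        out = build_global_bow(vecs, [0, 1, 2], 3)
        np.testing.assert_array_equal(out, np.concatenate(vecs))

    def test_duplicate_sections_average_to_themselves(self):
        v = np.arange(4.0)
        out = build_global_bow([v, v], [1, 1], 2)
        np.testing.assert_array_equal(out[:4], 0.0)
        np.testing.assert_array_equal(out[4:], v)

    def test_permutation_within_interval_is_invariant(self):
        g = np.random.default_rng(10)
        vecs = [g.random(6) for _ in range(5)]
        idx = [0, 0, 1, 1, 1]
        a = build_global_bow(vecs, idx, 2)
        b = build_global_bow([vecs[1], vecs[0], vecs[4], vecs[2], vecs[3]], idx, 2)
        np.testing.assert_allclose(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_global_bow([np.ones(3), np.ones(4)], [0, 0], 1)
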