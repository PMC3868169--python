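import numpy as np
import pytest

from rcga import (
    IntensityMap,
    LinkPValueMatrix,
    cluster_table,
    combine_max,
    connected_components_18,
    intensity_from_pvalues,
    peak_voxel,
    source_mean_series,
    threshold_mask,
    voxel_to_world,
)


from oracles import bfs_components_18, partition_from_labels


def _pmat(p, alpha=0.05):
    p = np.asarray(p, dtype=float)
    return LinkPValueMatrix(p=p, t=np.zeros_like(p), df=74.0, alpha=alpha,
                            roi_a="A", roi_b="B")


class TestIntensity:
    def test_fraction_of_significant_links(self):
        pmat = _pmat([[0.01, 0.2, 0.04, 0.5]])
        imap = intensity_from_pvalues(pmat, side="rows")
        assert imap.values[0] == pytest.approx(0.5)
        assert imap.n_other[0] == 4

    def test_all_null_links_give_zero(self):
        imap = intensity_from_pvalues(_pmat(np.ones((3, 5))), side="rows")
        assert np.all(imap.values == 0.0)

    def test_column_side_uses_other_denominator(self):
        pmat = _pmat([[0.01, 0.2], [0.01, 0.2], [0.6, 0.01]])
        imap = intensity_from_pvalues(pmat, side="cols")
        assert imap.values.tolist() == [2 / 3, 1 / 3]

    def test_values_times_denominator_are_integer_counts(self, rng):
        p = rng.random((20, 17))
        imap = intensity_from_pvalues(_pmat(p), side="rows")
        counts = imap.values * imap.n_other
        assert np.allclose(counts, np.round(counts), atol=1e-9)

    def test_raising_alpha_never_decreases_intensity(self, rng):
        p = rng.random((10, 30))
        lo = intensity_from_pvalues(_pmat(p), side="rows", alpha=0.05)
        hi = intensity_from_pvalues(_pmat(p), side="rows", alpha=0.20)
        assert np.all(hi.values >= lo.values)


class TestCombineMax:
    def test_elementwise_maximum(self):
        m1 = IntensityMap(values=[0.2, 0.0], n_other=10, alpha=0.05, link_label="l1")
        m2 = IntensityMap(values=[0.1, 0.3], n_other=10, alpha=0.05, link_label="l2")
        out = combine_max([m1, m2])
        assert out.values.tolist() == [0.2, 0.3]

    def test_single_map_identity(self):
        m = IntensityMap(values=[0.4, 0.1], n_other=10, alpha=0.05, link_label="l")
        assert np.array_equal(combine_max([m]).values, m.values)

    def test_winner_denominator_recorded(self):
        # mirrors the shared-ROI rule: winning link's denominator is kept so
        # intensity*denominator stays an integer count
        m1 = IntensityMap(values=[195 / 352], n_other=352, alpha=0.05, link_label="b-c")
        m2 = IntensityMap(values=[100 / 1184], n_other=1184, alpha=0.05, link_label="a-b")
        out = combine_max([m1, m2])
        assert out.values[0] == pytest.approx(195 / 352)
        assert out.n_other[0] == 352

    def test_misaligned_maps_rejected(self):
        m1 = IntensityMap(values=[0.2], n_other=10, alpha=0.05, link_label="l1")
        m2 = IntensityMap(values=[0.1, 0.3], n_other=10, alpha=0.05, link_label="l2")
        with pytest.raises(ValueError, match="align"):
            combine_max([m1, m2])


class TestThreshold:
    def test_strictly_greater_than(self):
        imap = IntensityMap(values=[0.15, 0.1501], n_other=10000, alpha=0.05,
                            link_label="l")
        mask = threshold_mask(imap, theta=0.15)
        assert mask.values.tolist() == [False, True]

    def test_unreachable_threshold_warns_empty(self):
        imap = IntensityMap(values=[0.5, 0.2], n_other=10, alpha=0.05, link_label="l")
        with pytest.warns(UserWarning, match="threshold"):
            mask = threshold_mask(imap, theta=0.999)
        assert mask.source_count == 0

    def test_count_matches_loop_oracle(self, rng):
        vals = rng.integers(0, 101, size=200) / 100.0
        imap = IntensityMap(values=vals, n_other=100, alpha=0.05, link_label="l")
        mask = threshold_mask(imap, theta=0.37)
        assert mask.source_count == sum(1 for v in vals if v > 0.37)

    def test_raising_theta_never_enlarges_mask(self, rng):
        vals = rng.integers(0, 101, size=100) / 100.0
        imap = IntensityMap(values=vals, n_other=100, alpha=0.05, link_label="l")
        lo = threshold_mask(imap, theta=0.1).values
        hi = threshold_mask(imap, theta=0.3).values
        assert np.all(lo[hi])  # hi-selected is a subset of lo-selected


class TestConnectedComponents18:
    def test_single_voxel(self):
        labels = connected_components_18(np.array([[2, 3, 4]]))
        assert labels.tolist() == [1]

    def test_edge_neighbors_merge(self):
        labels = connected_components_18(np.array([[0, 0, 0], [1, 1, 0]]))
        assert labels[0] == labels[1]

    def test_corner_neighbors_stay_apart(self):
        labels = connected_components_18(np.array([[0, 0, 0], [1, 1, 1]]))
        assert labels[0] != labels[1]

    def test_every_offset_pair_matches_bfs(self):
        # exhaustive over the whole neighborhood definition
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    coords = np.array([[2, 2, 2], [2 + dx, 2 + dy, 2 + dz]])
                    labels = connected_components_18(coords)
                    expected_one = bfs_components_18(coords) == [[0, 1]]
                    assert (labels[0] == labels[1]) == expected_one, (dx, dy, dz)

    @pytest.mark.parametrize("density", [0.2, 0.5, 0.8])
    def test_random_masks_match_bfs_partition(self, density):
        g = np.random.default_rng(int(density * 100))
        for _ in range(30):
            grid = g.random((6, 6, 6)) < density
            coords = np.argwhere(grid)
            if coords.size == 0:
                continue
            labels = connected_components_18(coords)
            assert partition_from_labels(labels) == bfs_components_18(coords)

    def test_ids_ordered_by_size_then_lowest_linear_index(self):
        # two singletons and one pair: pair gets id 1, singletons by position
        coords = np.array([[5, 5, 5], [0, 0, 0], [0, 0, 1], [3, 0, 0]])
        labels = connected_components_18(coords)
        assert labels.tolist() == [3, 1, 1, 2]

    def test_empty_input(self):
        assert connected_components_18(np.empty((0, 3))).size == 0


class TestPeakAndWorld:
    def test_singleton_cluster(self):
        imap = IntensityMap(values=[0.3, 0.7], n_other=10, alpha=0.05, link_label="l")
        idx, val = peak_voxel(imap, np.array([1]))
        assert (idx, val) == (1, 0.7)

    def test_tie_breaks_to_lowest_index(self):
        imap = IntensityMap(values=[0.5, 0.7, 0.7], n_other=10, alpha=0.05,
                            link_label="l")
        idx, _ = peak_voxel(imap, np.array([2, 1]))
        assert idx == 1

    def test_matches_loop_argmax(self, rng):
        vals = rng.integers(0, 100, size=50) / 100.0
        imap = IntensityMap(values=vals, n_other=100, alpha=0.05, link_label="l")
        members = rng.choice(50, size=20, replace=False)
        idx, val = peak_voxel(imap, members)
        best = max(sorted(members), key=lambda i: (vals[i], -i))
        assert idx == best and val == vals[best]

    def test_identity_affine(self):
        assert np.allclose(voxel_to_world((3, 4, 5), np.eye(4)), (3, 4, 5))

    def test_mni_style_affine(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = (-90.0, -126.0, -72.0)
        assert np.allclose(voxel_to_world((0, 0, 0), affine), (-90, -126, -72))

    def test_world_voxel_round_trip(self, rng):
        affine = np.eye(4)
        affine[:3, :3] = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        affine[:3, 3] = rng.standard_normal(3) * 10
        ijk = np.array([4.0, 7.0, 2.0])
        world = voxel_to_world(ijk, affine)
        back = np.linalg.inv(affine) @ np.append(world, 1.0)
        assert np.allclose(back[:3], ijk, atol=1e-9)


class TestSourceMeanSeries:
    def test_single_voxel_mask_returns_that_series(self, rng):
        mat = rng.standard_normal((20, 5))
        mask = np.zeros(5, dtype=bool)
        mask[3] = True
        assert np.array_equal(source_mean_series(mat, mask), mat[:, 3])

    def test_full_mask_reduces_to_roi_mean(self, rng):
        mat = rng.standard_normal((20, 5))
        assert np.allclose(
            source_mean_series(mat, np.ones(5, dtype=bool)), mat.mean(axis=1)
        )

    def test_matches_loop_mean(self, rng):
        mat = rng.standard_normal((15, 8))
        mask = rng.random(8) > 0.5
        mask[0] = True
        expected = np.array([
            np.mean([mat[t, v] for v in range(8) if mask[v]]) for t in range(15)
        ])
        assert np.allclose(source_mean_series(mat, mask), expected, atol=1e-12)

    def test_empty_mask_advises_lower_threshold(self, rng):
        with pytest.raises(ValueError, match="theta"):
            source_mean_series(rng.standard_normal((10, 3)), np.zeros(3, dtype=bool))


class TestClusterTable:
    def test_sizes_sum_to_source_count_and_peaks_are_maxima(self, rng):
        coords = np.argwhere(np.ones((5, 5, 5), dtype=bool))
        vals = rng.integers(0, 100, size=125) / 100.0
        imap = IntensityMap(values=vals, n_other=100, alpha=0.05, link_label="l",
                            voxel_coords=coords)
        mask = threshold_mask(imap, theta=0.6)
        table = cluster_table(imap, mask, affine=np.eye(4))
        assert table["size"].sum() == mask.source_count
        assert (table["size"].diff().dropna() <= 0).all()  # descending sizes
        for _, row in table.iterrows():
            assert row["peak_intensity"] <= vals.max()
            assert row["peak_intensity"] > 0.6
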