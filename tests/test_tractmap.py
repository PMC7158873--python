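import numpy as np
import pytest

from optirad.grids import MaskVolume, Volume3D, centered_affine
from optirad.roi import DEFAULT_SCHEME, Slab, composite_occipital_roi, exclusion_regions, lgn_seed_from_thalamus
from optirad.streamlines import StreamlineSet
from optirad.tractmap import (
    VisitationMap,
    filter_streamlines,
    threshold_map,
    tract_weighted_average,
    visitation_map,
)


def brute_force_visited(line, grid, step):
    """Oracle rasteriser: dense resampling + per-point binning + dedup."""
    pts = [line[0]]
    for a, b in zip(line[:-1], line[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        for f in np.linspace(0, 1, n + 1)[1:]:
            pts.append(a + f * (b - a))
    ijk = np.rint(grid.voxel_from_world(np.array(pts))).astype(int)
    ok = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
    return set(map(tuple, ijk[ok]))


@pytest.fixture
def unit_grid():
    return Volume3D(np.zeros((12, 12, 12)), centered_affine((12, 12, 12), 1.0))


class TestFilterStreamlines:
    def _masks(self, shape=(12, 12, 12)):
        aff = centered_affine(shape, 1.0)
        seed = np.zeros(shape, bool)
        seed[1:3, 5:7, 5:7] = True
        target = np.zeros(shape, bool)
        target[9:11, 5:7, 5:7] = True
        return MaskVolume(seed, aff), MaskVolume(target, aff), aff

    def test_keeps_connecting_streamline(self):
        seed, target, aff = self._masks()
        line = np.column_stack([np.linspace(-4, 4, 30), np.zeros(30), np.zeros(30)])
        kept = filter_streamlines(StreamlineSet([line]), seed, target)
        assert kept.count == 1

    def test_exclusion_removes_crossing_streamline(self):
        seed, target, aff = self._masks()
        excl = np.zeros((12, 12, 12), bool)
        excl[6, :, :] = True  # plane across the path
        line = np.column_stack([np.linspace(-4, 4, 30), np.zeros(30), np.zeros(30)])
        kept = filter_streamlines(StreamlineSet([line]), seed, target, MaskVolume(excl, aff))
        assert kept.count == 0

    def test_matches_brute_force_point_scan(self, phantom):
        parc = phantom["parcellation"]
        seed = lgn_seed_from_thalamus(parc, DEFAULT_SCHEME, "left")
        target = composite_occipital_roi(parc, DEFAULT_SCHEME, "left")
        excl = exclusion_regions(parc, DEFAULT_SCHEME, "left", [Slab("z", -30.0, -6.0)])
        kept = filter_streamlines(phantom["streamlines"], seed, target, excl)
        expected = []
        for line in phantom["streamlines"]:
            ijk = np.rint(parc.voxel_from_world(line)).astype(int)
            ok = np.all((ijk >= 0) & (ijk < np.array(parc.shape)), axis=1)
            ijk = ijk[ok]
            in_seed = seed.data[tuple(ijk.T)].any()
            in_target = target.data[tuple(ijk.T)].any()
            in_excl = excl.data[tuple(ijk.T)].any()
            if in_seed and in_target and not in_excl:
                expected.append(line)
        assert kept.count == len(expected)
        assert 0 < kept.count < phantom["streamlines"].count

    def test_idempotent(self, phantom):
        parc = phantom["parcellation"]
        seed = lgn_seed_from_thalamus(parc, DEFAULT_SCHEME, "left")
        target = composite_occipital_roi(parc, DEFAULT_SCHEME, "left")
        once = filter_streamlines(phantom["streamlines"], seed, target)
        twice = filter_streamlines(once, seed, target)
        assert twice.count == once.count

    def test_empty_seed_rejected(self, unit_grid):
        empty = MaskVolume(np.zeros((12, 12, 12), bool), unit_grid.affine)
        full = MaskVolume(np.ones((12, 12, 12), bool), unit_grid.affine)
        line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="non-empty"):
            filter_streamlines(StreamlineSet([line]), empty, full)


class TestVisitationMap:
    def test_single_streamline_marks_its_row(self, unit_grid):
        line = np.column_stack([np.linspace(-5.5, 5.5, 50), np.zeros(50), np.zeros(50)])
        vmap = visitation_map(StreamlineSet([line]), unit_grid)
        ijk = np.rint(unit_grid.voxel_from_world(np.array([[0.0, 0.0, 0.0]]))).astype(int)[0]
        row = vmap.data[:, ijk[1], ijk[2]]
        assert np.all(row == 1.0)
        assert vmap.data.sum() == 12  # only that row visited

    def test_fraction_counts_distinct_streamlines(self):
        # odd-sized grid: the world origin sits at a voxel centre, so small
        # lateral offsets cannot straddle a voxel boundary
        grid = Volume3D(np.zeros((13, 13, 13)), centered_affine((13, 13, 13), 1.0))
        through = np.array([[0.0, -3.0, 0.0], [0.0, 3.0, 0.0]])
        away = np.array([[4.0, -3.0, 4.0], [4.0, 3.0, 4.0]])
        s = StreamlineSet([through, through + 0.1, through - 0.1, away])
        vmap = visitation_map(s, grid)
        ijk = np.rint(grid.voxel_from_world(np.array([[0.0, 0.0, 0.0]]))).astype(int)[0]
        assert vmap.data[tuple(ijk)] == pytest.approx(0.75)

    def test_matches_oracle_rasterizer(self, phantom):
        parc = phantom["parcellation"]
        sub = StreamlineSet(list(phantom["streamlines"])[:100])
        vmap = visitation_map(sub, parc)
        edge = 2.0
        counts = np.zeros(parc.shape, dtype=int)
        for line in sub:
            for v in brute_force_visited(line, parc, edge / 2):
                counts[v] += 1
        np.testing.assert_allclose(vmap.data, counts / sub.count)

    def test_sparse_points_do_not_skip_voxels(self, unit_grid):
        # two distant points: intermediate voxels must still be counted
        line = np.array([[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        vmap = visitation_map(StreamlineSet([line]), unit_grid)
        assert (vmap.data > 0).sum() >= 10

    def test_out_of_grid_points_warn(self, unit_grid):
        line = np.array([[-50.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="outside"):
            visitation_map(StreamlineSet([line]), unit_grid)

    def test_values_bounded(self, phantom):
        vmap = visitation_map(phantom["streamlines"], phantom["parcellation"])
        assert vmap.data.max() <= 1.0 and vmap.data.min() >= 0.0


class TestThresholdMap:
    def test_uniform_map_keeps_support(self, unit_grid):
        data = np.zeros((12, 12, 12))
        data[3:6, 3:6, 3:6] = 0.5
        vmap = VisitationMap(data, unit_grid.affine, count=10)
        mask = threshold_map(vmap, 0.05)
        assert mask.n_voxels == 27

    def test_boundary_is_inclusive(self, unit_grid):
        data = np.zeros((12, 12, 12))
        data[0, 0, 0] = 0.04
        data[1, 0, 0] = 0.05
        vmap = VisitationMap(data, unit_grid.affine, count=100)
        mask = threshold_map(vmap, 0.05)
        assert not mask.data[0, 0, 0] and mask.data[1, 0, 0]

    def test_matches_counting_oracle(self, phantom):
        vmap = visitation_map(phantom["streamlines"], phantom["parcellation"])
        mask = threshold_map(vmap, 0.05)
        counts = np.rint(vmap.data * vmap.count).astype(int)
        np.testing.assert_array_equal(mask.data, counts >= 0.05 * vmap.count - 1e-9)

    def test_max_mode(self, unit_grid):
        data = np.zeros((12, 12, 12))
        data[0, 0, 0] = 0.4
        data[1, 0, 0] = 0.01
        vmap = VisitationMap(data, unit_grid.affine, count=100)
        assert threshold_map(vmap, 0.05, mode="max").n_voxels == 1

    def test_empty_result_rejected(self, unit_grid):
        data = np.zeros((12, 12, 12))
        data[0, 0, 0] = 0.01
        vmap = VisitationMap(data, unit_grid.affine, count=100)
        with pytest.raises(ValueError, match="tract"):
            threshold_map(vmap, 0.5)


class TestTractWeightedAverage:
    def test_two_voxel_arithmetic(self, unit_grid):
        w = np.zeros((12, 12, 12))
        m = np.zeros((12, 12, 12))
        w[0, 0, 0], w[1, 0, 0] = 0.25, 0.75
        m[0, 0, 0], m[1, 0, 0] = 0.2, 0.6
        vmap = VisitationMap(w, unit_grid.affine, count=4)
        assert tract_weighted_average(vmap, Volume3D(m, unit_grid.affine)) == pytest.approx(0.5)

    def test_constant_metric_returns_constant(self, phantom):
        vmap = visitation_map(phantom["streamlines"], phantom["parcellation"])
        metric = Volume3D(np.full(vmap.shape, 3.14), vmap.affine)
        assert tract_weighted_average(vmap, metric) == pytest.approx(3.14)

    def test_matches_double_loop_oracle(self, rng):
        shape = (20, 20, 20)
        aff = centered_affine(shape, 1.0)
        w = rng.uniform(0, 1, shape) * (rng.uniform(size=shape) < 0.3)
        m = rng.normal(size=shape)
        vmap = VisitationMap(w, aff, count=100)
        expected_num = 0.0
        expected_den = 0.0
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    expected_num += w[i, j, k] * m[i, j, k]
                    expected_den += w[i, j, k]
        result = tract_weighted_average(vmap, Volume3D(m, aff))
        assert result == pytest.approx(expected_num / expected_den, rel=1e-12)

    def test_undefined_metric_voxels_excluded(self, unit_grid):
        w = np.zeros((12, 12, 12))
        m = np.zeros((12, 12, 12))
        w[0, 0, 0], w[1, 0, 0] = 0.5, 0.5
        m[0, 0, 0], m[1, 0, 0] = 1.0, np.nan
        vmap = VisitationMap(w, unit_grid.affine, count=2)
        assert tract_weighted_average(vmap, Volume3D(m, unit_grid.affine)) == pytest.approx(1.0)

    def test_result_within_metric_range(self, phantom, rng):
        vmap = visitation_map(phantom["streamlines"], phantom["parcellation"])
        m = rng.normal(size=vmap.shape)
        val = tract_weighted_average(vmap, Volume3D(m, vmap.affine))
        support = vmap.data > 0
        assert m[support].min() <= val <= m[support].max()

    def test_zero_weight_rejected(self, unit_grid):
        vmap = VisitationMap(np.zeros((12, 12, 12)), unit_grid.affine, count=1)
        with pytest.raises(ValueError, match="mass"):
            tract_weighted_average(vmap, Volume3D(np.ones((12, 12, 12)), unit_grid.affine))
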