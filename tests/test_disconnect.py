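import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from optirad.disconnect import (
    RigidTransform,
    apply_transform,
    classify_overlap,
    overlap_score,
    principal_axis,
    rotate_to_canonical,
)
from optirad.grids import MaskVolume, centered_affine, voxel_centers_world
from optirad.phantom import PhantomSpec, make_tract_phantom
from optirad.tractmap import threshold_map, visitation_map


def brute_force_overlap(tract, resection, mode):
    """Oracle: explicit per-slice set enumeration along the AP voxel axis."""
    ap = int(np.argmax(np.abs(tract.affine[1, :3])))
    n_slices = tract.shape[ap]
    tract_sets = []
    res_sets = []
    for s in range(n_slices):
        sl = [slice(None)] * 3
        sl[ap] = s
        tract_sets.append(set(map(tuple, np.argwhere(tract.data[tuple(sl)]))))
        res_sets.append(set(map(tuple, np.argwhere(resection.data[tuple(sl)]))))
    total = sum(len(t) for t in tract_sets)
    profile = []
    for t, r in zip(tract_sets, res_sets):
        inter = len(t & r)
        if mode == "whole_volume":
            profile.append(inter / total)
        else:
            profile.append(inter / len(t) if t else 0.0)
    best = int(np.argmax(profile))
    return profile[best], best, profile


def random_rigid(rng, max_angle_deg=30.0, max_shift=8.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    m = np.eye(4)
    m[:3, :3] = Rotation.from_rotvec(angle * axis).as_matrix()
    m[:3, 3] = rng.uniform(-max_shift, max_shift, 3)
    return RigidTransform(m)


def blob_mask(shape=(20, 20, 20), voxel=1.0, center=(0, 0, 0), radii=(6, 4, 5)):
    aff = centered_affine(shape, voxel)
    idx = np.indices(shape).reshape(3, -1).T
    world = idx @ aff[:3, :3].T + aff[:3, 3]
    rel = (world - np.asarray(center, float)) / np.asarray(radii, float)
    return MaskVolume(((rel**2).sum(axis=1) <= 1).reshape(shape), aff)


class TestRigidTransform:
    def test_validation(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.diag([2.0, 1.0, 1.0, 1.0]))
        m = np.eye(4)
        m[:3, :3] = np.diag([1, 1, -1])  # improper
        with pytest.raises(ValueError, match="det"):
            RigidTransform(m)

    def test_text_roundtrip(self, tmp_path, rng):
        t = random_rigid(rng)
        path = str(tmp_path / "xfm.txt")
        t.save(path)
        np.testing.assert_allclose(RigidTransform.load(path).matrix, t.matrix, atol=1e-9)


class TestApplyTransform:
    def test_identity_is_noop(self):
        mask = blob_mask()
        out = apply_transform(mask, RigidTransform.identity())
        np.testing.assert_array_equal(out.data, mask.data)

    def test_one_voxel_translation_preserves_count(self):
        mask = blob_mask()
        m = np.eye(4)
        m[0, 3] = 1.0  # exactly one voxel along x
        out = apply_transform(mask, RigidTransform(m))
        assert out.n_voxels == mask.n_voxels
        np.testing.assert_array_equal(out.data[1:], mask.data[:-1])

    def test_rotation_round_trip_dice(self):
        mask = blob_mask()
        r = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        fwd = RigidTransform.from_rotation_about(r, np.zeros(3))
        back = RigidTransform.from_rotation_about(r.T, np.zeros(3))
        out = apply_transform(apply_transform(mask, fwd), back)
        inter = (out.data & mask.data).sum()
        dice = 2 * inter / (out.n_voxels + mask.n_voxels)
        assert dice >= 0.95

    def test_content_lost_raises(self):
        mask = blob_mask()
        m = np.eye(4)
        m[:3, 3] = 500.0
        with pytest.raises(ValueError, match="outside"):
            apply_transform(mask, RigidTransform(m))


class TestPrincipalAxis:
    def test_straight_line_along_x(self):
        aff = centered_affine((20, 8, 8), 1.0)
        data = np.zeros((20, 8, 8), bool)
        data[:, 4, 4] = True
        axis, centroid = principal_axis(MaskVolume(data, aff))
        np.testing.assert_allclose(np.abs(axis), [1, 0, 0], atol=1e-12)
        assert axis[0] > 0  # AP-tie resolved toward +X

    def test_oriented_anterior_to_posterior(self):
        aff = centered_affine((8, 20, 8), 1.0)
        data = np.zeros((8, 20, 8), bool)
        data[4, :, 4] = True
        axis, _ = principal_axis(MaskVolume(data, aff))
        assert axis[1] < 0  # points toward -Y (posterior)

    def test_tube_at_angle_recovered(self):
        # tube at 30 degrees to Y in the XY plane
        direction = np.array([np.sin(np.radians(30)), -np.cos(np.radians(30)), 0.0])
        aff = centered_affine((40, 40, 12), 1.0)
        idx = np.indices((40, 40, 12)).reshape(3, -1).T
        world = idx @ aff[:3, :3].T + aff[:3, 3]
        along = world @ direction
        perp = world - np.outer(along, direction)
        data = (np.linalg.norm(perp, axis=1) <= 2.5) & (np.abs(along) <= 15)
        axis, _ = principal_axis(MaskVolume(data.reshape(40, 40, 12), aff))
        angle = np.degrees(np.arccos(np.clip(abs(axis @ direction), -1, 1)))
        assert angle < 2.0

    def test_l_shape_matches_covariance_oracle(self):
        aff = centered_affine((20, 20, 8), 1.0)
        data = np.zeros((20, 20, 8), bool)
        data[3:17, 3:5, 3:5] = True
        data[3:5, 5:15, 3:5] = True
        mask = MaskVolume(data, aff)
        axis, centroid = principal_axis(mask)
        world = voxel_centers_world(mask)
        cov = (world - world.mean(0)).T @ (world - world.mean(0)) / (len(world) - 1)
        evals, evecs = np.linalg.eigh(cov)
        expected = evecs[:, -1]
        assert abs(abs(axis @ expected) - 1.0) < 1e-9

    def test_too_few_voxels(self):
        aff = np.eye(4)
        data = np.zeros((5, 5, 5), bool)
        data[0, 0, 0] = data[1, 1, 1] = True
        with pytest.raises(ValueError, match="at least 3"):
            principal_axis(MaskVolume(data, aff))


class TestRotateToCanonical:
    def test_already_aligned_identity(self):
        aff = centered_affine((8, 30, 8), 1.0)
        data = np.zeros((8, 30, 8), bool)
        data[3:5, 4:26, 3:5] = True
        rotated, _, t = rotate_to_canonical(MaskVolume(data, aff))
        np.testing.assert_allclose(t.matrix, np.eye(4), atol=1e-9)
        np.testing.assert_array_equal(rotated.data, data)

    def test_x_tube_rotates_90_degrees(self):
        aff = centered_affine((40, 40, 12), 1.0)
        data = np.zeros((40, 40, 12), bool)
        data[5:35, 18:22, 4:8] = True
        rotated, _, t = rotate_to_canonical(MaskVolume(data, aff))
        angle = np.degrees(np.arccos(np.clip((np.trace(t.matrix[:3, :3]) - 1) / 2, -1, 1)))
        assert angle == pytest.approx(90.0, abs=1e-6)
        axis_after, _ = principal_axis(rotated)
        ap_angle = np.degrees(np.arccos(np.clip(abs(axis_after[1]), -1, 1)))
        assert ap_angle < 2.0

    def test_joint_rotation_preserves_overlap_count(self, rng):
        tract = blob_mask(shape=(26, 26, 26), radii=(9, 5, 5))
        resection = blob_mask(shape=(26, 26, 26), center=(4, 0, 0), radii=(5, 5, 5))
        base = int((tract.data & resection.data).sum())
        # pre-rotate both by the same rigid motion, then count again
        t = random_rigid(rng, max_angle_deg=25, max_shift=3)
        a = apply_transform(tract, t)
        b = apply_transform(resection, t, reference=tract)
        after = int((a.data & b.data).sum())
        assert abs(after - base) / base <= 0.05


class TestOverlapScore:
    def _stacked_masks(self):
        # tract: 10 voxels per AP slice x 10 slices; resection: 5 voxels in
        # slice 3 and 2 in slice 4
        aff = centered_affine((10, 12, 10), 1.0)
        tract = np.zeros((10, 12, 10), bool)
        tract[2:7, 1:11, 4:6] = True  # 10 per slice over 10 slices
        res = np.zeros((10, 12, 10), bool)
        res[2:7, 3, 4] = True  # 5 voxels in slice 3
        res[2:4, 4, 4] = True  # 2 voxels in slice 4
        return MaskVolume(tract, aff), MaskVolume(res, aff)

    def test_explicit_slice_enumeration(self):
        tract, res = self._stacked_masks()
        whole = overlap_score(tract, res, mode="whole_volume")
        assert whole.score == pytest.approx(5 / 100)
        assert whole.argmax_slice == 3
        per_slice = overlap_score(tract, res, mode="slice")
        assert per_slice.score == pytest.approx(5 / 10)
        assert per_slice.argmax_slice == 3

    def test_disjoint_masks_score_zero(self):
        tract, _ = self._stacked_masks()
        empty = MaskVolume(np.zeros(tract.shape, bool), tract.affine)
        r = overlap_score(tract, empty)
        assert r.score == 0.0
        assert np.all(r.per_slice_profile == 0.0)
        assert not classify_overlap(r)

    def test_resection_superset_slice_mode_is_one(self):
        tract, _ = self._stacked_masks()
        everything = MaskVolume(np.ones(tract.shape, bool), tract.affine)
        assert overlap_score(tract, everything, mode="slice").score == 1.0

    def test_growing_resection_never_decreases_score(self, rng):
        tract = blob_mask(shape=(24, 24, 24), radii=(5, 8, 5))
        small = blob_mask(shape=(24, 24, 24), center=(2, 3, 0), radii=(3, 3, 3))
        big = blob_mask(shape=(24, 24, 24), center=(2, 3, 0), radii=(6, 6, 6))
        for mode in ("whole_volume", "slice"):
            assert (
                overlap_score(tract, big, mode=mode).score
                >= overlap_score(tract, small, mode=mode).score
            )

    def test_whole_volume_bounded_by_global_fraction(self):
        tract, res = self._stacked_masks()
        r = overlap_score(tract, res, mode="whole_volume")
        global_frac = (tract.data & res.data).sum() / tract.n_voxels
        assert r.score <= global_frac + 1e-12

    def test_matches_brute_force_on_random_masks(self, rng):
        aff = centered_affine((24, 24, 24), 1.0)
        for _ in range(50):
            tract = MaskVolume(rng.uniform(size=(24, 24, 24)) < 0.2, aff)
            res = MaskVolume(rng.uniform(size=(24, 24, 24)) < 0.15, aff)
            if tract.n_voxels == 0:
                continue
            for mode in ("whole_volume", "slice"):
                r = overlap_score(tract, res, mode=mode)
                score, best, profile = brute_force_overlap(tract, res, mode)
                assert r.score == pytest.approx(score, abs=1e-12)
                assert r.argmax_slice == best

    def test_empty_tract_rejected(self):
        aff = np.eye(4)
        empty = MaskVolume(np.zeros((5, 5, 5), bool), aff)
        full = MaskVolume(np.ones((5, 5, 5), bool), aff)
        with pytest.raises(ValueError, match="empty"):
            overlap_score(empty, full)

    def test_single_voxel_graze_classified(self):
        # resection touching exactly one tract voxel
        tract, _ = self._stacked_masks()
        res = np.zeros(tract.shape, bool)
        res[2, 1, 4] = True
        r = overlap_score(tract, MaskVolume(res, tract.affine))
        assert classify_overlap(r)
        assert r.score == pytest.approx(1 / 100)


class TestPhantomDisconnection:
    def test_tiny_resection_inside_tract_scores_positive(self):
        spec = PhantomSpec(resection_center=(-28.0, 8.0, 0.0), resection_radii=(2.0, 2.0, 2.0), seed=3)
        streamlines, parc, resection = make_tract_phantom(spec)
        vmap = visitation_map(streamlines, parc)
        tract = threshold_map(vmap, 0.05)
        rt, (rr,), t = rotate_to_canonical(tract, [resection])
        r = overlap_score(rt, rr)
        assert classify_overlap(r)
        assert (rt.data & rr.data).any()
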