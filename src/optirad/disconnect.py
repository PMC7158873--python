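"""Cross-sectional overlap between a tract mask and a resection mask.

The disconnection score answers: at the coronal level where the resection
cuts deepest into the optic radiation, how much of the tract is removed?
The thresholded tract map's principal axis is rotated onto the world
anterior-posterior axis (so slicing planes perpendicular to it are
"coronal"), the identical rotation is applied to the resection mask, and
for every coronal slice the tract-resection intersection is counted.  Two
denominator conventions are supported:

``whole_volume``
    slice overlap / total tract voxel count (literal "fraction of optic
    radiation voxels in common with the resected area over the whole optic
    radiation volume").
``slice``
    slice overlap / tract voxels in that slice (a per-slice disconnection
    percentage).

The score is the maximum over slices; presence/absence of overlap is the
score compared against a zero tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from .grids import MaskVolume, Volume3D, voxel_centers_world
from .tractmap import VisitationMap

__all__ = [
    "RigidTransform",
    "DisconnectionResult",
    "apply_transform",
    "principal_axis",
    "rotate_to_canonical",
    "overlap_score",
    "classify_overlap",
]

_POSTERIOR = np.array([0.0, -1.0, 0.0])


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid transform in world mm (rotation + translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform must be 4x4")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation block must be orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-6):
            raise ValueError("rotation block must be proper (det = +1)")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row must be [0, 0, 0, 1]")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_about(cls, rotation: np.ndarray, center: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = center - rotation @ center
        return cls(m)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def apply_points(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def save(self, path: str) -> None:
        np.savetxt(path, self.matrix, fmt="%.10f")

    @classmethod
    def load(cls, path: str) -> "RigidTransform":
        return cls(np.loadtxt(path))


@dataclass
class DisconnectionResult:
    """Cross-sectional overlap score and its provenance."""

    score: float
    argmax_slice: int
    rotation: RigidTransform
    denominator_mode: str
    per_slice_profile: np.ndarray

    def to_dict(self) -> dict:
        return {
            "score": float(self.score),
            "argmax_slice": int(self.argmax_slice),
            "denominator_mode": self.denominator_mode,
            "per_slice_profile": [float(x) for x in self.per_slice_profile],
            "rotation": self.rotation.matrix.tolist(),
        }


def apply_transform(
    volume: MaskVolume | VisitationMap | Volume3D,
    transform: RigidTransform,
    reference: Volume3D | None = None,
) -> MaskVolume | VisitationMap | Volume3D:
    """Resample a volume transformed by a world-space rigid motion.

    The output lives on the reference grid (the input's own grid by
    default); masks are resampled nearest-neighbour, continuous maps
    trilinearly.  Raises if a non-empty input maps entirely outside the
    reference grid.
    """
    reference = reference if reference is not None else volume
    is_mask = isinstance(volume, MaskVolume)
    # output voxel -> world(ref) -> inverse rigid -> input voxel
    chain = np.linalg.inv(volume.affine) @ transform.inverse().matrix @ reference.affine
    data = volume.data.astype(float)
    out = affine_transform(
        data,
        matrix=chain[:3, :3],
        offset=chain[:3, 3],
        output_shape=reference.shape,
        order=0 if is_mask else 1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if is_mask:
        result: Volume3D = MaskVolume(out > 0.5, reference.affine)
        if volume.data.any() and not result.data.any():
            raise ValueError("transform maps all mask content outside the reference grid")
    elif isinstance(volume, VisitationMap):
        result = VisitationMap(np.clip(out, 0.0, 1.0), reference.affine, count=volume.count)
        if volume.data.any() and not result.data.any():
            raise ValueError("transform maps all map content outside the reference grid")
    else:
        result = Volume3D(out, reference.affine)
    return result


def principal_axis(mask: MaskVolume) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of the mask's voxel centres, plus centroid.

    The axis is sign-oriented from the anterior toward the posterior end of
    the mask (positive projection onto world -Y wins; exact tie broken
    toward +X, then +Z).  Raises for masks with fewer than 3 voxels or a
    degenerate (zero) covariance.
    """
    world = voxel_centers_world(mask)
    if len(world) < 3:
        raise ValueError("principal axis needs at least 3 voxels")
    centroid = world.mean(axis=0)
    cov = np.cov((world - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-12:
        raise ValueError("degenerate covariance: mask voxels are coincident")
    axis = evecs[:, -1]
    proj = axis @ _POSTERIOR
    if proj < 0:
        axis = -axis
    elif proj == 0:
        if axis[0] < 0 or (axis[0] == 0 and axis[2] < 0):
            axis = -axis
    return axis, centroid


def rotate_to_canonical(
    tract: MaskVolume, others: list | None = None
) -> tuple[MaskVolume, list, RigidTransform]:
    """Rotate the tract's principal axis onto the anterior-posterior axis.

    Builds the minimal-angle rotation about the tract centroid taking the
    principal axis onto world -Y (anterior to posterior), applies the same
    transform to the tract and every volume in ``others``, and returns the
    rotated volumes together with the transform.  After rotation, slices
    perpendicular to Y are coronal.
    """
    axis, centroid = principal_axis(tract)
    cross = np.cross(axis, _POSTERIOR)
    dot = float(np.clip(axis @ _POSTERIOR, -1.0, 1.0))
    norm = np.linalg.norm(cross)
    if norm < 1e-12:
        rotation = np.eye(3) if dot > 0 else Rotation.from_rotvec(np.pi * np.array([0, 0, 1.0])).as_matrix()
    else:
        angle = np.arctan2(norm, dot)
        rotation = Rotation.from_rotvec(angle * cross / norm).as_matrix()
    transform = RigidTransform.from_rotation_about(rotation, centroid)
    rotated_tract = apply_transform(tract, transform, reference=tract)
    rotated_others = [apply_transform(v, transform, reference=tract) for v in (others or [])]
    return rotated_tract, rotated_others, transform


def _ap_voxel_axis(volume: Volume3D) -> int:
    """Voxel axis most aligned with world Y (anterior-posterior)."""
    return int(np.argmax(np.abs(volume.affine[1, :3])))


def overlap_score(
    tract: MaskVolume,
    resection: MaskVolume,
    mode: str = "whole_volume",
    rotation: RigidTransform | None = None,
) -> DisconnectionResult:
    """Maximum cross-sectional overlap fraction over coronal slices.

    Both masks must live on one grid, already rotated so the tract's main
    axis runs anterior-posterior.  Ties in the per-slice profile resolve to
    the smallest slice index; an empty resection yields score 0.
    """
    if mode not in ("whole_volume", "slice"):
        raise ValueError("mode must be 'whole_volume' or 'slice'")
    if not tract.same_grid(resection):
        raise ValueError("tract and resection masks must share one grid")
    n_tract = tract.n_voxels
    if n_tract == 0:
        raise ValueError("tract mask is empty")
    ap = _ap_voxel_axis(tract)
    other_axes = tuple(a for a in range(3) if a != ap)
    inter = tract.data & resection.data
    n_s = inter.sum(axis=other_axes).astype(float)
    tract_s = tract.data.sum(axis=other_axes).astype(float)
    if mode == "whole_volume":
        profile = n_s / n_tract
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            profile = np.where(tract_s > 0, n_s / np.maximum(tract_s, 1), 0.0)
    argmax = int(np.argmax(profile))
    return DisconnectionResult(
        score=float(profile[argmax]),
        argmax_slice=argmax,
        rotation=rotation if rotation is not None else RigidTransform.identity(),
        denominator_mode=mode,
        per_slice_profile=profile,
    )


def classify_overlap(result: DisconnectionResult, tol: float = 0.0) -> bool:
    """True iff the overlap score exceeds the tolerance (default: any overlap)."""
    return result.score > tol
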