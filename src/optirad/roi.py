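"""Seed, target and exclusion region construction from a parcellation.

The optic radiation is tracked between a thalamic seed standing in for the
lateral geniculate nucleus (LGN) and a composite occipital target.  The LGN
surrogate is the posterior half of the thalamus parcel, split at the
thalamic centre of mass along the world anterior-posterior axis.  Exclusion
regions combine the contralateral grey-matter mask with axis-aligned
half-spaces/slabs that stand in for the hand-drawn planes used to remove
lateral and midline projections (acoustic radiation, splenial callosal
fibres, cingulum, brainstem).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .grids import LabelVolume, MaskVolume, voxel_centers_world

__all__ = [
    "ParcellationScheme",
    "HalfSpace",
    "Slab",
    "DEFAULT_SCHEME",
    "lgn_seed_from_thalamus",
    "composite_occipital_roi",
    "exclusion_regions",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class ParcellationScheme:
    """Role -> label-id mapping, per hemisphere ('left'/'right')."""

    thalamus: dict
    lingual: dict
    pericalcarine: dict
    lateral_occipital: dict
    gray_matter: dict  # hemisphere -> tuple of label ids

    def __post_init__(self) -> None:
        ids: list[int] = []
        for role in (self.thalamus, self.lingual, self.pericalcarine, self.lateral_occipital):
            for hemi in ("left", "right"):
                if hemi not in role:
                    raise ValueError(f"scheme missing hemisphere {hemi!r} for a role")
                ids.append(int(role[hemi]))
        for hemi in ("left", "right"):
            ids.extend(int(i) for i in self.gray_matter[hemi])
        if len(ids) != len(set(ids)):
            raise ValueError("parcellation label ids must be disjoint across roles")

    def occipital_labels(self, hemisphere: str) -> dict:
        return {
            "lingual": self.lingual[hemisphere],
            "pericalcarine": self.pericalcarine[hemisphere],
            "lateral_occipital": self.lateral_occipital[hemisphere],
        }

    @staticmethod
    def other(hemisphere: str) -> str:
        if hemisphere not in ("left", "right"):
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        return "right" if hemisphere == "left" else "left"

    def to_yaml(self, path: str) -> None:
        payload = {
            "thalamus": dict(self.thalamus),
            "lingual": dict(self.lingual),
            "pericalcarine": dict(self.pericalcarine),
            "lateral_occipital": dict(self.lateral_occipital),
            "gray_matter": {h: list(v) for h, v in self.gray_matter.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "ParcellationScheme":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["gray_matter"] = {h: tuple(v) for h, v in payload["gray_matter"].items()}
        return cls(**payload)


#: FreeSurfer aparc+aseg label ids for the roles used by the pipeline.
DEFAULT_SCHEME = ParcellationScheme(
    thalamus={"left": 10, "right": 49},
    lingual={"left": 1013, "right": 2013},
    pericalcarine={"left": 1021, "right": 2021},
    lateral_occipital={"left": 1011, "right": 2011},
    gray_matter={"left": (3,), "right": (42,)},
)


@dataclass(frozen=True)
class HalfSpace:
    """World-coordinate half-space: voxels with ``coord <axis> side of coord``.

    side='below' keeps world coordinates strictly below ``coord``;
    side='above' keeps those strictly above.
    """

    axis: str
    coord: float
    side: str

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {sorted(_AXES)}")
        if self.side not in ("below", "above"):
            raise ValueError("side must be 'below' or 'above'")

    def contains(self, world: np.ndarray) -> np.ndarray:
        c = world[..., _AXES[self.axis]]
        return c < self.coord if self.side == "below" else c > self.coord


@dataclass(frozen=True)
class Slab:
    """World-coordinate slab ``lo <= coord <= hi`` along one axis."""

    axis: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {sorted(_AXES)}")
        if self.lo > self.hi:
            raise ValueError("slab lo must not exceed hi")

    def contains(self, world: np.ndarray) -> np.ndarray:
        c = world[..., _AXES[self.axis]]
        return (c >= self.lo) & (c <= self.hi)


def _world_grid(volume: LabelVolume) -> np.ndarray:
    """World coordinates of every voxel centre, shape grid + (3,)."""
    idx = np.indices(volume.shape).reshape(3, -1).T.astype(float)
    world = volume.world_from_voxel(idx)
    return world.reshape(volume.shape + (3,))


def lgn_seed_from_thalamus(
    parcellation: LabelVolume, scheme: ParcellationScheme, hemisphere: str
) -> MaskVolume:
    """Posterior half of the thalamus parcel, the LGN seed surrogate.

    The thalamic centre of mass (unweighted voxel centroid, world RAS mm) is
    computed and the voxels strictly posterior to it (world y below the
    centroid y) are retained.  Posteriority is resolved in world
    coordinates, not voxel indices, so oblique affines behave correctly;
    voxels exactly on the centre-of-mass plane count as anterior.
    """
    thalamus = parcellation.mask_for(scheme.thalamus[hemisphere])
    if thalamus.n_voxels == 0:
        raise ValueError(f"thalamus label empty for hemisphere {hemisphere!r}")
    world = voxel_centers_world(thalamus)
    com_y = world[:, 1].mean()
    posterior = world[:, 1] < com_y
    if not posterior.any() or posterior.all():
        raise ValueError("degenerate thalamus: no voxels strictly posterior to the centre of mass")
    seed = np.zeros(parcellation.shape, dtype=bool)
    ijk = np.argwhere(thalamus.data)[posterior]
    seed[tuple(ijk.T)] = True
    return MaskVolume(seed, parcellation.affine)


def composite_occipital_roi(
    parcellation: LabelVolume, scheme: ParcellationScheme, hemisphere: str
) -> MaskVolume:
    """Union of lingual, pericalcarine and lateral occipital parcels."""
    union = np.zeros(parcellation.shape, dtype=bool)
    n_present = 0
    for role, label in scheme.occipital_labels(hemisphere).items():
        part = parcellation.data == label
        if not part.any():
            warnings.warn(f"occipital label {role!r} ({label}) empty; proceeding without it")
            continue
        union |= part
        n_present += 1
    if n_present == 0:
        raise ValueError("all occipital labels empty")
    return MaskVolume(union, parcellation.affine)


def exclusion_regions(
    parcellation: LabelVolume,
    scheme: ParcellationScheme,
    hemisphere: str,
    planes: list = (),
) -> MaskVolume:
    """Contralateral grey matter plus user-specified half-spaces/slabs.

    ``hemisphere`` is the hemisphere being tracked; the grey matter of the
    opposite hemisphere is always excluded.  ``planes`` is a list of
    :class:`HalfSpace` / :class:`Slab` specs in world mm.
    """
    contra = scheme.other(hemisphere)
    exclusion = np.isin(parcellation.data, scheme.gray_matter[contra])
    if planes:
        lo, hi = parcellation.world_bounds()
        world = _world_grid(parcellation)
        for plane in planes:
            axis = _AXES[plane.axis]
            coords = (plane.coord,) if isinstance(plane, HalfSpace) else (plane.lo, plane.hi)
            for c in coords:
                if not (lo[axis] - 1e-9 <= c <= hi[axis] + 1e-9):
                    raise ValueError(
                        f"plane coordinate {c} on axis {plane.axis!r} lies outside the grid"
                    )
            exclusion |= plane.contains(world)
    return MaskVolume(exclusion, parcellation.affine)
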