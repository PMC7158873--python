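"""Synthetic tract-geometry phantoms.

These phantoms stand in for patient anatomy so that every downstream stage
(ROI construction, streamline filtering, visitation mapping, disconnection
scoring) can be exercised against known ground truth.  A phantom consists of

* a bundle of streamlines jittered around a parametric centreline whose
  default shape bends anteriorly before sweeping back, emulating the
  anterior loop of the optic radiation;
* a label volume with a synthetic "thalamus" box at the anterior end of the
  curve, a composite "occipital" target (three adjacent parcels) at the
  posterior end, and a contralateral grey-matter block;
* an ellipsoidal "resection" mask at a configurable position.

All three share one RAS affine.  Outputs are bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .grids import LabelVolume, MaskVolume, centered_affine
from .roi import DEFAULT_SCHEME, ParcellationScheme
from .streamlines import StreamlineSet

__all__ = ["PhantomSpec", "make_tract_phantom"]

# left-hemisphere course: thalamus -> anterior bend -> occipital target (mm, RAS)
_DEFAULT_CENTERLINE = (
    (-14.0, 6.0, 0.0),
    (-26.0, 16.0, -2.0),
    (-32.0, 2.0, 0.0),
    (-28.0, -22.0, 1.0),
    (-22.0, -42.0, 2.0),
)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic optic-radiation phantom."""

    grid_shape: tuple[int, int, int] = (48, 64, 32)
    voxel_size: float = 2.0  # mm
    tract_centerline: tuple = _DEFAULT_CENTERLINE  # control points, world mm
    tract_radius: float = 4.0  # mm
    n_streamlines: int = 1000
    resection_center: tuple[float, float, float] = (-28.0, 10.0, 0.0)  # world mm
    resection_radii: tuple[float, float, float] = (8.0, 10.0, 8.0)  # mm per axis
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 along every axis")
        if self.tract_radius <= 0:
            raise ValueError("tract_radius must be positive")
        if self.n_streamlines < 1:
            raise ValueError("need at least one streamline")
        if len(self.tract_centerline) < 2:
            raise ValueError("centerline needs at least two control points")

    @property
    def affine(self) -> np.ndarray:
        return centered_affine(self.grid_shape, self.voxel_size)


def _sample_centerline(spec: PhantomSpec, step: float) -> np.ndarray:
    pts = np.asarray(spec.tract_centerline, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] <= 0:
        raise ValueError("centerline has zero length")
    n = max(int(np.ceil(t[-1] / step)) + 1, 2)
    s = np.linspace(0.0, t[-1], n)
    if len(pts) > 2:
        return np.asarray(CubicSpline(t, pts, axis=0)(s))
    frac = (s / t[-1])[:, None]
    return pts[0] + frac * (pts[1] - pts[0])


def _frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Perpendicular frame (n1, n2) at each centreline point."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    n1 = np.cross(tangents, ref)
    bad = np.linalg.norm(n1, axis=1) < 1e-8
    if bad.any():
        n1[bad] = np.cross(tangents[bad], [1.0, 0.0, 0.0])
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    return n1, n2


def _paint_box(
    labels: np.ndarray, volume: LabelVolume, center: np.ndarray, half_mm: np.ndarray, value: int
) -> None:
    idx = np.indices(labels.shape).reshape(3, -1).T
    world = volume.world_from_voxel(idx)
    inside = np.all(np.abs(world - center) <= half_mm, axis=1)
    labels.reshape(-1)[inside] = value


def make_tract_phantom(
    spec: PhantomSpec, scheme: ParcellationScheme = DEFAULT_SCHEME
) -> tuple[StreamlineSet, LabelVolume, MaskVolume]:
    """Build streamlines, parcellation and resection mask for a phantom.

    Streamlines share the centreline's course with a per-streamline radial
    offset drawn as half-normal (sd = tract_radius / 2) truncated at
    tract_radius, at a uniform azimuth in the plane perpendicular to the
    local tangent — every point therefore stays within tract_radius of the
    centreline.

    Raises ``ValueError`` if the centreline (plus radius margin) leaves the
    grid or if the resection ellipsoid contains no voxel of the grid.
    """
    rng = np.random.default_rng(spec.seed)
    affine = spec.affine
    template = LabelVolume(np.zeros(spec.grid_shape, dtype=np.int32), affine)
    lo, hi = template.world_bounds()

    step = spec.voxel_size / 2.0
    center_pts = _sample_centerline(spec, step)
    if np.any(center_pts < lo) or np.any(center_pts > hi):
        raise ValueError("tract centerline leaves the grid")

    n1, n2 = _frames(center_pts)
    radii = np.abs(rng.normal(0.0, spec.tract_radius / 2.0, size=spec.n_streamlines))
    radii = np.minimum(radii, spec.tract_radius)
    phis = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_streamlines)
    lines = []
    for r, phi in zip(radii, phis):
        offset = r * (np.cos(phi) * n1 + np.sin(phi) * n2)
        lines.append(center_pts + offset)
    streamlines = StreamlineSet(lines, step_size=step)

    hemisphere = "left" if center_pts[:, 0].mean() < 0 else "right"
    contra = ParcellationScheme.other(hemisphere)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    anterior_end = center_pts[0]
    posterior_end = center_pts[-1]
    box_half = np.full(3, max(5.0 * spec.voxel_size, spec.tract_radius + 2 * spec.voxel_size))
    _paint_box(labels, template, anterior_end, box_half, scheme.thalamus[hemisphere])
    # composite occipital target: three adjacent parcels stacked along z
    occ = scheme.occipital_labels(hemisphere)
    z_third = box_half[2] / 3.0
    for k, label in enumerate(occ.values()):
        center = posterior_end + np.array([0.0, 0.0, (k - 1) * 2.0 * z_third])
        _paint_box(labels, template, center, np.array([box_half[0], box_half[1], z_third]), label)
    # contralateral grey matter block, mirrored in x
    gm_center = np.array([-anterior_end[0], 0.0, 0.0])
    _paint_box(labels, template, gm_center, np.array([box_half[0], hi[1] * 0.9, box_half[2]]), scheme.gray_matter[contra][0])
    parcellation = LabelVolume(labels, affine)

    idx = np.indices(spec.grid_shape).reshape(3, -1).T
    world = template.world_from_voxel(idx)
    radii_r = np.maximum(np.asarray(spec.resection_radii, dtype=float), 1e-9)
    rel = (world - np.asarray(spec.resection_center)) / radii_r
    inside = (rel**2).sum(axis=1) <= 1.0
    if not inside.any():
        raise ValueError("resection ellipsoid lies entirely outside the grid")
    resection = MaskVolume(inside.reshape(spec.grid_shape), affine)

    return streamlines, parcellation, resection
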