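"""Streamline ROI filtering, visitation maps and tract-weighted averages.

A visitation map records, per voxel, the fraction of streamlines in a
bundle with at least one point inside the voxel (distinct-streamline
counting, so the tracking step size does not bias the weights).
Thresholding it at a visitation fraction (default 5%) yields the binary
tract mask used by the disconnection score, and using the fractions as
weights gives a single tract-weighted value per metric map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import MaskVolume, Volume3D
from .streamlines import StreamlineSet

__all__ = [
    "VisitationMap",
    "filter_streamlines",
    "visitation_map",
    "threshold_map",
    "tract_weighted_average",
]


@dataclass
class VisitationMap(Volume3D):
    """Per-voxel streamline visitation fraction in [0, 1]."""

    count: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.data < -1e-12) or np.any(self.data > 1 + 1e-12):
            raise ValueError("visitation fractions must lie in [0, 1]")


def _voxel_indices(points: np.ndarray, grid: Volume3D) -> np.ndarray:
    """World points -> integer voxel indices by rounding; no bounds check."""
    return np.rint(grid.voxel_from_world(points)).astype(np.int64)


def _inside(ijk: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    return np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)


def _visited_voxels(line: np.ndarray, grid: Volume3D, resample_step: float | None) -> np.ndarray:
    """Distinct in-grid voxel indices visited by one polyline.

    Segments longer than ``resample_step`` are subdivided first so that no
    traversed voxel is skipped between consecutive points.
    """
    if resample_step is not None and len(line) > 1:
        seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
        if np.any(seg > resample_step):
            pieces = [line[[0]]]
            for a, b, s in zip(line[:-1], line[1:], seg):
                n = max(int(np.ceil(s / resample_step)), 1)
                frac = np.linspace(0.0, 1.0, n + 1)[1:, None]
                pieces.append(a + frac * (b - a))
            line = np.vstack(pieces)
    ijk = _voxel_indices(line, grid)
    ok = _inside(ijk, grid.shape)
    if not ok.all():
        warnings.warn("streamline points outside the grid were ignored")
    return np.unique(ijk[ok], axis=0)


def filter_streamlines(
    s: StreamlineSet, seed: MaskVolume, target: MaskVolume, exclude: MaskVolume | None = None
) -> StreamlineSet:
    """Keep streamlines touching both seed and target and never the exclusion.

    A streamline touches a mask when any of its points falls inside a True
    voxel (point-in-voxel by world-to-voxel rounding).  Idempotent.
    """
    if not seed.same_grid(target) or (exclude is not None and not seed.same_grid(exclude)):
        raise ValueError("seed/target/exclusion masks must share one grid")
    if seed.n_voxels == 0 or target.n_voxels == 0:
        raise ValueError("seed and target masks must be non-empty")
    kept = []
    for line in s:
        ijk = _voxel_indices(line, seed)
        ok = _inside(ijk, seed.shape)
        ijk = ijk[ok]
        if len(ijk) == 0:
            continue
        i, j, k = ijk.T
        if not seed.data[i, j, k].any():
            continue
        if not target.data[i, j, k].any():
            continue
        if exclude is not None and exclude.data[i, j, k].any():
            continue
        kept.append(line)
    return StreamlineSet(kept, step_size=s.step_size)


def visitation_map(s: StreamlineSet, grid: Volume3D) -> VisitationMap:
    """Fraction of streamlines visiting each voxel of ``grid``.

    Long segments are resampled at half the smallest voxel edge before
    binning so no traversed voxel is skipped.
    """
    if s.count < 1:
        raise ValueError("need at least one streamline")
    edge = np.linalg.norm(grid.affine[:3, :3], axis=0).min()
    counts = np.zeros(grid.shape, dtype=np.int64)
    for line in s:
        visited = _visited_voxels(line, grid, resample_step=edge / 2.0)
        if len(visited):
            counts[tuple(visited.T)] += 1
    return VisitationMap(counts / float(s.count), grid.affine, count=s.count)


def threshold_map(v: VisitationMap, q: float = 0.05, mode: str = "total") -> MaskVolume:
    """Binary tract mask of voxels with visitation fraction >= threshold.

    mode='total' thresholds the fraction of all streamlines (q = 0.05 keeps
    voxels visited by at least 5% of streamlines); mode='max' thresholds at
    q times the map's maximum value.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if mode not in ("total", "max"):
        raise ValueError("mode must be 'total' or 'max'")
    cut = q if mode == "total" else q * float(v.data.max())
    mask = v.data >= cut
    if not mask.any():
        raise ValueError("thresholding removed the whole tract")
    return MaskVolume(mask, v.affine)


def tract_weighted_average(
    v: VisitationMap | Volume3D, metric: Volume3D, weighted: bool = True
) -> float:
    """Visitation-weighted mean of a metric map over the tract.

    ``sum_i w_i m_i / sum_i w_i`` with w the visitation fraction; voxels
    with undefined (non-finite) metric values are excluded from both sums.
    With ``weighted=False`` an unweighted mean over the support w > 0 is
    returned instead.
    """
    if not v.same_grid(metric):
        raise ValueError("visitation map and metric grids do not match")
    w = np.asarray(v.data, dtype=float)
    m = np.asarray(metric.data, dtype=float)
    defined = np.isfinite(m)
    w = np.where(defined, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("visitation map has no positive mass over defined metric voxels")
    if not weighted:
        support = (w > 0) & defined
        return float(m[support].mean())
    return float((w * np.where(defined, m, 0.0)).sum() / total)
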