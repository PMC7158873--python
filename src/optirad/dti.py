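"""Diffusion tensor fitting and scalar maps (FA, MD, AD, RD).

Log-linear weighted least-squares tensor fit, with squared-signal weights —
the usual variance stabilisation for log-transformed magnitude (Rician)
data.  Negative eigenvalues from noisy fits are clamped to zero before the
scalars are computed and the affected voxels flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import MaskVolume, Volume3D
from .protocol import DiffusionProtocol
from .signal_sim import SignalVolume

__all__ = ["DTIMetricsMap", "fit_dti", "tensor_scalars"]


@dataclass
class DTIMetricsMap:
    """Per-voxel DTI scalars plus eigensystem, on the signal's grid."""

    FA: Volume3D
    MD: Volume3D
    AD: Volume3D
    RD: Volume3D
    eigenvalues: np.ndarray  # (..., 3), descending
    principal_direction: np.ndarray  # (..., 3)
    clamped: np.ndarray  # bool, eigenvalue clamped at zero
    excluded: np.ndarray  # bool, voxel dropped (non-positive signal)

    def __getitem__(self, name: str) -> Volume3D:
        return getattr(self, name)


def _design_matrix(protocol: DiffusionProtocol) -> np.ndarray:
    """Rows: [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    b = protocol.bvals
    g = protocol.bvecs
    cols = [
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2.0 * b * g[:, 0] * g[:, 1],
        -2.0 * b * g[:, 0] * g[:, 2],
        -2.0 * b * g[:, 1] * g[:, 2],
    ]
    return np.column_stack(cols)


def tensor_scalars(eigenvalues: np.ndarray) -> dict:
    """FA/MD/AD/RD from eigenvalues sorted descending along the last axis."""
    l1, l2, l3 = eigenvalues[..., 0], eigenvalues[..., 1], eigenvalues[..., 2]
    md = (l1 + l2 + l3) / 3.0
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return {"FA": np.clip(fa, 0.0, 1.0), "MD": md, "AD": l1, "RD": (l2 + l3) / 2.0}


def fit_dti(
    signal: SignalVolume, protocol: DiffusionProtocol | None = None, mask: MaskVolume | None = None
) -> DTIMetricsMap:
    """Weighted log-linear tensor fit over the masked voxels.

    Requires at least six unique (up to sign) nonzero gradient directions
    spanning a full-rank design; voxels with non-positive signal anywhere
    are excluded and flagged rather than fitted.
    """
    protocol = protocol if protocol is not None else signal.protocol
    if protocol.n_unique_directions() < 6:
        raise ValueError("DTI requires >= 6 unique nonzero gradient directions")
    design = _design_matrix(protocol)
    if np.linalg.matrix_rank(design) < 7:
        raise ValueError("rank-deficient design: gradient directions are degenerate (coplanar)")

    grid_shape = signal.data.shape[:3]
    flat = signal.flat()
    if mask is not None:
        if mask.shape != grid_shape:
            raise ValueError("mask grid does not match the signal grid")
        sel = mask.data.reshape(-1)
    else:
        sel = np.ones(flat.shape[0], dtype=bool)

    n_vox = flat.shape[0]
    evals = np.full((n_vox, 3), np.nan)
    evecs1 = np.full((n_vox, 3), np.nan)
    clamped = np.zeros(n_vox, dtype=bool)
    excluded = np.zeros(n_vox, dtype=bool)

    idx = np.flatnonzero(sel)
    s = flat[idx]
    positive = (s > 0).all(axis=1)
    excluded[idx[~positive]] = True
    idx = idx[positive]
    s = s[positive]

    if len(idx):
        y = np.log(s)  # (n, N)
        w = s**2
        # batched weighted least squares: (A^T W A) x = A^T W y per voxel
        aw = design[None, :, :] * w[:, :, None]  # (n, N, 7)
        lhs = np.einsum("nji,jk->nik", aw, design)
        rhs = np.einsum("nji,nj->ni", aw, y)
        coef = np.linalg.solve(lhs, rhs[:, :, None])[:, :, 0]  # (n, 7)

        d = np.empty((len(idx), 3, 3))
        d[:, 0, 0] = coef[:, 1]
        d[:, 1, 1] = coef[:, 2]
        d[:, 2, 2] = coef[:, 3]
        d[:, 0, 1] = d[:, 1, 0] = coef[:, 4]
        d[:, 0, 2] = d[:, 2, 0] = coef[:, 5]
        d[:, 1, 2] = d[:, 2, 1] = coef[:, 6]
        lam, vec = np.linalg.eigh(d)  # ascending
        lam = lam[:, ::-1]
        vec = vec[:, :, ::-1]
        clamped[idx] = (lam < 0).any(axis=1)
        lam = np.maximum(lam, 0.0)
        evals[idx] = lam
        evecs1[idx] = vec[:, :, 0]

    scalars = tensor_scalars(evals)
    affine = signal.affine

    def vol(arr: np.ndarray) -> Volume3D:
        return Volume3D(arr.reshape(grid_shape), affine)

    return DTIMetricsMap(
        FA=vol(scalars["FA"]),
        MD=vol(scalars["MD"]),
        AD=vol(scalars["AD"]),
        RD=vol(scalars["RD"]),
        eigenvalues=evals.reshape(grid_shape + (3,)),
        principal_direction=evecs1.reshape(grid_shape + (3,)),
        clamped=clamped.reshape(grid_shape),
        excluded=excluded.reshape(grid_shape),
    )
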