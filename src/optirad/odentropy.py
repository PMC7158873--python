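"""Orientation dispersion entropy of the fibre orientation distribution.

The directional (non-averaged) part of the multi-shell signal is
deconvolved with the voxel's fitted axisymmetric microdomain kernel in an
even real spherical-harmonic basis (Funk-Hecke: each harmonic order l is
scaled by the kernel's Legendre coefficient), giving the fibre orientation
distribution p(n).  Negative lobes are clipped and p renormalised to unit
mass on the sphere.  The summary scalar is the normalised negentropy

    ODEntropy = 1 - H[p] / ln(4 pi),    H[p] = -int p ln p dOmega,

which is 0 for a uniform orientation distribution (grey matter, CSF) and
approaches 1 for highly coherent bundles.  Voxels whose kernel is too close
to isotropic for the deconvolution to be well posed are flagged and set
to 0.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre, sph_harm_y

from .grids import MaskVolume, Volume3D
from .protocol import DiffusionProtocol, fibonacci_directions
from .signal_sim import SignalVolume
from .smt import SMTMetricsMap

__all__ = ["od_entropy", "real_even_sh_basis", "kernel_legendre_coeffs"]

_LN_4PI = float(np.log(4.0 * np.pi))


def real_even_sh_basis(order: int, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real, even-order spherical-harmonic basis evaluated at unit vectors.

    Returns ``(basis, degrees)`` with basis shape ``(n_dirs, n_coeffs)`` and
    ``degrees[i]`` the harmonic degree l of column i.  Uses the orthonormal
    real basis built from complex harmonics (m < 0 -> imaginary part,
    m > 0 -> real part, both scaled by sqrt(2)).
    """
    dirs = np.asarray(dirs, dtype=float)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])  # azimuth
    cols = []
    degrees = []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                col = np.sqrt(2.0) * (-1.0) ** m * y.imag
            elif m == 0:
                col = y.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** m * y.real
            cols.append(col)
            degrees.append(l)
    return np.column_stack(cols), np.asarray(degrees)


def kernel_legendre_coeffs(
    b: float, lambda_par: float, lambda_perp: float, order: int, n_quad: int = 64
) -> np.ndarray:
    """Funk-Hecke eigenvalues 2 pi * int K(t) P_l(t) dt of the microdomain kernel.

    ``K(t) = exp(-b (l_perp + (l_par - l_perp) t^2))`` with t the cosine
    between gradient and microdomain axis; returns one coefficient per even
    degree 0, 2, ..., order.
    """
    t, w = leggauss(n_quad)
    k = np.exp(-b * (lambda_perp + (lambda_par - lambda_perp) * t**2))
    return np.array(
        [2.0 * np.pi * np.sum(w * k * eval_legendre(l, t)) for l in range(0, order + 1, 2)]
    )


def od_entropy(
    signal: SignalVolume,
    protocol: DiffusionProtocol | None = None,
    smt: SMTMetricsMap | None = None,
    mask: MaskVolume | None = None,
    sh_order: int = 8,
    reg: float = 1e-3,
    isotropy_tol: float = 1e-3,
    n_entropy_dirs: int = 1200,
) -> Volume3D:
    """Per-voxel orientation dispersion entropy map.

    Parameters
    ----------
    smt
        Fitted microscopic diffusivities providing the per-voxel
        deconvolution kernel; required.
    reg
        Laplace-Beltrami regularisation weight (relative), the standard
        stabiliser for spherical deconvolution in a truncated basis.
    isotropy_tol
        Minimum |ratio| of the degree-2 to degree-0 kernel coefficient for
        the deconvolution to be attempted; below it the voxel is set to 0.
    """
    protocol = protocol if protocol is not None else signal.protocol
    if smt is None:
        raise ValueError("od_entropy requires a fitted SMTMetricsMap")
    grid_shape = signal.data.shape[:3]
    flat = signal.flat()
    n_vox = flat.shape[0]
    sel = mask.data.reshape(-1) if mask is not None else np.ones(n_vox, dtype=bool)

    dw = ~protocol.is_b0
    dirs = protocol.bvecs[dw]
    bvals = protocol.bvals[dw]
    basis, degrees = real_even_sh_basis(sh_order, dirs)
    lb_penalty = (degrees**2) * (degrees + 1.0) ** 2

    ent_dirs = fibonacci_directions(n_entropy_dirs)
    ent_basis, _ = real_even_sh_basis(sh_order, ent_dirs)
    d_omega = 4.0 * np.pi / n_entropy_dirs

    b0 = flat[:, protocol.is_b0].mean(axis=1)
    long_flat = smt.Long.data.reshape(-1)
    trans_flat = smt.Trans.data.reshape(-1)

    out = np.zeros(n_vox)
    flags = np.zeros(n_vox, dtype=bool)
    shells = protocol.shells
    for v in np.flatnonzero(sel):
        l_par, l_perp = long_flat[v], trans_flat[v]
        if not (np.isfinite(l_par) and np.isfinite(l_perp)) or b0[v] <= 0:
            flags[v] = True
            continue
        coeffs = {b: kernel_legendre_coeffs(b, l_par, l_perp, sh_order) for b in shells}
        aniso = max(abs(coeffs[b][1] / coeffs[b][0]) for b in shells)
        if aniso < isotropy_tol:
            flags[v] = True  # near-isotropic kernel: deconvolution ill posed
            continue
        scale = np.empty((len(bvals), basis.shape[1]))
        for b in shells:
            rows = np.round(bvals) == np.round(b)
            per_degree = coeffs[b][(degrees // 2)]
            scale[rows] = per_degree
        design = basis * scale
        y = flat[v, dw] / b0[v]
        lhs = design.T @ design
        lam = reg * np.trace(lhs) / len(lhs)
        lhs = lhs + lam * np.diag(lb_penalty)
        f = np.linalg.solve(lhs, design.T @ y)
        p = ent_basis @ f
        p = np.clip(p, 0.0, None)
        mass = p.sum() * d_omega
        if mass <= 0:
            flags[v] = True
            continue
        p /= mass
        nz = p > 0
        h = -np.sum(p[nz] * np.log(p[nz])) * d_omega
        out[v] = float(np.clip(1.0 - h / _LN_4PI, 0.0, 1.0))

    result = Volume3D(out.reshape(grid_shape), signal.affine)
    smt.ODEntropy = result
    smt.flags = smt.flags | flags.reshape(grid_shape)
    return result
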