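"""Spherical mean technique (SMT): microscopic diffusivities from shell means.

For any fixed b-value the direction-averaged (spherical-mean) signal of a
voxel filled with identical axisymmetric microdomains is independent of the
fibre orientation distribution:

    e(b) = exp(-b l_perp) * sqrt(pi) * erf(sqrt(b (l_par - l_perp)))
           / (2 sqrt(b (l_par - l_perp)))

with the isotropic limit e(b) -> exp(-b l_par) as l_perp -> l_par and
e(0) = 1.  Fitting this model to the per-shell means of a multi-shell
acquisition yields the microscopic parallel/perpendicular diffusivities
(Long/Trans), from which microscopic mean diffusivity and microscopic
fractional anisotropy follow:

    muMD = (Long + 2 Trans) / 3
    muFA = |Long - Trans| / sqrt(Long^2 + 2 Trans^2)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .grids import MaskVolume, Volume3D
from .protocol import DiffusionProtocol
from .signal_sim import MAX_DIFFUSIVITY, SignalVolume

__all__ = ["SMTMetricsMap", "shell_spherical_mean", "smt_mean_model", "fit_smt"]


@dataclass
class SMTMetricsMap:
    """Per-voxel SMT scalars on the signal's grid."""

    Long: Volume3D  # microscopic lambda_par, mm^2/s
    Trans: Volume3D  # microscopic lambda_perp, mm^2/s
    muMD: Volume3D
    muFA: Volume3D
    flags: np.ndarray  # bool, boundary/non-converged fit or bad b0
    ODEntropy: Volume3D | None = None

    def __getitem__(self, name: str) -> Volume3D:
        vol = getattr(self, name)
        if vol is None:
            raise KeyError(name)
        return vol


def smt_mean_model(lambda_par, lambda_perp, b) -> np.ndarray:
    """Predicted spherical-mean attenuation for given diffusivities.

    Vectorised over any broadcastable combination of arguments; handles the
    isotropic limit and b = 0 smoothly (second-order series for small
    arguments).
    """
    lambda_par = np.asarray(lambda_par, dtype=float)
    lambda_perp = np.asarray(lambda_perp, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(lambda_perp > lambda_par + 1e-15):
        raise ValueError("lambda_perp must not exceed lambda_par")
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    d = b * (lambda_par - lambda_perp)
    with np.errstate(invalid="ignore", divide="ignore"):
        exact = np.sqrt(np.pi) * erf(np.sqrt(d)) / (2.0 * np.sqrt(d))
    series = 1.0 - d / 3.0 + d**2 / 10.0  # erf ratio expansion near d = 0
    ratio = np.where(d > 1e-8, exact, series)
    return np.exp(-b * lambda_perp) * ratio


def shell_spherical_mean(
    signal: SignalVolume, protocol: DiffusionProtocol | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel, per-shell arithmetic mean of b0-normalised signals.

    Returns ``(shells, means, bad_b0)`` where ``means`` has shape
    ``(n_voxels, n_shells)``, the normaliser is the mean of all b = 0
    volumes, and voxels with non-positive b0 are flagged (NaN means).
    """
    protocol = protocol if protocol is not None else signal.protocol
    shells = protocol.shells
    for b in shells:
        if len(protocol.shell_indices(b)) < 15:
            raise ValueError(f"shell b={b:.0f} has fewer than 15 directions")
    flat = signal.flat()
    b0 = flat[:, protocol.is_b0].mean(axis=1)
    bad = b0 <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = flat / b0[:, None]
    means = np.column_stack([norm[:, protocol.shell_indices(b)].mean(axis=1) for b in shells])
    means[bad] = np.nan
    return shells, means, bad


def _fit_means(shells: np.ndarray, means: np.ndarray, grid_n: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Fit (lambda_par, lambda_perp) per voxel to its shell means.

    Multi-start evaluation on a grid over the feasible triangle
    0 <= l_perp <= l_par <= MAX_DIFFUSIVITY, then bounded local refinement
    in the (l_par, fraction) parameterisation.  Returns parameters and a
    boundary/non-convergence flag.
    """
    lp_grid = np.linspace(1e-5, MAX_DIFFUSIVITY, grid_n)
    frac_grid = np.linspace(0.0, 1.0, grid_n)
    lp, fr = np.meshgrid(lp_grid, frac_grid, indexing="ij")
    lp = lp.ravel()
    lt = (lp * fr.ravel())
    pred = smt_mean_model(lp[:, None], lt[:, None], shells[None, :])  # (grid, n_shells)

    n = means.shape[0]
    params = np.full((n, 2), np.nan)
    flags = np.zeros(n, dtype=bool)
    ok = np.isfinite(means).all(axis=1)
    flags[~ok] = True
    if ok.any():
        m = means[ok]
        cost = ((pred[None, :, :] - m[:, None, :]) ** 2).sum(axis=2)  # (n_ok, grid)
        best = cost.argmin(axis=1)
        ids = np.flatnonzero(ok)
        for row, g in zip(ids, best):
            x0 = np.array([lp[g], lt[g] / max(lp[g], 1e-12)])
            res = least_squares(
                lambda x: smt_mean_model(x[0], x[0] * x[1], shells) - means[row],
                np.clip(x0, [1e-6, 0.0], [MAX_DIFFUSIVITY, 1.0]),
                bounds=([1e-6, 0.0], [MAX_DIFFUSIVITY, 1.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            l_par = res.x[0]
            l_perp = res.x[0] * res.x[1]
            params[row] = (l_par, l_perp)
            at_bound = l_par >= MAX_DIFFUSIVITY * (1 - 1e-6) or res.x[1] >= 1 - 1e-9
            flags[row] = (not res.success) or at_bound
    return params, flags


def fit_smt(
    signal: SignalVolume,
    protocol: DiffusionProtocol | None = None,
    mask: MaskVolume | None = None,
    grid_n: int = 32,
) -> SMTMetricsMap:
    """Fit the spherical-mean model voxelwise and derive muMD/muFA."""
    protocol = protocol if protocol is not None else signal.protocol
    shells = protocol.shells
    if len(shells) < 2:
        raise ValueError("SMT requires at least two distinct nonzero shells")
    grid_shape = signal.data.shape[:3]
    _, means, bad = shell_spherical_mean(signal, protocol)
    if mask is not None:
        if mask.shape != grid_shape:
            raise ValueError("mask grid does not match the signal grid")
        sel = mask.data.reshape(-1)
    else:
        sel = np.ones(means.shape[0], dtype=bool)

    n = means.shape[0]
    params = np.full((n, 2), np.nan)
    flags = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(sel)
    p, f = _fit_means(shells, means[idx], grid_n=grid_n)
    params[idx] = p
    flags[idx] = f | bad[idx]

    l_par, l_perp = params[:, 0], params[:, 1]
    mu_md = (l_par + 2.0 * l_perp) / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_fa = np.abs(l_par - l_perp) / np.sqrt(l_par**2 + 2.0 * l_perp**2)
    mu_fa = np.where(np.isfinite(mu_fa), mu_fa, np.nan)

    affine = signal.affine

    def vol(arr: np.ndarray) -> Volume3D:
        return Volume3D(arr.reshape(grid_shape), affine)

    return SMTMetricsMap(
        Long=vol(l_par),
        Trans=vol(l_perp),
        muMD=vol(mu_md),
        muFA=vol(mu_fa),
        flags=flags.reshape(grid_shape),
    )
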