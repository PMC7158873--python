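"""Multi-shell diffusion acquisition protocols.

A protocol pairs one b-value (s/mm^2) and one unit gradient direction with
every volume of a 4-D diffusion acquisition.  The default protocol mirrors a
paediatric multi-shell sequence: two shells at b = 1000 and 2200 s/mm^2 with
60 non-collinear directions each, plus 13 interleaved b = 0 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionProtocol",
    "fibonacci_directions",
    "electrostatic_directions",
    "default_protocol",
]

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2


def fibonacci_directions(n: int, offset: float = 0.5) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (Fibonacci lattice).

    Deterministic, well spread for any n; used both for gradient tables and
    for orientation quadrature grids.
    """
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + offset) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def electrostatic_directions(n: int, offset: float = 0.5, maxiter: int = 2000) -> np.ndarray:
    """Unit directions optimised by antipodal electrostatic repulsion.

    Minimises the Coulomb energy of the n antipodal point pairs {x, -x}
    (the standard construction for diffusion gradient tables) starting from
    a Fibonacci lattice; fully deterministic.
    """
    from scipy.optimize import minimize

    def energy_grad(flat: np.ndarray):
        p = flat.reshape(n, 3)
        r = np.linalg.norm(p, axis=1, keepdims=True)
        u = p / r
        energy = 0.0
        grad = np.zeros_like(u)
        for sign in (1.0, -1.0):
            diff = u[:, None, :] - sign * u[None, :, :]
            d2 = (diff**2).sum(axis=2)
            np.fill_diagonal(d2, np.inf)
            d2[d2 < 1e-12] = np.inf  # x against its own antipode
            d = np.sqrt(d2)
            energy += 0.5 * (1.0 / d).sum()
            grad -= (diff / (d2 * d)[:, :, None]).sum(axis=1)
        tangential = grad - (grad * u).sum(axis=1, keepdims=True) * u
        return energy, (tangential / r).ravel()

    x0 = fibonacci_directions(n, offset=offset).ravel()
    res = minimize(energy_grad, x0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    dirs = res.x.reshape(n, 3)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass
class DiffusionProtocol:
    """Per-volume b-values and unit gradient directions.

    Volumes with ``b <= b0_threshold`` are treated as non-diffusion-weighted
    (b = 0); the remaining volumes are grouped into shells by rounded
    b-value.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n, 3)")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("bvals and bvecs length mismatch")
        norms = np.linalg.norm(self.bvecs[~self.is_b0], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-4):
            raise ValueError("gradient directions of diffusion-weighted volumes must be unit vectors")

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def shells(self) -> np.ndarray:
        """Sorted distinct nonzero b-values (rounded to 1 s/mm^2)."""
        return np.unique(np.round(self.bvals[~self.is_b0]))

    def shell_indices(self, b: float) -> np.ndarray:
        return np.flatnonzero((~self.is_b0) & (np.round(self.bvals) == np.round(b)))

    def n_unique_directions(self) -> int:
        """Nonzero directions distinct up to antipodal symmetry."""
        d = self.bvecs[~self.is_b0]
        d = d * np.sign(d[:, [2]] + np.where(d[:, [2]] == 0, 1.0, 0.0))
        return len(np.unique(np.round(d, 6), axis=0))

    # ---- FSL-style text I/O -------------------------------------------------

    def to_files(self, bval_path: str, bvec_path: str) -> None:
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")

    @classmethod
    def from_files(
        cls, bval_path: str, bvec_path: str, b0_threshold: float = DEFAULT_B0_THRESHOLD
    ) -> "DiffusionProtocol":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        # b=0 rows are conventionally written as zero vectors; keep them but
        # replace exact zeros with a unit placeholder so validation passes.
        zero = np.linalg.norm(bvecs, axis=1) == 0
        bvecs[zero] = (0.0, 0.0, 1.0)
        return cls(bvals, bvecs, b0_threshold)


def default_protocol(
    b_shells: tuple[float, ...] = (1000.0, 2200.0),
    n_dirs_per_shell: int = 60,
    n_b0: int = 13,
) -> DiffusionProtocol:
    """Two-shell protocol with interleaved b = 0 volumes.

    Each shell gets its own electrostatically-repelled direction set (the
    shells are seeded differently so they do not share directions).
    """
    n_total = n_b0 + n_dirs_per_shell * len(b_shells)
    b0_positions = set(np.round(np.linspace(0, n_total - 1, n_b0)).astype(int))
    dw_bvals = np.repeat(b_shells, n_dirs_per_shell)
    dw_bvecs = []
    for s, _ in enumerate(b_shells):
        dirs = electrostatic_directions(n_dirs_per_shell, offset=0.5 + 0.17 * s)
        dw_bvecs.append(dirs)
    dw_bvecs = np.vstack(dw_bvecs)
    # interleave shells so that consecutive DW volumes alternate b-values
    order = np.argsort(np.tile(np.arange(n_dirs_per_shell), len(b_shells)), kind="stable")
    dw_bvals = dw_bvals[order]
    dw_bvecs = dw_bvecs[order]

    bvals = np.zeros(n_total)
    bvecs = np.zeros((n_total, 3))
    bvecs[:, 2] = 1.0
    dw_i = 0
    for vol in range(n_total):
        if vol in b0_positions:
            continue
        bvals[vol] = dw_bvals[dw_i]
        bvecs[vol] = dw_bvecs[dw_i]
        dw_i += 1
    return DiffusionProtocol(bvals, bvecs)
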