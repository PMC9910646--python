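"""Regularized least-squares synthesis of a prescribed field hotspot.

The transmitter moments M (stacked, 3N_t) map linearly to the interior
electric field through the system matrix G_E (3N_d × 3N_t) whose column
3n+j is the stacked E field of a unit moment along axis j at transmitter n:

    E_mod = G_E M.

Given a desired field E_d, Tikhonov-regularized least squares minimizes

    ΔE(M) = ‖G_E M − E_d‖² + α‖M‖²,

whose unique minimizer for α > 0 is the Hermitian normal-equation solution

    M_opt = (G_Eᴴ G_E + αI)⁻¹ G_Eᴴ E_d.

Stacking convention: per point [Ex, Ey, Ez], points in row-major order;
per transmitter [mx, my, mz]; all vectors are columns.

The misfit is evaluated over the full tissue interior (with E_d ≈ 0 away
from the hotspot), not only over the hotspot voxels — penalizing fringe
fields is what suppresses sidelobes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.linalg

from .array_geometry import ArrayLayout
from .dipole_fields import MagneticDipole, dipole_E
from .forward_solver import GreensTable
from .tissue_properties import Medium

__all__ = [
    "DesiredField",
    "SystemMatrix",
    "DipoleSolution",
    "gaussian_target",
    "assemble_system",
    "solve_rls",
    "steer",
    "choose_alpha",
]


@dataclasses.dataclass
class DesiredField:
    """Target field profile: evaluation points (N_d, 3) and the stacked
    desired phasor E_d (3N_d,), plus profile metadata for steering."""

    grid: np.ndarray
    E_d: np.ndarray
    description: dict

    def __post_init__(self) -> None:
        self.grid = np.atleast_2d(np.asarray(self.grid, float))
        self.E_d = np.asarray(self.E_d, complex).reshape(-1)
        if self.E_d.size != 3 * self.grid.shape[0]:
            raise ValueError("E_d must have length 3*N_d")


@dataclasses.dataclass
class SystemMatrix:
    """The linear map G_E (3N_d × 3N_t) from stacked moments to the stacked
    interior E field, with the grid/layout it was assembled on."""

    G_E: np.ndarray
    grid: np.ndarray
    layout: ArrayLayout
    frequency: float

    def __post_init__(self) -> None:
        nd = self.grid.shape[0]
        nt = self.layout.count
        if self.G_E.shape != (3 * nd, 3 * nt):
            raise ValueError(f"G_E must be (3N_d, 3N_t) = ({3*nd}, {3*nt}), got {self.G_E.shape}")


@dataclasses.dataclass
class DipoleSolution:
    """Optimal stacked moments with the regularization and realized field.

    `residual` is the full objective ΔE = ‖E_mod − E_d‖² + α‖M‖² at M_opt;
    `misfit` and `moment_norm` are its two pieces.
    """

    M_opt: np.ndarray
    alpha: float
    residual: float
    E_mod: np.ndarray
    misfit: float
    moment_norm: float


def gaussian_target(
    grid: np.ndarray,
    center: np.ndarray,
    sigma_g: float,
    peak: float,
    polarization: np.ndarray,
) -> DesiredField:
    """Isotropic 3D Gaussian hotspot along a fixed polarization:

        E_d(r) = peak · exp(−‖r−center‖²/(2 σ_g²)) · p̂

    FWHM of the amplitude profile is 2·sqrt(2 ln 2)·σ_g (≈ 2.355 cm for
    σ_g = 1 cm).
    """
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    pol = np.asarray(polarization, float)
    if abs(np.linalg.norm(pol) - 1.0) > 1e-9:
        raise ValueError("polarization must be unit-norm")
    grid = np.atleast_2d(np.asarray(grid, float))
    center = np.asarray(center, float).reshape(3)
    lo, hi = grid.min(axis=0), grid.max(axis=0)
    if np.any(center < lo) or np.any(center > hi):
        warnings.warn("hotspot center lies outside the evaluation-grid bounding box")
    r2 = np.sum((grid - center) ** 2, axis=1)
    amp = peak * np.exp(-r2 / (2.0 * sigma_g**2))
    E = amp[:, None] * pol[None, :]
    return DesiredField(
        grid=grid,
        E_d=E.reshape(-1),
        description={
            "profile": "gaussian",
            "center": center.tolist(),
            "sigma_g": float(sigma_g),
            "peak": float(peak),
            "polarization": pol.tolist(),
        },
    )


def spherical_target(
    grid: np.ndarray, center: np.ndarray, radius: float, peak: float, polarization: np.ndarray
) -> DesiredField:
    """Uniform spherical hotspot: peak·p̂ inside `radius`, zero outside."""
    pol = np.asarray(polarization, float)
    if abs(np.linalg.norm(pol) - 1.0) > 1e-9:
        raise ValueError("polarization must be unit-norm")
    grid = np.atleast_2d(np.asarray(grid, float))
    center = np.asarray(center, float).reshape(3)
    inside = np.linalg.norm(grid - center, axis=1) <= radius
    E = np.where(inside[:, None], peak * pol[None, :], 0.0).astype(complex)
    return DesiredField(
        grid=grid,
        E_d=E.reshape(-1),
        description={
            "profile": "sphere",
            "center": center.tolist(),
            "radius": float(radius),
            "peak": float(peak),
            "polarization": pol.tolist(),
        },
    )


def assemble_system(
    fields_source: GreensTable | Medium,
    layout: ArrayLayout,
    grid: np.ndarray,
) -> SystemMatrix:
    """Build G_E column by column from unit-moment fields.

    `fields_source` is either a homogeneous :class:`Medium` (analytic mode —
    closed-form dipole fields) or a :class:`GreensTable` (numerical mode —
    VIE solutions sampled at the grid points, which must coincide with
    phantom voxel centers).
    """
    grid = np.atleast_2d(np.asarray(grid, float))
    nd, nt = grid.shape[0], layout.count
    G = np.empty((3 * nd, 3 * nt), dtype=complex)

    if isinstance(fields_source, Medium):
        for n, pos in enumerate(layout.positions):
            for j in range(3):
                m = np.zeros(3, complex)
                m[j] = 1.0
                E = dipole_E(MagneticDipole(pos, m), grid, fields_source)
                G[:, 3 * n + j] = E.reshape(-1)
        frequency = fields_source.frequency
    elif isinstance(fields_source, GreensTable):
        table = fields_source
        ref = table.entries[(0, 0)].points
        # map each evaluation point to its voxel index in the table grid
        idx = np.empty(nd, dtype=int)
        for i, p in enumerate(grid):
            j = np.argmin(np.linalg.norm(ref - p, axis=1))
            if np.linalg.norm(ref[j] - p) > 1e-6:
                raise ValueError("evaluation grid points must coincide with table voxel centers")
            idx[i] = j
        if table.n_transmitters != nt:
            raise ValueError("layout count does not match Green's table")
        for n in range(nt):
            for j in range(3):
                G[:, 3 * n + j] = table.entries[(n, j)].E[idx].reshape(-1)
        frequency = table.frequency
    else:
        raise TypeError("fields_source must be a Medium or a GreensTable")

    return SystemMatrix(G_E=G, grid=grid, layout=layout, frequency=frequency)


def solve_rls(system: SystemMatrix, target: DesiredField, alpha: float) -> DipoleSolution:
    """Closed-form Tikhonov solution of the focusing problem.

    Solves the Hermitian normal equations (G_Eᴴ G_E + αI) M = G_Eᴴ E_d by
    Cholesky factorization.  With α = 0 the system matrix must be
    numerically full column rank, otherwise the problem is ill-posed and an
    error directs the caller to regularize.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    G = system.G_E
    E_d = target.E_d
    if E_d.size != G.shape[0]:
        raise ValueError("target grid does not match system matrix")
    GhG = G.conj().T @ G
    rhs = G.conj().T @ E_d
    if alpha == 0.0:
        if np.linalg.matrix_rank(G) < G.shape[1]:
            raise np.linalg.LinAlgError(
                "system matrix is rank-deficient: the unregularized problem is "
                "ill-posed; use alpha > 0 (Tikhonov regularization)"
            )
        A = GhG
    else:
        A = GhG + alpha * np.eye(G.shape[1])
    c, low = scipy.linalg.cho_factor(A)
    M = scipy.linalg.cho_solve((c, low), rhs)
    E_mod = G @ M
    misfit = float(np.linalg.norm(E_mod - E_d) ** 2)
    mnorm = float(np.linalg.norm(M) ** 2)
    return DipoleSolution(
        M_opt=M,
        alpha=float(alpha),
        residual=misfit + alpha * mnorm,
        E_mod=E_mod,
        misfit=misfit,
        moment_norm=mnorm,
    )


def steer(system: SystemMatrix, target_template: DesiredField, new_center: np.ndarray, alpha: float) -> DipoleSolution:
    """Re-solve for the template hotspot moved to `new_center`, reusing the
    assembled system matrix (no new Green's-function solves)."""
    desc = dict(target_template.description)
    new_center = np.asarray(new_center, float).reshape(3)
    lo, hi = system.grid.min(axis=0), system.grid.max(axis=0)
    if np.any(new_center < lo) or np.any(new_center > hi):
        raise ValueError("steering center lies outside the tissue evaluation region")
    if desc.get("profile") == "gaussian":
        tgt = gaussian_target(
            system.grid, new_center, desc["sigma_g"], desc["peak"], np.asarray(desc["polarization"])
        )
    elif desc.get("profile") == "sphere":
        tgt = spherical_target(
            system.grid, new_center, desc["radius"], desc["peak"], np.asarray(desc["polarization"])
        )
    else:
        raise ValueError(f"cannot steer target profile {desc.get('profile')!r}")
    return solve_rls(system, tgt, alpha)


def choose_alpha(
    system: SystemMatrix,
    target: DesiredField | None = None,
    strategy: str = "fixed-relative",
    tau: float = 1e-3,
    n_grid: int = 25,
) -> float:
    """Deterministic regularization choice.

    fixed-relative: α = τ · s_max(G_E)² (τ = 0 passes through α = 0).
    l-curve: scan a log grid of α, return the point of maximum curvature of
    (log misfit, log ‖M‖).
    """
    s_max = float(np.linalg.norm(system.G_E, 2))
    if strategy == "fixed-relative":
        return tau * s_max**2
    if strategy != "l-curve":
        raise ValueError("strategy must be 'fixed-relative' or 'l-curve'")
    if target is None:
        raise ValueError("l-curve strategy requires a target")
    alphas = s_max**2 * np.logspace(-8, 0, n_grid)
    rho = np.empty(n_grid)
    eta = np.empty(n_grid)
    for i, a in enumerate(alphas):
        sol = solve_rls(system, target, a)
        rho[i] = np.log(max(sol.misfit, 1e-300))
        eta[i] = np.log(max(sol.moment_norm, 1e-300))
    t = np.log(alphas)
    dr, de = np.gradient(rho, t), np.gradient(eta, t)
    d2r, d2e = np.gradient(dr, t), np.gradient(de, t)
    curvature = (dr * d2e - de * d2r) / np.maximum((dr**2 + de**2) ** 1.5, 1e-300)
    return float(alphas[int(np.argmax(curvature))])
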