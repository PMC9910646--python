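"""Closed-form fields of an infinitesimal magnetic dipole in an unbounded
homogeneous (possibly lossy) medium.

A small transmitting loop with moment ``m`` (A·m²) at the origin of a medium
with complex wavenumber ``k`` and intrinsic impedance ``η`` radiates, under
the ``e^{+jωt}`` convention with outgoing waves ``e^{−jkr}``,

    H(r) = e^{−jkr}/(4π) [ k² (n̂×m)×n̂ / r + (3 n̂ (n̂·m) − m)(1/r³ + jk/r²) ]
    E(r) = −η k²/(4π) (n̂×m) e^{−jkr}/r (1 + 1/(jkr))

with ``n̂ = (r − r_n)/|r − r_n|``.  E is purely azimuthal about the moment
axis; both fields are linear in ``m``, which is what makes the focusing
problem a linear least-squares problem.

These expressions are the homogeneous-medium dyadic Green's function in
closed form; heterogeneous phantoms are handled numerically by
:mod:`mwfocus.forward_solver`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .tissue_properties import Medium

__all__ = [
    "MagneticDipole",
    "FieldGrid",
    "SourceSingularityError",
    "dipole_H",
    "dipole_E",
    "dyadic_green",
    "superpose",
]

#: Default exclusion radius around a source (m); evaluation closer than this
#: raises rather than returning a clipped value.
DEFAULT_EXCLUSION_RADIUS = 1e-12


class SourceSingularityError(ValueError):
    """Field evaluation requested at (or too close to) a source point."""


@dataclasses.dataclass
class MagneticDipole:
    """A point magnetic dipole: position (m) and complex moment (A·m²)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=complex).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("dipole position must be finite")


@dataclasses.dataclass
class FieldGrid:
    """Phasor E and H sampled on a list of points.

    ``points`` is (N, 3) float; ``E`` (V/m) and ``H`` (A/m) are (N, 3)
    complex arrays conforming to it.
    """

    points: np.ndarray
    E: np.ndarray
    H: np.ndarray
    frequency: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.E = np.atleast_2d(np.asarray(self.E, dtype=complex))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=complex))
        if self.E.shape != self.points.shape or self.H.shape != self.points.shape:
            raise ValueError("E and H must conform to points (N, 3)")


def _displacements(source_pos, points, exclusion_radius):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - np.asarray(source_pos, dtype=float).reshape(1, 3)
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= exclusion_radius):
        raise SourceSingularityError(
            f"evaluation within exclusion radius {exclusion_radius:g} m of source"
        )
    return d, r


def dipole_H(
    dipole: MagneticDipole,
    points: np.ndarray,
    medium: Medium,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> np.ndarray:
    """Magnetic field (A/m) of `dipole` at `points` ((N,3) or (3,))."""
    single = np.asarray(points).ndim == 1
    d, r = _displacements(dipole.position, points, exclusion_radius)
    k = medium.k
    n = d / r[:, None]
    m = dipole.moment
    n_dot_m = n @ m
    transverse = m[None, :] - n * n_dot_m[:, None]       # (n̂×m)×n̂
    longitudinal = 3.0 * n * n_dot_m[:, None] - m[None, :]
    phase = np.exp(-1j * k * r)
    H = (phase / (4.0 * np.pi))[:, None] * (
        (k**2 / r)[:, None] * transverse
        + (1.0 / r**3 + 1j * k / r**2)[:, None] * longitudinal
    )
    return H[0] if single else H


def dipole_E(
    dipole: MagneticDipole,
    points: np.ndarray,
    medium: Medium,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> np.ndarray:
    """Electric field (V/m) of `dipole` at `points`; azimuthal about the
    moment axis (∝ n̂ × m), zero on the axis itself."""
    single = np.asarray(points).ndim == 1
    d, r = _displacements(dipole.position, points, exclusion_radius)
    k = medium.k
    n = d / r[:, None]
    n_cross_m = np.cross(n, np.broadcast_to(dipole.moment, n.shape))
    phase = np.exp(-1j * k * r)
    scal = -medium.eta * k**2 / (4.0 * np.pi) * phase / r * (1.0 + 1.0 / (1j * k * r))
    E = scal[:, None] * n_cross_m
    return E[0] if single else E


def dyadic_green(
    source_pos: np.ndarray,
    field_pos: np.ndarray,
    medium: Medium,
    which: str = "H",
) -> np.ndarray:
    """3×3 dyadic mapping a unit moment at `source_pos` to the chosen field
    at `field_pos`; column j is the field of a unit moment along axis j.

    The H-dyadic of a homogeneous reciprocal medium satisfies
    Ĝ(r1, r2) = Ĝ(r2, r1)ᵀ.
    """
    if which not in ("E", "H"):
        raise ValueError("which must be 'E' or 'H'")
    field = dipole_E if which == "E" else dipole_H
    cols = []
    for j in range(3):
        m = np.zeros(3, dtype=complex)
        m[j] = 1.0
        cols.append(field(MagneticDipole(source_pos, m), np.asarray(field_pos, float), medium))
    return np.stack(cols, axis=-1)


def superpose(
    dipoles: list[MagneticDipole],
    points: np.ndarray,
    medium: Medium,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> FieldGrid:
    """Total E and H of a dipole collection: the exact linear superposition
    of the per-dipole closed forms."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    E = np.zeros_like(pts, dtype=complex)
    H = np.zeros_like(pts, dtype=complex)
    for dp in dipoles:
        E += dipole_E(dp, pts, medium, exclusion_radius)
        H += dipole_H(dp, pts, medium, exclusion_radius)
    return FieldGrid(points=pts, E=E, H=H, frequency=medium.frequency)
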