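"""Transmitter placement on spherical and cylindrical shells.

Arrays surround the phantom at `phantom outer radius + standoff` (default
standoff 1 cm).  "Uniform" placement is made deterministic: a Fibonacci
lattice on spheres, equally spaced rings with alternating half-step azimuth
offsets on cylinders.  Each element carries an orthonormal local triad
(r̂, θ̂, φ̂) used for reporting moment components in the surface-adapted
basis (for cylinders the triad is (ρ̂, ẑ, φ̂), mapped onto the same slots).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ArrayLayout",
    "spherical_array",
    "cylindrical_array",
    "spherical_components",
    "DEFAULT_STANDOFF",
]

DEFAULT_STANDOFF = 0.01  # m

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclasses.dataclass
class ArrayLayout:
    """Transmitter positions (N,3) on a named surface, with per-element
    orthonormal (r̂, θ̂, φ̂) triads stacked as (N, 3, 3): basis[i, :, 0] = r̂."""

    positions: np.ndarray
    surface: str
    standoff: float
    local_basis: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.local_basis = np.asarray(self.local_basis, dtype=float)
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("layout needs at least one element")
        if self.local_basis.shape != (n, 3, 3):
            raise ValueError("local_basis must be (N, 3, 3)")

    @property
    def count(self) -> int:
        return self.positions.shape[0]


def _spherical_triad(pos: np.ndarray) -> np.ndarray:
    """(r̂, θ̂, φ̂) at a point; at the poles φ = 0 is used by convention."""
    r = np.linalg.norm(pos)
    rhat = pos / r
    rho = np.hypot(pos[0], pos[1])
    if rho < 1e-12 * r:
        phi = 0.0  # pole convention
    else:
        phi = np.arctan2(pos[1], pos[0])
    theta = np.arccos(np.clip(pos[2] / r, -1.0, 1.0))
    that = np.array(
        [np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi), -np.sin(theta)]
    )
    phat = np.array([-np.sin(phi), np.cos(phi), 0.0])
    return np.stack([rhat, that, phat], axis=1)


def spherical_array(radius: float, count: int, standoff: float = DEFAULT_STANDOFF) -> ArrayLayout:
    """Near-uniform deterministic placement of `count` elements on a sphere
    of `radius` via a Fibonacci lattice.  ``count == 1`` places the single
    element on the +z pole."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if count == 1:
        pos = np.array([[0.0, 0.0, radius]])
    else:
        i = np.arange(count)
        z = 1.0 - 2.0 * (i + 0.5) / count
        rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        phi = _GOLDEN_ANGLE * i
        pos = radius * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    basis = np.stack([_spherical_triad(p) for p in pos])
    return ArrayLayout(pos, surface=f"sphere(radius={radius:g})", standoff=standoff, local_basis=basis)


def _ring_factorization(count: int) -> tuple[int, int]:
    """rings × per-ring split: rings is the largest divisor ≤ sqrt(count).

    Counts whose only such divisor is 1 (primes) are rejected above 4
    elements — a single long ring is not a surface-covering array.
    """
    best = 1
    for d in range(1, int(np.sqrt(count)) + 1):
        if count % d == 0:
            best = d
    if best == 1 and count > 4:
        valid = [n for n in range(max(4, count - 8), count + 9) if _has_factor(n)]
        raise ValueError(
            f"count {count} not factorable into rings x per-ring; nearby valid counts: {valid}"
        )
    return best, count // best


def _has_factor(n: int) -> bool:
    return any(n % d == 0 for d in range(2, int(np.sqrt(n)) + 1)) or n <= 4


def cylindrical_array(
    radius: float, length: float, count: int, standoff: float = DEFAULT_STANDOFF
) -> ArrayLayout:
    """Rings of elements on a cylindrical shell: `rings` equally spaced
    axial stations (cell-centered within ±length/2), equal azimuth steps per
    ring, with odd rings offset by half a step so elements do not align
    axially."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    rings, per_ring = _ring_factorization(count)
    z_stations = (np.arange(rings) + 0.5) / rings * length - length / 2.0
    positions = []
    bases = []
    for ir, z in enumerate(z_stations):
        offset = (0.5 if ir % 2 else 0.0) * 2.0 * np.pi / per_ring
        for ia in range(per_ring):
            phi = 2.0 * np.pi * ia / per_ring + offset
            positions.append([radius * np.cos(phi), radius * np.sin(phi), z])
            rhat = np.array([np.cos(phi), np.sin(phi), 0.0])
            zhat = np.array([0.0, 0.0, 1.0])
            phat = np.array([-np.sin(phi), np.cos(phi), 0.0])
            bases.append(np.stack([rhat, zhat, phat], axis=1))
    return ArrayLayout(
        np.array(positions),
        surface=f"cylinder(radius={radius:g}, length={length:g}, rings={rings}x{per_ring})",
        standoff=standoff,
        local_basis=np.stack(bases),
    )


def spherical_components(layout: ArrayLayout, moments: np.ndarray) -> np.ndarray:
    """Project stacked Cartesian moments (3N,) onto each element's local
    (r̂, θ̂, φ̂) triad; returns (N, 3) complex with columns (m_r, m_θ, m_φ).

    The triads are orthonormal, so per-element Euclidean norm is preserved.
    """
    m = np.asarray(moments, dtype=complex).reshape(-1)
    n = layout.count
    if m.size != 3 * n:
        raise ValueError(f"moments must have length 3*N_t = {3*n}, got {m.size}")
    mcart = m.reshape(n, 3)
    # basis[i] columns are the triad vectors: components = basisᵀ · m
    return np.einsum("nij,ni->nj", layout.local_basis, mcart)


def cartesian_from_spherical_components(layout: ArrayLayout, comps: np.ndarray) -> np.ndarray:
    """Inverse of :func:`spherical_components` (stacked (3N,) output)."""
    comps = np.asarray(comps, dtype=complex).reshape(layout.count, 3)
    mcart = np.einsum("nij,nj->ni", layout.local_basis, comps)
    return mcart.reshape(-1)
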