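"""Deterministic generators for the simplified tissue phantoms.

Three geometries are provided: a homogeneous sphere (idealized brain), a
three-layer sphere (brain / skull / skin-like shell), and a three-layer
cylinder (bone / muscle / outer-tissue limb).  Voxelization classifies each
voxel by its center point (no partial-volume mixing), which keeps the grids
deterministic and makes labeled volumes converge to the analytic volumes as
the spacing shrinks.

Material-name mapping where the dielectric table has no direct entry:
the head "skin" layer uses the Muscle entry (skin conductivity is closer to
muscle than fat) and the limb outer "tissue" layer uses the Fat entry
(it stands in for skin plus interspersed adipose tissue); "bone" uses the
table's Skull entry.  All three are overridable per layer.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .forward_solver import VoxelPhantom
from .tissue_properties import FREE_SPACE, Medium, load_material

__all__ = [
    "PhantomSpec",
    "homogeneous_sphere",
    "layered_sphere_head",
    "layered_cylinder_limb",
    "voxelize",
]


@dataclasses.dataclass
class PhantomSpec:
    """Geometry + material recipe for a phantom.

    `kind` is one of "homogeneous-sphere", "layered-sphere",
    "layered-cylinder".  `dimensions` are the nested radii/thicknesses in
    meters, innermost first; `materials` the per-layer table names,
    innermost first.  For cylinders `length` is the axial extent.
    """

    kind: str
    dimensions: tuple
    materials: tuple
    frequency: float
    length: float | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("all layer dimensions must be positive")
        if len(self.dimensions) != len(self.materials):
            raise ValueError("one material per layer required")

    @property
    def outer_radius(self) -> float:
        return float(sum(self.dimensions))

    def layer_radii(self) -> np.ndarray:
        return np.cumsum(self.dimensions)


def homogeneous_sphere(radius: float, material: str = "Brain", frequency: float = 1e9) -> PhantomSpec:
    """Single-region sphere (default: the 5 cm brain-material sphere)."""
    return PhantomSpec("homogeneous-sphere", (radius,), (material,), frequency)


def layered_sphere_head(
    brain_radius: float = 0.032,
    skull_thickness: float = 0.01,
    skin_thickness: float = 0.008,
    frequency: float = 1e9,
    materials: tuple = ("Brain", "Skull", "Muscle"),
) -> PhantomSpec:
    """Concentric brain/skull/skin sphere; defaults give a 5 cm outer
    radius.  The skin layer maps to the Muscle table entry by default."""
    return PhantomSpec(
        "layered-sphere",
        (brain_radius, skull_thickness, skin_thickness),
        materials,
        frequency,
    )


def layered_cylinder_limb(
    bone_radius: float = 0.01,
    muscle_thickness: float = 0.02,
    tissue_thickness: float = 0.02,
    length: float = 0.20,
    frequency: float = 1e9,
    materials: tuple = ("Skull", "Muscle", "Fat"),
) -> PhantomSpec:
    """Concentric bone/muscle/tissue cylinder; defaults give a 5 cm outer
    radius over a 20 cm length.  Bone uses the Skull table entry; the outer
    tissue layer uses the Fat entry by default."""
    return PhantomSpec(
        "layered-cylinder",
        (bone_radius, muscle_thickness, tissue_thickness),
        materials,
        frequency,
        length=length,
    )


def voxelize(spec: PhantomSpec, spacing: float = 0.0025, padding: int = 1) -> VoxelPhantom:
    """Voxelize a phantom spec onto a cell-centered grid in an air
    background.  `padding` adds that many background voxels per side."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    background = Medium(FREE_SPACE, spec.frequency)
    R = spec.outer_radius
    half_xy = R + padding * spacing
    n_xy = int(np.ceil(2 * half_xy / spacing))
    if spec.kind == "layered-cylinder":
        half_z = spec.length / 2.0 + padding * spacing
        n_z = int(np.ceil(2 * half_z / spacing))
    else:
        n_z = n_xy
    shape = (n_xy, n_xy, n_z)

    origin = np.zeros(3)
    axes = [
        origin[d] + (np.arange(shape[d]) - (shape[d] - 1) / 2.0) * spacing for d in range(3)
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")

    radii = spec.layer_radii()
    mats = [load_material(name, spec.frequency) for name in spec.materials]
    eps_r = np.ones(shape)
    sigma = np.zeros(shape)

    if spec.kind in ("homogeneous-sphere", "layered-sphere"):
        rr = np.sqrt(X**2 + Y**2 + Z**2)
        inside_z = np.ones(shape, bool)
    elif spec.kind == "layered-cylinder":
        rr = np.sqrt(X**2 + Y**2)
        inside_z = np.abs(Z) <= spec.length / 2.0
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")

    # innermost layer last so inner materials overwrite outer shells
    for rad, mat in list(zip(radii, mats))[::-1]:
        mask = (rr <= rad) & inside_z
        eps_r[mask] = mat.eps_r
        sigma[mask] = mat.sigma

    return VoxelPhantom(
        origin=origin,
        spacing=spacing,
        shape=shape,
        eps_r=eps_r,
        sigma=sigma,
        background=background,
    )
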