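"""Dielectric tissue materials and derived microwave propagation quantities.

A time-harmonic ``e^{+jωt}`` (engineering) convention is used throughout the
package.  Under that convention a lossy dielectric has complex permittivity

    ε_c = ε0 ε_r − j σ/ω,

the complex wavenumber is ``k = ω sqrt(μ ε_c)`` on the branch with
``Re k > 0`` and ``Im k < 0``, and outgoing waves ``e^{−jkr}`` decay with
distance whenever σ > 0.

Two penetration-depth quantities are exposed, because they genuinely differ
in tissue at microwave frequencies (the loss tangent σ/ωε is of order one,
neither a good conductor nor a good dielectric):

* :func:`skin_depth_conductor` — the good-conductor skin depth
  ``δ = 1/sqrt(π μ σ f)``;
* :func:`skin_depth_general` — ``1/α`` with the exact lossy-dielectric
  attenuation constant ``α = ω sqrt(με/2) sqrt(sqrt(1+(σ/ωε)^2) − 1)``,
  which is the decay constant actually obeyed by the fields.

The built-in material table covers Brain, Skull, Muscle, Blood and Fat at
100 MHz, 1 GHz and 10 GHz; lookups between the tabulated frequencies are
log–log interpolated and extrapolation is refused.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
from scipy.constants import epsilon_0 as EPS0, mu_0 as MU0

__all__ = [
    "TissueMaterial",
    "Medium",
    "MATERIAL_NAMES",
    "load_material",
    "load_material_table",
    "complex_permittivity",
    "skin_depth_conductor",
    "skin_depth_general",
    "wavelength_in_medium",
]

#: Materials available in the packaged dielectric table.
MATERIAL_NAMES = ("Brain", "Skull", "Muscle", "Blood", "Fat")

_TABLE_FMIN = 1e8
_TABLE_FMAX = 1e10


@dataclasses.dataclass(frozen=True)
class TissueMaterial:
    """A named dielectric at a single frequency.

    Parameters
    ----------
    name
        Label, e.g. ``"Brain"`` or ``"free_space"``.
    eps_r
        Relative permittivity (dimensionless, ≥ 1).
    sigma
        Electrical conductivity in S/m (≥ 0).
    mu_r
        Relative permeability; biological tissue is non-magnetic so this is
        fixed at 1.
    """

    name: str
    eps_r: float
    sigma: float
    mu_r: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_r < 1.0:
            raise ValueError(f"eps_r must be >= 1, got {self.eps_r}")
        if self.sigma < 0.0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.mu_r != 1.0:
            raise ValueError("only non-magnetic media (mu_r = 1) are supported")


FREE_SPACE = TissueMaterial("free_space", 1.0, 0.0)


@dataclasses.dataclass(frozen=True)
class Medium:
    """A material at an operating frequency, with derived phasor constants.

    Attributes
    ----------
    eps_complex
        ε0·eps_r − j σ/ω  (F/m).
    k
        Complex wavenumber ω√(μ ε_c) with Re k > 0, Im k ≤ 0 (1/m).
    eta
        Complex intrinsic impedance √(μ/ε_c) with Re η > 0 (Ω).
    """

    material: TissueMaterial
    frequency: float
    eps_complex: complex = dataclasses.field(init=False)
    k: complex = dataclasses.field(init=False)
    eta: complex = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        eps_c = complex_permittivity(self.material, self.frequency)
        omega = 2.0 * np.pi * self.frequency
        mu = MU0 * self.material.mu_r
        # principal sqrt of eps_c (which lies in the fourth quadrant) puts
        # k in the fourth quadrant too: decaying outgoing e^{-jkr} waves.
        k = omega * np.sqrt(mu) * np.sqrt(eps_c)
        eta = np.sqrt(mu) / np.sqrt(eps_c)
        object.__setattr__(self, "eps_complex", complex(eps_c))
        object.__setattr__(self, "k", complex(k))
        object.__setattr__(self, "eta", complex(eta))

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def mu(self) -> float:
        return MU0 * self.material.mu_r


def load_material_table(path=None) -> pd.DataFrame:
    """Load the dielectric table (packaged CSV, or a user CSV of the same
    schema: columns material, frequency_hz, eps_r, sigma_s_per_m)."""
    if path is None:
        ref = resources.files("mwfocus.data") / "tissue_properties.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    expected = {"material", "frequency_hz", "eps_r", "sigma_s_per_m"}
    if not expected.issubset(df.columns):
        raise ValueError(f"material table must have columns {sorted(expected)}")
    return df


def load_material(name: str, frequency: float, table: pd.DataFrame | None = None) -> TissueMaterial:
    """Look up a tissue material at `frequency`, log–log interpolating
    (eps_r, sigma) between the tabulated frequencies.

    Raises
    ------
    KeyError
        If `name` is not in the table.
    ValueError
        If `frequency` falls outside the tabulated range (extrapolation is
        refused).
    """
    df = load_material_table() if table is None else table
    rows = df[df["material"] == name].sort_values("frequency_hz")
    if rows.empty:
        known = sorted(df["material"].unique())
        raise KeyError(f"unknown material {name!r}; known materials: {known}")
    f_tab = rows["frequency_hz"].to_numpy(float)
    if not (f_tab[0] <= frequency <= f_tab[-1]):
        raise ValueError(
            f"frequency {frequency:g} Hz outside tabulated range "
            f"[{f_tab[0]:g}, {f_tab[-1]:g}] Hz for {name}; extrapolation refused"
        )
    logf = np.log(frequency)
    eps_r = float(np.exp(np.interp(logf, np.log(f_tab), np.log(rows["eps_r"].to_numpy(float)))))
    sigma = float(np.exp(np.interp(logf, np.log(f_tab), np.log(rows["sigma_s_per_m"].to_numpy(float)))))
    return TissueMaterial(name, eps_r, sigma)


def complex_permittivity(material: TissueMaterial, frequency: float) -> complex:
    """ε_c = ε0 ε_r − j σ/ω (F/m) under the e^{+jωt} convention."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * frequency
    return EPS0 * material.eps_r - 1j * material.sigma / omega


def skin_depth_conductor(material: TissueMaterial, frequency: float) -> float:
    """Good-conductor skin depth δ = 1/sqrt(π μ σ f) (m).

    Undefined (raises) for lossless media.  Accurate only when the loss
    tangent σ/ωε is large; see :func:`skin_depth_general` for the exact
    field-decay length.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if material.sigma <= 0:
        raise ValueError("good-conductor skin depth undefined for sigma = 0")
    mu = MU0 * material.mu_r
    return 1.0 / np.sqrt(np.pi * mu * material.sigma * frequency)


def skin_depth_general(material: TissueMaterial, frequency: float) -> float:
    """Exact 1/e field-decay depth 1/α in a lossy dielectric (m).

    α = ω sqrt(μ ε / 2) · sqrt( sqrt(1 + (σ/ωε)^2) − 1 ), with ε = ε0·eps_r.
    Returns ``inf`` for σ = 0 (no attenuation).  Converges to the
    good-conductor form when σ/ωε ≫ 1.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if material.sigma == 0:
        return float("inf")
    omega = 2.0 * np.pi * frequency
    eps = EPS0 * material.eps_r
    mu = MU0 * material.mu_r
    tan_loss = material.sigma / (omega * eps)
    alpha = omega * np.sqrt(mu * eps / 2.0) * np.sqrt(np.sqrt(1.0 + tan_loss**2) - 1.0)
    return float(1.0 / alpha)


def wavelength_in_medium(material: TissueMaterial, frequency: float) -> float:
    """In-medium wavelength λ = 1/(f sqrt(μ ε)) with real ε = ε0·eps_r (m)."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    eps = EPS0 * material.eps_r
    mu = MU0 * material.mu_r
    return float(1.0 / (frequency * np.sqrt(mu * eps)))
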