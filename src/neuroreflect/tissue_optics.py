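"""Chromophore spectra and tissue optical-property construction.

Provides the molar extinction table for oxygenated (HbO) and deoxygenated
(HbR) hemoglobin, Beer-Lambert assembly of the absorption coefficient, the
power-law reduced scattering model, and the layered tissue / fiber-probe
descriptions shared by the forward Monte Carlo simulator and the spectral
inversion.

Units follow one convention throughout the package: lengths in mm,
concentrations in mM, wavelengths in nm, extinction coefficients in
1/(mM cm), absorption and reduced scattering coefficients in 1/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreTable",
    "ScatteringLaw",
    "Layer",
    "TissueModel",
    "FiberGeometry",
    "load_default_chromophores",
    "extinction",
    "absorption_coefficient",
    "reduced_scattering",
]

#: natural-log conversion for decadic extinction coefficients
LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class ChromophoreTable:
    """Tabulated molar extinction of HbO and HbR on a common wavelength grid.

    Attributes
    ----------
    wavelength_grid : ndarray, nm, strictly increasing
    eps_HbO, eps_HbR : ndarray, 1/(mM cm), all positive
    """

    wavelength_grid: np.ndarray
    eps_HbO: np.ndarray
    eps_HbR: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength_grid, dtype=float)
        eo = np.asarray(self.eps_HbO, dtype=float)
        er = np.asarray(self.eps_HbR, dtype=float)
        if not (wl.shape == eo.shape == er.shape):
            raise ValueError("wavelength grid and extinction columns must have equal length")
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 nodes")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(eo <= 0) or np.any(er <= 0):
            raise ValueError("extinction coefficients must be positive")
        object.__setattr__(self, "wavelength_grid", wl)
        object.__setattr__(self, "eps_HbO", eo)
        object.__setattr__(self, "eps_HbR", er)

    @property
    def wl_min(self) -> float:
        return float(self.wavelength_grid[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelength_grid[-1])


def load_default_chromophores() -> ChromophoreTable:
    """Load the packaged HbO/HbR extinction compilation (450-1000 nm, 1 nm).

    The table is a landmark-calibrated compilation of standard whole-blood
    molar extinction values, interpolated monotonically to a uniform grid;
    it reproduces the visible-band structure used by ratiometric oximetry
    (twin HbO peaks at 542/578 nm, HbR peak at 555 nm, isosbestic points
    near 500, 529, 569 and 797 nm).
    """
    ref = resources.files("neuroreflect.data").joinpath("hemoglobin_extinction.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    return ChromophoreTable(
        wavelength_grid=df["wavelength_nm"].to_numpy(),
        eps_HbO=df["eps_HbO"].to_numpy(),
        eps_HbR=df["eps_HbR"].to_numpy(),
    )


def extinction(table: ChromophoreTable, wavelength, species: str):
    """Molar extinction at ``wavelength`` by linear interpolation, 1/(mM cm).

    Parameters
    ----------
    species : {"HbO", "HbR"}

    Raises
    ------
    ValueError
        If ``wavelength`` lies outside the table's grid range, or the
        species name is unknown.
    """
    if species == "HbO":
        eps = table.eps_HbO
    elif species == "HbR":
        eps = table.eps_HbR
    else:
        raise ValueError(f"unknown species {species!r}; expected 'HbO' or 'HbR'")
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl < table.wl_min) or np.any(wl > table.wl_max):
        raise ValueError(
            f"wavelength outside tabulated range [{table.wl_min:g}, {table.wl_max:g}] nm"
        )
    out = np.interp(wl, table.wavelength_grid, eps)
    return float(out) if np.isscalar(wavelength) else out


def absorption_coefficient(C_HbO, C_HbR, wavelength, table: ChromophoreTable):
    """Beer-Lambert absorption coefficient mu_a in 1/mm.

    mu_a = ln(10) * (eps_HbO * C_HbO + eps_HbR * C_HbR), with the extinction
    table in 1/(mM cm) converted to 1/mm (factor 1/10).
    """
    if np.any(np.asarray(C_HbO) < 0) or np.any(np.asarray(C_HbR) < 0):
        raise ValueError("hemoglobin concentrations must be non-negative")
    eo = extinction(table, wavelength, "HbO")
    er = extinction(table, wavelength, "HbR")
    return LN10 * (eo * C_HbO + er * C_HbR) / 10.0


@dataclass(frozen=True)
class ScatteringLaw:
    """Power-law reduced scattering: mu_s'(lam) = a * (lam/lam_ref)**(-b).

    ``amplitude_a`` (1/mm) is the single free scattering parameter of the
    inversion; the Mie-like slope ``exponent_b`` and the reference
    wavelength are fixed configuration.
    """

    amplitude_a: float = 2.0
    exponent_b: float = 1.3
    reference_wavelength: float = 500.0

    def __post_init__(self):
        if self.amplitude_a < 0:
            raise ValueError("scattering amplitude must be >= 0")
        if self.reference_wavelength <= 0:
            raise ValueError("reference wavelength must be positive")


def reduced_scattering(law: ScatteringLaw, wavelength):
    """Reduced scattering coefficient mu_s' at ``wavelength``, 1/mm."""
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    out = law.amplitude_a * (wl / law.reference_wavelength) ** (-law.exponent_b)
    return float(out) if np.isscalar(wavelength) else out


@dataclass(frozen=True)
class Layer:
    """One tissue layer. ``thickness=None`` marks a semi-infinite layer."""

    thickness: float | None  # mm; None => semi-infinite
    C_HbO: float = 0.0  # mM
    C_HbR: float = 0.0  # mM
    scattering: ScatteringLaw = field(default_factory=ScatteringLaw)
    anisotropy_g: float = 0.9
    refractive_index: float = 1.37

    def __post_init__(self):
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError("layer thickness must be positive or None (semi-infinite)")
        if not (0.0 <= self.anisotropy_g < 1.0):
            raise ValueError("anisotropy g must satisfy 0 <= g < 1")
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.C_HbO < 0 or self.C_HbR < 0:
            raise ValueError("hemoglobin concentrations must be non-negative")

    def mu_a(self, wavelength, table: ChromophoreTable):
        return absorption_coefficient(self.C_HbO, self.C_HbR, wavelength, table)

    def mu_s_prime(self, wavelength):
        return reduced_scattering(self.scattering, wavelength)


@dataclass(frozen=True)
class TissueModel:
    """Ordered stack of layers, top (illuminated) first.

    Only the last layer may be semi-infinite; intermediate layers need a
    finite thickness.
    """

    layers: tuple[Layer, ...]

    def __post_init__(self):
        layers = tuple(self.layers)
        if not layers:
            raise ValueError("tissue model needs at least one layer")
        for lay in layers[:-1]:
            if lay.thickness is None:
                raise ValueError("only the deepest layer may be semi-infinite")
        object.__setattr__(self, "layers", layers)

    @staticmethod
    def single_layer_cortex(C_HbO=0.06, C_HbR=0.04, amplitude_a=2.0, **kw) -> "TissueModel":
        """Semi-infinite single-layer cortex (skull-window measurement geometry)."""
        law = ScatteringLaw(amplitude_a=amplitude_a)
        return TissueModel(layers=(Layer(thickness=None, C_HbO=C_HbO, C_HbR=C_HbR,
                                         scattering=law, **kw),))

    @staticmethod
    def skull_cortex(
        skull_thickness=1.0,
        skull_mu_a_surrogate=(0.0005, 0.0005),
        skull_a=2.4,
        skull_b=0.65,
        cortex_C_HbO=0.06,
        cortex_C_HbR=0.04,
        cortex_a=2.0,
    ) -> "TissueModel":
        """Two-layer skull + semi-infinite cortex (transcranial geometry).

        Skull absorption is weak and nearly hemoglobin-free; it is encoded
        through tiny surrogate concentrations so that all layers share the
        Beer-Lambert machinery. Defaults are conventional rodent-skull
        values and are config-overridable.
        """
        skull = Layer(
            thickness=skull_thickness,
            C_HbO=skull_mu_a_surrogate[0],
            C_HbR=skull_mu_a_surrogate[1],
            scattering=ScatteringLaw(amplitude_a=skull_a, exponent_b=skull_b),
            anisotropy_g=0.9,
            refractive_index=1.55,
        )
        cortex = Layer(
            thickness=None,
            C_HbO=cortex_C_HbO,
            C_HbR=cortex_C_HbR,
            scattering=ScatteringLaw(amplitude_a=cortex_a),
        )
        return TissueModel(layers=(skull, cortex))


@dataclass(frozen=True)
class FiberGeometry:
    """Source-detector fiber pair resting on the tissue surface.

    Defaults follow the in-vivo probe: 800 um core, 2 mm center-to-center
    separation; NA 0.39 is typical of such multimode fibers.
    """

    core_diameter_um: float = 800.0
    center_separation_mm: float = 2.0
    numerical_aperture: float = 0.39
    coupling_index: float = 1.0  # medium above the tissue (air)

    def __post_init__(self):
        if min(self.core_diameter_um, self.center_separation_mm,
               self.numerical_aperture) <= 0:
            raise ValueError("fiber geometry parameters must be positive")
        if self.numerical_aperture >= self.coupling_index:
            raise ValueError("NA must be smaller than the coupling medium index")

    @property
    def core_radius_mm(self) -> float:
        return self.core_diameter_um / 2000.0
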