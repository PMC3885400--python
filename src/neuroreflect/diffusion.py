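"""Diffusion-approximation reflectance for a semi-infinite medium.

Dipole (extrapolated-boundary) solution for spatially resolved
steady-state diffuse reflectance, plus its closed-form radial integral
for total diffuse reflectance. Serves two roles: an independent oracle
for the Monte Carlo transport in the diffusive regime, and a fast
analytic forward model behind the same interface as the MC path for
quick inversion tests.
"""

from __future__ import annotations

import numpy as np

from .tissue_optics import ChromophoreTable, FiberGeometry, TissueModel, load_default_chromophores

__all__ = [
    "internal_reflection_parameter",
    "radial_reflectance",
    "total_diffuse_reflectance",
    "fiber_reflectance_diffusion",
]


def internal_reflection_parameter(n_rel: float) -> float:
    """Boundary parameter A(n) from the empirical internal-reflectance fit."""
    if n_rel == 1.0:
        return 1.0
    r_id = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_id) / (1.0 - r_id)


def _dipole_terms(mu_a, mu_s_p, n_rel):
    mu_t = mu_a + mu_s_p
    albedo = mu_s_p / mu_t
    D = 1.0 / (3.0 * mu_t)
    mu_eff = np.sqrt(mu_a / D)
    z0 = 1.0 / mu_t
    zb = 2.0 * internal_reflection_parameter(n_rel) * D
    return albedo, mu_eff, z0, z0 + 2.0 * zb


def radial_reflectance(mu_a: float, mu_s_p: float, rho, n_rel: float = 1.0):
    """Diffuse reflectance per unit area R(rho) in 1/mm^2 (dipole model)."""
    if mu_s_p <= 0:
        raise ValueError("mu_s_p must be positive")
    albedo, mu_eff, z0, zp = _dipole_terms(mu_a, mu_s_p, n_rel)
    rho = np.asarray(rho, dtype=float)
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt(zp**2 + rho**2)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
    term2 = zp * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    out = albedo / (4.0 * np.pi) * (term1 + term2)
    return float(out) if out.ndim == 0 else out


def total_diffuse_reflectance(mu_a: float, mu_s_p: float, n_rel: float = 1.0) -> float:
    """Total diffuse reflectance of the semi-infinite medium.

    Closed-form radial integral of the dipole solution:
    R = (a'/2) * (exp(-mu_eff z0) + exp(-mu_eff z_p)). Valid in the
    diffusive regime mu_s' >> mu_a; tends to 1 as mu_a -> 0.
    """
    albedo, mu_eff, z0, zp = _dipole_terms(mu_a, mu_s_p, n_rel)
    return float(albedo / 2.0 * (np.exp(-mu_eff * z0) + np.exp(-mu_eff * zp)))


def fiber_reflectance_diffusion(
    tissue: TissueModel,
    fibers: FiberGeometry,
    wavelength: float,
    table: ChromophoreTable | None = None,
) -> float:
    """Detected reflectance of the fiber pair under the dipole model.

    R(rho = fiber separation) times the detector face area; restricted to
    the single-layer semi-infinite inversion geometry. The absolute scale
    differs from the MC estimate by a geometry factor that is flat in
    wavelength and is therefore absorbed by the regression intercept.
    """
    if len(tissue.layers) != 1 or tissue.layers[0].thickness is not None:
        raise ValueError("diffusion forward model requires a single semi-infinite layer")
    if table is None:
        table = load_default_chromophores()
    lay = tissue.layers[0]
    mu_a = float(lay.mu_a(wavelength, table))
    mu_s_p = float(lay.mu_s_prime(wavelength))
    n_rel = lay.refractive_index / fibers.coupling_index
    area = np.pi * fibers.core_radius_mm**2
    return float(radial_reflectance(mu_a, mu_s_p, fibers.center_separation_mm, n_rel) * area)
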