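"""Forward Monte Carlo photon transport in layered tissue.

Weighted-photon random walk in a plane-parallel layer stack, with
Henyey-Greenstein scattering, Fresnel reflection/refraction at
refractive-index mismatches and Russian-roulette termination, scoring
diffuse reflectance collected by a detector fiber at a fixed
source-detector separation.

Detection exploits the azimuthal symmetry of the centered source fiber:
a photon escaping the top surface at radial distance rho contributes the
fraction of the circle of radius rho that overlaps the detector fiber
face (exact under symmetry, and far lower variance than a binary
footprint test). The fiber numerical aperture is applied both at launch
and at detection.

A second entry point, :func:`simulate_path_ensemble`, runs the same walk
in a non-absorbing medium and records per-detected-photon total path
lengths; absorption is then applied analytically as exp(-mu_a * L)
(the standard path-length estimator), which lets one scattering
realization serve an entire grid of absorber concentrations when
building the inversion's conversion model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .tissue_optics import ChromophoreTable, FiberGeometry, TissueModel, load_default_chromophores

__all__ = [
    "McResult",
    "PathEnsemble",
    "simulate_reflectance",
    "simulate_path_ensemble",
    "reflectance_from_paths",
    "sampling_depth",
    "InsufficientStatisticsError",
]

WEIGHT_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1
_MAX_STEPS = 1_000_000


class InsufficientStatisticsError(RuntimeError):
    """Raised when too few detected photons support the requested statistic."""


@njit(cache=True)
def _ring_overlap(rho, d, rd):
    # fraction of the circle of radius rho (centered on the source) that
    # falls on the detector face of radius rd centered a distance d away
    if rho < 1e-12:
        return 1.0 if d < rd else 0.0
    if rho + d <= rd:
        return 1.0
    if abs(rho - d) >= rd:
        return 0.0
    c = (rho * rho + d * d - rd * rd) / (2.0 * rho * d)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return np.arccos(c) / np.pi


@njit(cache=True)
def _fresnel(n1, n2, ci):
    # unpolarized Fresnel reflectance for incidence cosine ci (>=0)
    if n1 == n2:
        return 0.0, ci
    si = np.sqrt(max(0.0, 1.0 - ci * ci))
    st = n1 * si / n2
    if st >= 1.0:
        return 1.0, 0.0
    ct = np.sqrt(1.0 - st * st)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True)
def _mc_kernel(n_photons, seed, z_bot, mua, mus, g, n_lay, n_out,
               src_radius, det_sep, det_radius, sin_accept,
               kill_depth, kill_path, mu_a_floor):
    """Trace n_photons; return totals and per-detected-photon records.

    ``mu_a_floor > 0`` activates termination sampling of a baseline
    absorber: each photon draws an exponential absorption horizon
    ~ Exp(mu_a_floor) and is killed when its path exceeds it. Survivors
    then carry an implicit exp(-mu_a_floor * L) survival factor that the
    caller divides out when reweighting to a target absorber.
    """
    np.random.seed(seed)
    n_layers = z_bot.shape[0]
    r_total = 0.0
    a_total = 0.0
    t_total = 0.0
    det_w = np.zeros(n_photons)
    det_depth = np.zeros(n_photons)
    det_path = np.zeros(n_photons)
    n_det = 0

    cos_na_out = np.sqrt(max(0.0, 1.0 - sin_accept * sin_accept))

    for _ in range(n_photons):
        # launch: uniform over the source core, direction uniform in the
        # NA cone of the coupling medium
        r = src_radius * np.sqrt(np.random.random())
        ang = 2.0 * np.pi * np.random.random()
        x = r * np.cos(ang)
        y = r * np.sin(ang)
        z = 0.0
        czi = cos_na_out + (1.0 - cos_na_out) * np.random.random()
        szi = np.sqrt(max(0.0, 1.0 - czi * czi))
        phi = 2.0 * np.pi * np.random.random()
        # Fresnel at entry
        refl, ct = _fresnel(n_out, n_lay[0], czi)
        if np.random.random() < refl:
            r_total += 1.0  # specular, returns through the top surface
            continue
        scale = n_out / n_lay[0]
        ux = szi * np.cos(phi) * scale
        uy = szi * np.sin(phi) * scale
        uz = ct
        nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
        ux /= nrm
        uy /= nrm
        uz /= nrm

        w = 1.0
        lay = 0
        zmax = 0.0
        path = 0.0
        alive = True
        steps = 0
        sleft = 0.0  # dimensionless remaining optical step
        horizon = kill_path
        if mu_a_floor > 0.0:
            h = -np.log(np.random.random() + 1e-300) / mu_a_floor
            if h < horizon:
                horizon = h

        while alive and steps < _MAX_STEPS:
            steps += 1
            mut = mua[lay] + mus[lay]
            if sleft <= 0.0:
                sleft = -np.log(np.random.random() + 1e-300)
            s = sleft / mut

            # distance to the layer boundary along the current direction
            if uz > 1e-12:
                db = (z_bot[lay] - z) / uz
            elif uz < -1e-12:
                ztop = 0.0 if lay == 0 else z_bot[lay - 1]
                db = (ztop - z) / uz
            else:
                db = 1e30

            if db < s:
                # move to the boundary and attempt to cross
                x += ux * db
                y += uy * db
                z += uz * db
                path += db
                if z > zmax:
                    zmax = z
                sleft -= db * mut
                if sleft < 0.0:
                    sleft = 0.0
                n1 = n_lay[lay]
                going_up = uz < 0.0
                if going_up:
                    n2 = n_out if lay == 0 else n_lay[lay - 1]
                else:
                    n2 = n_out if lay == n_layers - 1 else n_lay[lay + 1]
                refl, ct = _fresnel(n1, n2, abs(uz))
                if np.random.random() < refl:
                    uz = -uz  # internal reflection
                else:
                    scale = n1 / n2
                    ux *= scale
                    uy *= scale
                    uz = ct if uz > 0.0 else -ct
                    nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= nrm
                    uy /= nrm
                    uz /= nrm
                    if going_up and lay == 0:
                        # escaped the top surface
                        r_total += w
                        sin_out = np.sqrt(max(0.0, 1.0 - uz * uz))
                        if sin_out <= sin_accept:
                            rho = np.sqrt(x * x + y * y)
                            frac = _ring_overlap(rho, det_sep, det_radius)
                            if frac > 0.0:
                                det_w[n_det] = w * frac
                                det_depth[n_det] = zmax
                                det_path[n_det] = path
                                n_det += 1
                        alive = False
                    elif (not going_up) and lay == n_layers - 1:
                        t_total += w  # escaped the bottom
                        alive = False
                    else:
                        lay = lay - 1 if going_up else lay + 1
                continue

            # interaction inside the layer
            x += ux * s
            y += uy * s
            z += uz * s
            path += s
            if z > zmax:
                zmax = z
            sleft = 0.0

            dw = w * mua[lay] / mut
            a_total += dw
            w -= dw

            # Henyey-Greenstein deflection
            gg = g[lay]
            if gg > 1e-6:
                tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
            else:
                cost = 2.0 * np.random.random() - 1.0
            if cost > 1.0:
                cost = 1.0
            elif cost < -1.0:
                cost = -1.0
            sint = np.sqrt(1.0 - cost * cost)
            phi = 2.0 * np.pi * np.random.random()
            cosp = np.cos(phi)
            sinp = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                den = np.sqrt(1.0 - uz * uz)
                uxn = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                uyn = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                uzn = -sint * cosp * den + uz * cost
                ux, uy, uz = uxn, uyn, uzn

            if z > kill_depth or path > horizon:
                # photons beyond the cutoffs cannot reach the detector with
                # non-negligible weight for the absorber range served
                a_total += w
                alive = False
            elif w < WEIGHT_THRESHOLD:
                if np.random.random() < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    alive = False

    return r_total, a_total, t_total, det_w[:n_det], det_depth[:n_det], det_path[:n_det]


@dataclass(frozen=True)
class McResult:
    """Outcome of one forward simulation at a single wavelength.

    ``max_depth_samples`` holds the maximum visited depth (mm, from the
    top surface) of each detected photon; ``detected_weights`` the
    corresponding ring-overlap-weighted photon weights.
    """

    reflectance_detected: float
    reflectance_total: float
    absorbed_fraction: float
    transmitted_fraction: float
    max_depth_samples: np.ndarray
    detected_weights: np.ndarray
    detected_pathlengths: np.ndarray
    n_photons: int
    seed: int
    cortical_surface_mm: float = 0.0

    @property
    def n_detected(self) -> int:
        return int(self.max_depth_samples.size)


def _layer_arrays(tissue: TissueModel, wavelength: float, table: ChromophoreTable):
    z_bot, mua, mus, g, n = [], [], [], [], []
    depth = 0.0
    for lay in tissue.layers:
        depth = 1e9 if lay.thickness is None else depth + lay.thickness
        z_bot.append(depth)
        ma = float(lay.mu_a(wavelength, table))
        msp = float(lay.mu_s_prime(wavelength))
        if ma < 0 or msp < 0:
            raise ValueError("optical coefficients must be non-negative")
        mua.append(ma)
        mus.append(msp / (1.0 - lay.anisotropy_g))
        g.append(lay.anisotropy_g)
        n.append(lay.refractive_index)
    return (np.array(z_bot), np.array(mua), np.array(mus), np.array(g), np.array(n))


def simulate_reflectance(
    tissue: TissueModel,
    fibers: FiberGeometry,
    wavelength: float,
    n_photons: int = 100_000,
    seed: int = 0,
    table: ChromophoreTable | None = None,
) -> McResult:
    """Run the forward Monte Carlo at one wavelength.

    Returns an :class:`McResult`; fixed ``seed`` gives bit-identical output.
    """
    if n_photons < 1000:
        raise ValueError("n_photons must be >= 1000")
    if table is None:
        table = load_default_chromophores()
    z_bot, mua, mus, g, n = _layer_arrays(tissue, wavelength, table)
    r, a, t, dw, dd, dp = _mc_kernel(
        int(n_photons), int(seed) & 0x7FFFFFFF, z_bot, mua, mus, g, n,
        fibers.coupling_index, fibers.core_radius_mm,
        fibers.center_separation_mm, fibers.core_radius_mm,
        fibers.numerical_aperture / fibers.coupling_index,
        1e30, 1e30, 0.0,
    )
    cortical = 0.0
    if len(tissue.layers) > 1:
        cortical = sum(l.thickness for l in tissue.layers[:-1])
    return McResult(
        reflectance_detected=float(dw.sum() / n_photons),
        reflectance_total=float(r / n_photons),
        absorbed_fraction=float(a / n_photons),
        transmitted_fraction=float(t / n_photons),
        max_depth_samples=dd,
        detected_weights=dw,
        detected_pathlengths=dp,
        n_photons=int(n_photons),
        seed=int(seed),
        cortical_surface_mm=float(cortical),
    )


@dataclass(frozen=True)
class PathEnsemble:
    """Detected-photon path records from a non-absorbing simulation.

    For a semi-infinite single layer the walk depends only on (mu_s, g, n)
    and the probe geometry; the detected reflectance in the presence of a
    uniform absorber mu_a is the path-length estimator
    ``mean(w * exp(-mu_a * L))``.
    """

    weights: np.ndarray
    pathlengths_mm: np.ndarray
    n_photons: int
    seed: int
    mu_s_mm: float
    mu_a_floor: float = 0.0

    @property
    def n_detected(self) -> int:
        return int(self.weights.size)


def simulate_path_ensemble(
    tissue: TissueModel,
    fibers: FiberGeometry,
    wavelength: float,
    n_photons: int = 100_000,
    seed: int = 0,
    kill_depth_mm: float = 30.0,
    kill_path_mm: float = 2000.0,
    mu_a_floor: float = 0.0,
) -> PathEnsemble:
    """Scattering-only forward run recording detected-photon path lengths.

    Requires a single-layer semi-infinite tissue (the inversion geometry).
    Without an absorber the escape-path distribution is heavy-tailed, so
    absorption at a floor value ``mu_a_floor`` (choose it at or below the
    smallest absorber the ensemble will be reweighted to) is applied by
    termination sampling: each photon draws an exponential absorption
    horizon ~ Exp(mu_a_floor) and dies when its path exceeds it. This is
    an unbiased absorber model; :func:`reflectance_from_paths` divides the
    implicit exp(-mu_a_floor L) survival factor back out. The deterministic
    ``kill_depth_mm`` / ``kill_path_mm`` cutoffs are safety nets whose
    truncation bias is below 1e-8 for that absorber range.
    """
    if len(tissue.layers) != 1 or tissue.layers[0].thickness is not None:
        raise ValueError("path ensembles require a single semi-infinite layer")
    lay = tissue.layers[0]
    msp = float(lay.mu_s_prime(wavelength))
    mus = msp / (1.0 - lay.anisotropy_g)
    z_bot = np.array([1e9])
    r, a, t, dw, dd, dp = _mc_kernel(
        int(n_photons), int(seed) & 0x7FFFFFFF, z_bot,
        np.array([0.0]), np.array([mus]),
        np.array([lay.anisotropy_g]), np.array([lay.refractive_index]),
        fibers.coupling_index, fibers.core_radius_mm,
        fibers.center_separation_mm, fibers.core_radius_mm,
        fibers.numerical_aperture / fibers.coupling_index,
        float(kill_depth_mm), float(kill_path_mm), float(mu_a_floor),
    )
    return PathEnsemble(weights=dw, pathlengths_mm=dp, n_photons=int(n_photons),
                        seed=int(seed), mu_s_mm=float(mus),
                        mu_a_floor=float(mu_a_floor))


def reflectance_from_paths(ensemble: PathEnsemble, mu_a: float) -> float:
    """Detected reflectance for absorption ``mu_a`` (1/mm) from an ensemble.

    Path-length estimator mean(w * exp(-(mu_a - mu_a_floor) * L)); the
    floor term cancels the survival factor already realized by the
    ensemble's termination sampling. Unbiased for any mu_a >= 0, with
    variance growing for mu_a far below the floor.
    """
    if mu_a < 0:
        raise ValueError("mu_a must be non-negative")
    return float(np.sum(ensemble.weights
                        * np.exp(-(mu_a - ensemble.mu_a_floor) * ensemble.pathlengths_mm))
                 / ensemble.n_photons)


def _weighted_percentile(values, weights, q):
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(np.asarray(q) / 100.0, cw, v)


def sampling_depth(result: McResult, lower_pct: float = 25.0, upper_pct: float = 75.0):
    """Percentile band of detected-photon maximum depths, mm.

    Depths are reported relative to the cortical surface (i.e. the top of
    the deepest layer) when overburden layers such as skull are present.

    Raises
    ------
    InsufficientStatisticsError
        If fewer than 100 photons were detected.
    """
    if result.n_detected < 100:
        raise InsufficientStatisticsError(
            f"only {result.n_detected} detected photons; >= 100 required"
        )
    depths = result.max_depth_samples - result.cortical_surface_mm
    lo, hi = _weighted_percentile(depths, result.detected_weights,
                                  [lower_pct, upper_pct])
    return float(lo), float(hi)
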