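"""Hemoglobin oxygen-saturation quantification from diffuse reflectance.

The estimation chain mirrors inverse Monte Carlo oximetry:

1. a measured reflectance spectrum R(lambda) is converted to absorbance
   A(lambda) = -log10 R(lambda);
2. A(lambda) is regressed on the HbO and HbR extinction spectra plus an
   intercept, giving coefficients (alpha_HbO, alpha_HbR, alpha_0); the
   intercept captures the scattering contribution to attenuation;
3. a pre-computed *conversion model* — a quadratic polynomial map fitted
   on a grid of Monte Carlo forward simulations — converts the alpha
   triple into (C_HbO, C_HbR, a), the hemoglobin concentrations and the
   scattering amplitude;
4. StO2 = C_HbO / (C_HbO + C_HbR).

The conversion model is exposed as the sklearn-style estimator
:class:`HemoglobinInverter` (fit builds the forward grid and the map;
predict inverts spectra); the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import photon_mc
from .diffusion import fiber_reflectance_diffusion
from .tissue_optics import (
    ChromophoreTable,
    FiberGeometry,
    Layer,
    ScatteringLaw,
    TissueModel,
    load_default_chromophores,
)

__all__ = [
    "Spectrum",
    "RegressionCoefficients",
    "ConversionModel",
    "HemoglobinEstimate",
    "HemoglobinInverter",
    "absorbance",
    "regress_chromophores",
    "build_conversion_model",
    "invert_spectrum",
    "oxygen_saturation",
    "forward_reflectance_spectrum",
    "read_spectra_csv",
    "estimates_to_frame",
    "ConditioningError",
    "ModelQualityError",
]

DEFAULT_WAVELENGTHS = np.arange(500.0, 621.0, 5.0)
DEFAULT_WINDOW = (500.0, 620.0)


class ConditioningError(np.linalg.LinAlgError):
    """Regression design is rank-deficient or numerically singular."""


class ModelQualityError(RuntimeError):
    """Conversion-model fit failed its quality threshold."""


@dataclass(frozen=True)
class Spectrum:
    """Reflectance vs wavelength at one time point."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.shape != r.shape or wl.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D arrays of equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError("reflectance must lie in (0, 1] for a finite absorbance")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class RegressionCoefficients:
    alpha_HbO: float
    alpha_HbR: float
    alpha_0: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_HbO, self.alpha_HbR, self.alpha_0])


@dataclass(frozen=True)
class HemoglobinEstimate:
    """Inverted hemoglobin parameters for one spectrum."""

    C_HbO: float  # mM
    C_HbR: float  # mM
    a: float  # 1/mm
    StO2: float  # fraction in [0, 1]
    clipped: bool = False  # a negative mapped concentration was clipped to 0
    extrapolated: bool = False  # alpha triple outside the training hull

    @property
    def C_HbT(self) -> float:
        return self.C_HbO + self.C_HbR


def absorbance(spectrum: Spectrum) -> np.ndarray:
    """Absorbance A(lambda) = -log10 R(lambda)."""
    return -np.log10(spectrum.reflectance)


def _window_mask(wavelengths, window):
    lo, hi = window
    return (wavelengths >= lo) & (wavelengths <= hi)


def regress_chromophores(
    wavelengths: np.ndarray,
    absorbance_values: np.ndarray,
    table: ChromophoreTable,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> RegressionCoefficients:
    """OLS of A(lambda) on [eps_HbO(lambda), eps_HbR(lambda), 1] over ``window``.

    The intercept alpha_0 absorbs the scattering contribution to the
    attenuation (and any wavelength-flat instrument scale).
    """
    wl = np.asarray(wavelengths, dtype=float)
    A = np.asarray(absorbance_values, dtype=float)
    mask = _window_mask(wl, window)
    if mask.sum() < 10:
        raise ValueError("regression window must contain >= 10 wavelength samples")
    wl = wl[mask]
    A = A[mask]
    from .tissue_optics import extinction

    X = np.column_stack([
        extinction(table, wl, "HbO"),
        extinction(table, wl, "HbR"),
        np.ones_like(wl),
    ])
    if np.linalg.matrix_rank(X) < 3 or np.linalg.cond(X) > 1e10:
        raise ConditioningError("regression design is rank-deficient over this window")
    coef, *_ = np.linalg.lstsq(X, A, rcond=None)
    return RegressionCoefficients(*map(float, coef))


def oxygen_saturation(C_HbO: float, C_HbR: float) -> float:
    """StO2 = C_HbO / (C_HbO + C_HbR)."""
    if C_HbO < 0 or C_HbR < 0:
        raise ValueError("concentrations must be non-negative")
    total = C_HbO + C_HbR
    if total == 0:
        raise ValueError("oxygen saturation undefined for zero total hemoglobin")
    return C_HbO / total


def _quadratic_features(alphas: np.ndarray) -> np.ndarray:
    a1, a2, a3 = alphas[..., 0], alphas[..., 1], alphas[..., 2]
    return np.stack(
        [np.ones_like(a1), a1, a2, a3, a1 * a1, a2 * a2, a3 * a3,
         a1 * a2, a1 * a3, a2 * a3],
        axis=-1,
    )


@dataclass(frozen=True)
class ConversionModel:
    """Fitted quadratic map from alpha triples to (C_HbO, C_HbR, a)."""

    alphas: np.ndarray  # (n_grid, 3) training regression coefficients
    targets: np.ndarray  # (n_grid, 3) corresponding (C_HbO, C_HbR, a)
    coefficients: np.ndarray  # (10, 3) polynomial coefficients per target
    r2: np.ndarray  # (3,) in-sample R^2 per target
    wavelengths: np.ndarray
    window: tuple[float, float]
    forward: str  # 'mc' or 'diffusion'
    alpha_low: np.ndarray = field(init=False)
    alpha_high: np.ndarray = field(init=False)

    def __post_init__(self):
        lo = self.alphas.min(axis=0)
        hi = self.alphas.max(axis=0)
        margin = 0.10 * (hi - lo)
        object.__setattr__(self, "alpha_low", lo - margin)
        object.__setattr__(self, "alpha_high", hi + margin)

    def evaluate(self, coefs: RegressionCoefficients):
        """Map one alpha triple to (C_HbO, C_HbR, a) plus an extrapolation flag."""
        al = coefs.as_array()
        mapped = _quadratic_features(al) @ self.coefficients
        extrapolated = bool(np.any(al < self.alpha_low) or np.any(al > self.alpha_high))
        return mapped, extrapolated


class HemoglobinInverter(BaseEstimator):
    """Estimator for hemoglobin parameters from diffuse reflectance spectra.

    ``fit`` forward-simulates the fiber-pair reflectance over a rectangular
    grid of (C_HbO, C_HbR, a) in a semi-infinite single-layer cortex,
    regresses each simulated absorbance spectrum on the extinction spectra,
    and fits a full quadratic polynomial map from the resulting
    (alpha_HbO, alpha_HbR, alpha_0) triples back to the grid truth.
    ``predict`` applies absorbance conversion, regression and the fitted
    map to measured spectra.

    Parameters
    ----------
    grid_C_HbO, grid_C_HbR : array-like, mM
        Grid levels for each hemoglobin species (>= 3 levels each).
    grid_a : array-like, 1/mm
        Grid levels of the scattering amplitude (a single level collapses
        that axis; `a` is then returned as the constant).
    wavelengths : array-like, nm
        Forward-simulation and regression wavelength grid.
    forward : {'mc', 'diffusion'}
        Reference Monte Carlo forward model, or the fast dipole-diffusion
        fallback behind the same interface.
    n_photons : int
        Photons per Monte Carlo forward run.
    min_r2 : float
        Quality floor for the in-sample map fit.
    n_replicates : int
        Number of independently seeded conversion-model replicates.
        With more than one, inversion reports the component-wise median
        across replicates, which suppresses occasional model-level noise
        draws of a single Monte Carlo build.
    """

    def __init__(
        self,
        grid_C_HbO=(0.01, 0.0466667, 0.0833333, 0.12),
        grid_C_HbR=(0.01, 0.0466667, 0.0833333, 0.12),
        grid_a=(1.0, 2.0, 3.0),
        wavelengths=tuple(DEFAULT_WAVELENGTHS),
        window=DEFAULT_WINDOW,
        forward="mc",
        n_photons=100_000,
        seed=0,
        fibers=None,
        anisotropy_g=0.9,
        refractive_index=1.37,
        scattering_exponent=1.3,
        scattering_reference_nm=500.0,
        min_r2=0.95,
        n_replicates=1,
    ):
        self.grid_C_HbO = grid_C_HbO
        self.grid_C_HbR = grid_C_HbR
        self.grid_a = grid_a
        self.wavelengths = wavelengths
        self.window = window
        self.forward = forward
        self.n_photons = n_photons
        self.seed = seed
        self.fibers = fibers
        self.anisotropy_g = anisotropy_g
        self.refractive_index = refractive_index
        self.scattering_exponent = scattering_exponent
        self.scattering_reference_nm = scattering_reference_nm
        self.min_r2 = min_r2
        self.n_replicates = n_replicates

    # -- forward machinery -------------------------------------------------

    def _tissue(self, C_HbO, C_HbR, a) -> TissueModel:
        law = ScatteringLaw(amplitude_a=a, exponent_b=self.scattering_exponent,
                            reference_wavelength=self.scattering_reference_nm)
        return TissueModel(layers=(Layer(thickness=None, C_HbO=C_HbO, C_HbR=C_HbR,
                                         scattering=law, anisotropy_g=self.anisotropy_g,
                                         refractive_index=self.refractive_index),))

    def _fibers(self) -> FiberGeometry:
        return self.fibers if self.fibers is not None else FiberGeometry()

    def _ensembles(self, table, seed_offset=0):
        """One scattering-only MC path ensemble per (a-level, wavelength).

        The absorption floor of each ensemble is set just below the
        smallest grid absorber at that wavelength, so reweighting to any
        grid point never amplifies variance. At strongly absorbing
        wavelengths (the hemoglobin 540-585 nm peaks) the detected
        reflectance is carried by few short paths, so the photon count is
        boosted up to 4x there, proportionally to the mid-grid absorber;
        those runs are also the cheapest per photon, keeping the total
        cost well inside the per-grid-point forward-run budget.
        """
        from .tissue_optics import absorption_coefficient

        wl = np.asarray(self.wavelengths, dtype=float)
        fibers = self._fibers()
        c_lo = (float(np.min(self.grid_C_HbO)), float(np.min(self.grid_C_HbR)))
        c_mid = (float(np.mean(self.grid_C_HbO)), float(np.mean(self.grid_C_HbR)))
        out = {}
        for ia, a in enumerate(np.asarray(self.grid_a, dtype=float)):
            tis = self._tissue(0.0, 0.0, a)
            for iw, w in enumerate(wl):
                seed = (int(self.seed) * 1_000_003 + seed_offset * 7919
                        + ia * 1009 + iw * 13 + 1) % (2**31 - 1)
                floor = 0.9 * absorption_coefficient(c_lo[0], c_lo[1], w, table)
                mu_mid = absorption_coefficient(c_mid[0], c_mid[1], w, table)
                boost = int(np.clip(np.ceil(mu_mid / 0.3), 1, 4))
                out[(ia, iw)] = photon_mc.simulate_path_ensemble(
                    tis, fibers, w, n_photons=int(self.n_photons) * boost,
                    seed=seed, mu_a_floor=floor)
        return out

    def _forward_spectrum_from_ensembles(self, ensembles, table, C_HbO, C_HbR, ia):
        from .tissue_optics import absorption_coefficient

        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.empty_like(wl)
        for iw, w in enumerate(wl):
            mu_a = absorption_coefficient(C_HbO, C_HbR, w, table)
            refl[iw] = photon_mc.reflectance_from_paths(ensembles[(ia, iw)], mu_a)
        return refl

    # -- sklearn API -------------------------------------------------------

    def fit(self, X=None, y=None):
        """Build the conversion model(s); ``X`` and ``y`` are ignored."""
        table = load_default_chromophores()
        if int(self.n_replicates) < 1:
            raise ValueError("n_replicates must be >= 1")
        self.conversion_models_ = [
            self._fit_one(table, seed_offset=r) for r in range(int(self.n_replicates))]
        self.conversion_model_ = self.conversion_models_[0]
        self.table_ = table
        return self

    def _fit_one(self, table, seed_offset=0) -> ConversionModel:
        wl = np.asarray(self.wavelengths, dtype=float)
        c1 = np.asarray(self.grid_C_HbO, dtype=float)
        c2 = np.asarray(self.grid_C_HbR, dtype=float)
        aa = np.asarray(self.grid_a, dtype=float)
        if c1.size < 3 or c2.size < 3:
            raise ValueError("need >= 3 grid levels per hemoglobin axis")
        if self.forward not in ("mc", "diffusion"):
            raise ValueError("forward must be 'mc' or 'diffusion'")

        ensembles = (self._ensembles(table, seed_offset=seed_offset)
                     if self.forward == "mc" else None)
        alphas, targets = [], []
        for ia, a in enumerate(aa):
            for C_HbO in c1:
                for C_HbR in c2:
                    if self.forward == "mc":
                        refl = self._forward_spectrum_from_ensembles(
                            ensembles, table, C_HbO, C_HbR, ia)
                    else:
                        tis = self._tissue(C_HbO, C_HbR, a)
                        refl = np.array([
                            fiber_reflectance_diffusion(tis, self._fibers(), w, table)
                            for w in wl])
                    if np.any(refl <= 0):
                        raise ModelQualityError(
                            "forward model produced non-positive reflectance "
                            f"at grid point (C_HbO={C_HbO}, C_HbR={C_HbR}, a={a})")
                    A = -np.log10(np.clip(refl, None, 1.0))
                    coefs = regress_chromophores(wl, A, table, self.window)
                    alphas.append(coefs.as_array())
                    targets.append([C_HbO, C_HbR, a])
        alphas = np.array(alphas)
        targets = np.array(targets)

        F = _quadratic_features(alphas)
        coeffs, *_ = np.linalg.lstsq(F, targets, rcond=None)
        pred = F @ coeffs
        ss_res = ((targets - pred) ** 2).sum(axis=0)
        ss_tot = ((targets - targets.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
        # The quality floor applies to the hemoglobin concentrations. The
        # scattering amplitude is only weakly identified by the alpha triple
        # at a single source-detector separation (grid points differing only
        # in `a` produce nearly coincident alpha triples), so its R^2 is
        # reported as a diagnostic rather than gated.
        checked = r2[:2][ss_tot[:2] > 0]  # collapsed axes are exempt
        if np.any(checked < self.min_r2):
            raise ModelQualityError(
                f"conversion map R^2 {r2.round(4).tolist()} below floor {self.min_r2}")
        if aa.size == 1:
            coeffs[:, 2] = 0.0
            coeffs[0, 2] = aa[0]
        return ConversionModel(
            alphas=alphas, targets=targets, coefficients=coeffs, r2=r2,
            wavelengths=wl, window=tuple(self.window), forward=self.forward)

    def invert(self, spectrum: Spectrum) -> HemoglobinEstimate:
        """Invert one spectrum to a :class:`HemoglobinEstimate`.

        With several model replicates, the mapped parameters are the
        component-wise median across replicates.
        """
        A = absorbance(spectrum)
        coefs = regress_chromophores(spectrum.wavelengths, A, self.table_,
                                     self.conversion_model_.window)
        mapped_all, extrap_all = zip(*(m.evaluate(coefs)
                                       for m in self.conversion_models_))
        mapped = np.median(np.stack(mapped_all), axis=0)
        extrapolated = sum(extrap_all) * 2 > len(extrap_all)
        C_HbO, C_HbR, a = map(float, mapped)
        clipped = C_HbO < 0 or C_HbR < 0
        C_HbO = max(C_HbO, 0.0)
        C_HbR = max(C_HbR, 0.0)
        total = C_HbO + C_HbR
        sto2 = C_HbO / total if total > 0 else np.nan
        return HemoglobinEstimate(C_HbO=C_HbO, C_HbR=C_HbR, a=a,
                                  StO2=float(np.clip(sto2, 0.0, 1.0)),
                                  clipped=clipped, extrapolated=extrapolated)

    def predict(self, X) -> np.ndarray:
        """Invert reflectance rows; returns StO2 per row.

        ``X`` is (n_samples, n_wavelengths) on the estimator's wavelength
        grid, or an iterable of :class:`Spectrum`.
        """
        return np.array([e.StO2 for e in self.predict_estimates(X)])

    def predict_estimates(self, X) -> list[HemoglobinEstimate]:
        wl = np.asarray(self.wavelengths, dtype=float)
        out = []
        for row in X:
            spec = row if isinstance(row, Spectrum) else Spectrum(wl, np.asarray(row))
            out.append(self.invert(spec))
        return out


# -- module-level wrappers -------------------------------------------------

def build_conversion_model(**params) -> HemoglobinInverter:
    """Fit and return a :class:`HemoglobinInverter` (thin wrapper)."""
    return HemoglobinInverter(**params).fit()


def invert_spectrum(spectrum: Spectrum, inverter: HemoglobinInverter) -> HemoglobinEstimate:
    return inverter.invert(spectrum)


def forward_reflectance_spectrum(
    C_HbO: float,
    C_HbR: float,
    a: float,
    wavelengths=DEFAULT_WAVELENGTHS,
    forward: str = "mc",
    n_photons: int = 100_000,
    seed: int = 1,
    fibers: FiberGeometry | None = None,
    table: ChromophoreTable | None = None,
    **tissue_kw,
) -> Spectrum:
    """Forward-simulate a fiber-pair reflectance spectrum at known truth.

    Uses the same forward family as the conversion model ('mc' path
    ensembles with per-wavelength seeds, or the diffusion fallback).
    """
    if table is None:
        table = load_default_chromophores()
    fibers = fibers if fibers is not None else FiberGeometry()
    wl = np.asarray(wavelengths, dtype=float)
    law = ScatteringLaw(amplitude_a=a)
    tissue = TissueModel(layers=(Layer(thickness=None, C_HbO=C_HbO, C_HbR=C_HbR,
                                       scattering=law, **tissue_kw),))
    refl = np.empty_like(wl)
    if forward == "mc":
        # direct absorbing-walk simulation per wavelength: an independent
        # estimator route from the path-ensemble reweighting used to build
        # the conversion model
        for iw, w in enumerate(wl):
            res = photon_mc.simulate_reflectance(
                tissue, fibers, w, n_photons=n_photons,
                seed=(int(seed) * 131_071 + iw * 29 + 3) % (2**31 - 1), table=table)
            refl[iw] = res.reflectance_detected
    elif forward == "diffusion":
        for iw, w in enumerate(wl):
            refl[iw] = fiber_reflectance_diffusion(tissue, fibers, w, table)
    else:
        raise ValueError("forward must be 'mc' or 'diffusion'")
    return Spectrum(wl, np.clip(refl, 1e-12, 1.0))


def read_spectra_csv(path) -> tuple[np.ndarray, list[Spectrum]]:
    """Read a spectra CSV: first column time_s, remaining columns are
    wavelength-labelled reflectance."""
    df = pd.read_csv(path)
    times = df.iloc[:, 0].to_numpy(dtype=float)
    wl = np.array([float(c) for c in df.columns[1:]])
    order = np.argsort(wl)
    wl = wl[order]
    vals = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    return times, [Spectrum(wl, v) for v in vals]


def estimates_to_frame(times, estimates) -> pd.DataFrame:
    """Assemble an estimates table (time_s, concentrations, StO2, flags)."""
    return pd.DataFrame({
        "time_s": np.asarray(times, dtype=float),
        "C_HbO_mM": [e.C_HbO for e in estimates],
        "C_HbR_mM": [e.C_HbR for e in estimates],
        "C_THb_mM": [e.C_HbT for e in estimates],
        "a_mm": [e.a for e in estimates],
        "StO2": [e.StO2 for e in estimates],
        "flags": ["|".join(
            f for f, on in (("clipped", e.clipped), ("extrapolated", e.extrapolated)) if on)
            for e in estimates],
    })
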