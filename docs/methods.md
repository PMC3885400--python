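# Methods

This note records the models, numerical choices and known limits of the
package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Tissue optics

Absorption is a two-chromophore Beer–Lambert assembly,
μₐ(λ) = ln 10 · (ε_HbO(λ)·C_HbO + ε_HbR(λ)·C_HbR)/10 in 1/mm with
concentrations in mM and extinctions in 1/(mM·cm). Water, lipid and
cytochrome absorption are deliberately excluded from the quantitative
inversion — within the 500–620 nm analysis band hemoglobin dominates
cortical absorption, and the ratiometric heme-aa₃ signal is treated as a
trace-level detector rather than a fitted chromophore.

The packaged extinction table (450–1000 nm, 1 nm steps) is a
landmark-calibrated compilation of standard whole-blood molar extinction
values: anchor points at the Soret tail, the HbO₂ 542/578 nm twin peaks,
the HbR 555 nm peak and the 500/529/569/797 nm isosbestic points,
monotonically (PCHIP) interpolated to the uniform grid. The table
satisfies the constraints the analysis relies on — |ε_HbO−ε_HbR|/ε_HbO
< 5% at 569 nm, < 15% at 805 nm, ε_HbO(578) well above ε_HbR(578) — and
is intended as a conventional stand-in: any other published compilation
can be dropped in as a CSV with the same columns.

Reduced scattering follows the power law μ′ₛ(λ) = a·(λ/500 nm)^(−b)
with b = 1.3 (a typical Mie-like brain slope) fixed, leaving the
amplitude a (1/mm) as the single scattering unknown of the inversion.
Cortex defaults: g = 0.9, n = 1.37. The optional skull layer defaults to
1.0 mm thickness, a = 2.4 1/mm with b = 0.65, n = 1.55 and near-zero
absorption; all values are config-overridable since rodent skull optics
vary strongly with age and preparation.

## Monte Carlo transport

`photon_mc` is a standard weighted-photon walk in a plane-parallel layer
stack: step length s = −ln ξ/μₜ, per-collision weight decrement W·μₐ/μₜ,
Henyey–Greenstein deflection, unpolarized Fresnel splitting at
refractive-index mismatches, Russian roulette below weight 1e−4 with
survival factor 10. Photons launch uniformly over the source-fiber core
with directions uniform in the NA cone (NA 0.39, typical for 800 µm
multimode fiber), refracted at entry.

Detection uses the azimuthal symmetry of the geometry: a photon escaping
at radial distance ρ contributes the exact arc fraction of the circle of
radius ρ that overlaps the detector face, rather than a binary footprint
hit. This is unbiased under the symmetric source and reduces detection
variance by roughly the ring-to-fiber area ratio (~20× at 2 mm
separation). Escaping photons must also fall inside the NA cone after
refraction. Each detected photon records its maximum visited depth; the
sampling-depth diagnostic reports weighted percentiles of those depths,
referenced to the cortical surface when a skull layer is present.

Energy accounting (reflected + absorbed + transmitted = 1) holds to the
roulette tolerance of 1e−3. A fixed seed gives bit-identical results;
the generator is NumPy's Mersenne Twister seeded inside the jitted
kernel, single-threaded.

**Path ensembles.** Building the conversion model needs the detected
reflectance over a 4×4×3 grid of (C_HbO, C_HbR, a) at 25 wavelengths.
Instead of 1200 absorbing-walk runs, one scattering-only run per
(a-level, wavelength) — 75 ensembles of 10⁵ photons — records each
detected photon's true path length L, and the reflectance for any
absorber follows from the path-length estimator mean(w·exp(−μₐL)).
Because the escape-path distribution of a non-absorbing semi-infinite
medium is heavy-tailed (first-passage t^(−3/2)), a baseline absorber at
90% of the smallest grid μₐ(λ) is applied by termination sampling: each
photon draws an exponential absorption horizon and dies when its path
exceeds it. This is itself an unbiased absorber model; the estimator
divides the implicit exp(−μₐ,floor·L) factor back out, so reweighting to
any grid absorber stays exact while the tail cost disappears.
Deterministic safety cutoffs (30 mm depth, 2000 mm path) truncate with
relative bias below 1e−8 for the absorber range served.

At the hemoglobin absorption peaks (540–585 nm) the detected
reflectance falls to ~10⁻⁵–10⁻⁶ and is carried by few short paths, so
per-wavelength noise there dominates the conversion-model error — and,
because every grid point shares the same ensembles, that noise is
*correlated* across the grid and does not average out with more grid
points. The ensemble photon count is therefore boosted up to 4× at
wavelengths with high mid-grid absorption (those runs are also the
cheapest per photon, since the absorption floor terminates paths early).
Total photon launches for the model build (~1.4×10⁷) remain an order of
magnitude below the 48 per-grid-point forward runs they replace
(48 × 25 × 10⁵ = 1.2×10⁸ launches).

Test spectra for round trips are simulated by the *direct* absorbing
walk at 10⁵ photons per wavelength — a deliberately different estimator
route from the path-ensemble reweighting, so that the inversion is
checked against independently generated data.

## Diffusion fallback and oracle

`diffusion` implements the extrapolated-boundary dipole solution for
spatially resolved steady-state reflectance R(ρ) (Groenhuis internal
reflection parameter for mismatched boundaries) and its closed-form
radial integral for total diffuse reflectance,
R_tot = (a′/2)(e^(−μ_eff z₀) + e^(−μ_eff z_p)). The radial form serves
as a fast analytic forward model behind the same interface as the MC
path (absolute scale differences are flat in wavelength and absorbed by
the regression intercept); the integral form is the independent oracle
for MC total reflectance in the diffusive regime (μ′ₛ/μₐ ≥ 100, matched
boundary), where the two agree within a few percent.

## Spectral inversion

The chain is: absorbance A(λ) = −log₁₀ R(λ); ordinary least squares of
A on [ε_HbO, ε_HbR, 1] over 500–620 nm (25 samples at 5 nm; the window
covers the 569/578/605/620 nm ratiometric anchors and is hemoglobin-
dominated); a full quadratic polynomial map (10 terms per target) from
the coefficient triple to each of C_HbO, C_HbR and a, fitted by least
squares on the 48-point forward grid C_HbO, C_HbR ∈ {0.01…0.12 mM, 4
levels}, a ∈ {1, 2, 3 1/mm}. StO₂ = C_HbO/(C_HbO+C_HbR); negative
mapped concentrations are clipped to zero and flagged; coefficient
triples outside the training box (±10% margin) are flagged as
extrapolated but still inverted.

**Identifiability.** The coefficient triple localizes the hemoglobin
concentrations sharply (map R² ≥ 0.99 on its own grid) but the
scattering amplitude only weakly: grid points differing solely in a
produce nearly coincident triples at a single 2 mm source–detector
separation, so the a-map plateaus near R² ≈ 0.8 for any smooth
functional form. The model-quality gate therefore applies to the
concentration targets; a is returned as a diagnostic with its grid R²
reported, and changing the tissue's true a does not bias recovered StO₂
by more than ~3 percentage points (tested). Resolving a properly would
require multi-distance or spatially resolved measurements, which are out
of scope.

**Model replicates.** A single Monte Carlo model build carries
wavelength-correlated noise that occasionally shifts inverted StO₂ by
several points. The estimator therefore supports bagging
(`n_replicates`): several independently seeded conversion models are
built and inversion reports the component-wise median of the mapped
parameters. The acceptance computations use three replicates; the
default stays one for interactive use.

The quadratic map is accurate at interior grid points (median in-sample
relative error 1–2%) and degrades toward the lowest-concentration
corners of the box (tens of percent); trajectories of physiological
interest (total hemoglobin ~0.1 mM, StO₂ 35–70%) sit well inside the
accurate region. Round trips recover StO₂ within ±5 percentage points
through the Monte Carlo chain (photon-noise limited) and within well
under 1 point noiseless through the analytic chain.

## Event detectors

All detectors act on baseline-normalized traces (pre-stimulus window
mean mapped to 1), making them invariant to positive rescaling, and all
booleans are monotone in their thresholds. Defaults: scattering
|ΔR₈₀₅| > 5% within 5 min; EEG sliding-RMS envelope (10 s window) below
50% of pre-stimulus RMS for ≥ 60 s; hypoxemia ratio below 0.97 for ≥
1800 s after its turning point; heme ratio below 0.98 (longest epoch
starting within 10 min); DC shift = pre-stimulus mean minus
post-stimulus minimum of a 5 s-smoothed trace, onset at 3 noise-SDs
below baseline, ±5 s around the stimulus excluded as artifact.

The turning point (hyperoxemia→hypoxemia, or hyperemia→oligemia) is the
first baseline crossing after the post-stimulus extremum, linearly
interpolated between samples, ties toward the earlier time. The
implementation anchors on the earlier of the global positive/negative
extrema of a lightly smoothed (5 s) trace that exceed
max(3 baseline-noise SD, 10% of maximum deviation): anchoring on global
extrema rather than the first threshold exceedance makes the detector
robust to isolated noise excursions in the pre-onset interval.

Sign conventions are explicit configuration: a *decrease* in normalized
R₅₆₉ encodes increased blood volume (hyperemia); an *increase* in
R₅₇₈/R₅₆₉ encodes hyperoxemia; a *decrease* in R₆₀₅/R₆₂₀ encodes
heme-aa₃ reduction. The heme ratio's printed orientation differs
between sources; the generator and detector both treat polarity as a
flag with "decrease = reduction" as the default.

## Wave kinetics

Difference images (frame minus the frame at stimulus time) expose the
expanding bright annulus with a trailing dark annulus. Per frame, pixels
above 3× the per-pixel SD of the first three difference frames are kept
if they belong to a connected component of ≥ 20 px; the front radius is
the 95th percentile of their distances from the application site
(robust to ragged blob edges; the percentile's constant offset from the
true front is absorbed by the fit intercept). Speed is the OLS slope of
radius versus time in mm/min. The front definition and fit interval are
this module's own operationalization — validated on synthetic truth
across 1.6–3.3 mm/min with < 5% bias — since printed speeds in the
literature rarely state theirs. The multichannel expansion speed is the
OLS slope of probe distance versus detected turning-point time.

## Synthetic generators

Trace templates are piecewise cubic-smoothed steps (smoothing constant
10 s) so the sub-sample turning-point interpolation is genuinely
exercised. The default episode transcribes the reference morphology:
4 min oscillatory scattering transient (±15% amplitude), 7 min EEG
suppression (residual amplitude 20%), hyperoxemia (+3%) turning to
hypoxemia (−5%) at 4 min and lasting 1.5 h, heme dip (−4%) from 1.5 min
lasting 3 min, DC shift of 7.2 mV at 2 min with a 30 s fall and 50%
partial recovery before a second decline. Noise models: additive
Gaussian for traces (SD 0.002 of the normalized scale, spectrometer
class), multiplicative Gaussian for spectra, Poisson-approximate
Gaussian for 8-bit image stacks (SD 2 DN on a 120 DN background, CCD
class). Image stacks expand a Gaussian-profile bright annulus (FWHM
0.8 mm) trailed by a dark annulus 1.2 mm behind, at 1 frame/5 s and
0.05 mm/px.

The generators emulate event *morphology and timing*, not biophysics:
there is no reaction–diffusion substrate, no hemodynamic coupling, and
the spectra carry no instrument baseline drift or stray-light terms.
Passing round trips therefore demonstrate that the estimators recover
the parameters they are defined on under realistic noise — not that the
detectors are robust to every artifact of real recordings. Absolute
reflectance scales of real instruments are unknown; generators emit
normalized-scale data throughout.

The cohort generator draws Bernoulli events with the empirical
per-fluence rates of the packaged 24-animal table (group sizes 5/12/5/2
at 0.75/1.0/1.25/1.5 J/cm²), with hypoxemia and heme reduction
conditioned on SD occurrence; at large n the pooled conditional
fractions converge to the table's 83.3%/77.8%.

## Problem sizes and determinism

Default problem sizes are desk-scale by design: 10⁵ photons per Monte
Carlo forward run (48-point grid, 25 wavelengths via 75 shared path
ensembles), 40-frame 340×340 image stacks, hour-scale traces at 1 Hz
(EEG 100 Hz, DC 10 Hz). Every stochastic component takes an explicit
seed and is reproducible bit-for-bit; derived seeds are folded modulo
2³¹−1.

## Known limitations

* The scattering amplitude a is weakly identified (see above); treat
  its absolute value as qualitative.
* The extinction compilation is a landmark-calibrated stand-in, not a
  certified reference dataset.
* The MC model assumes smooth plane-parallel layers; surface curvature,
  vasculature heterogeneity and the finite skull window are not
  represented.
* Detector thresholds are tuned to the generator's noise class; real
  recordings with movement or electrode artifacts will need the config
  knobs the detectors expose.
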