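# neuroreflect

Diffuse-reflectance neurophotonics for cortical spreading depolarization
(SD) studies in rodents. The package implements, end to end, the optical
analysis used when a shock wave (or comparable insult) is applied to the
cortex and the brain is monitored in real time with a fiber-based
spectrometer, an EEG electrode, a DC-potential electrode and an NIR
camera:

* **Forward Monte Carlo photon transport** (`photon_mc`) in layered
  tissue for a source–detector fiber pair (800 µm cores, 2 mm
  separation), with Henyey–Greenstein scattering, Fresnel boundaries and
  Russian-roulette termination, plus a dipole diffusion-approximation
  fallback (`diffusion`).
* **Hemoglobin oxygen-saturation inversion** (`inversion`). A measured
  reflectance spectrum R(λ) is converted to absorbance
  A(λ) = −log₁₀ R(λ) and regressed on the HbO/HbR molar extinction
  spectra, A(λ) ≈ α_HbO ε_HbO(λ) + α_HbR ε_HbR(λ) + α₀; a pre-computed
  quadratic *conversion model*, fitted on a grid of Monte Carlo forward
  simulations, maps (α_HbO, α_HbR, α₀) to (C_HbO, C_HbR, a), and
  StO₂ = C_HbO/(C_HbO + C_HbR). Exposed as the sklearn-style estimator
  `HemoglobinInverter` (`fit` builds the model, `predict` inverts
  spectra).
* **Ratiometric band signals and event detectors** (`ratiometrics`):
  R₈₀₅ (scattering), R₅₆₉ (inverse rCBV, isosbestic), R₅₇₈/R₅₆₉
  (oxygenation) and R₆₀₅/R₆₂₀ (heme-aa₃ redox) traces; detectors for the
  drastic scattering change, EEG suppression, the hyperoxemia→hypoxemia
  turning point, long-lasting hypoxemia, heme-aa₃ reduction and the
  negative DC-potential shift; per-animal event classification.
* **Wave kinetics** (`wave_kinetics`): difference imaging of NIR stacks,
  front-radius tracking (95th-percentile radius of super-threshold
  pixels) and OLS radius-vs-time speed fits; multichannel onset
  regression for the hypoxemia expansion speed.
* **Cohort summaries** (`cohort`): SD tallies and conditional event
  fractions over an event table, and the linear fluence→peak-pressure /
  impulse calibration fit.
* **Synthetic data** (`synthetic`): generators for every input modality
  with programmed event parameters, so the full pipeline is testable
  without instrument data.

## Worked example

Estimate StO₂ from a synthetic hypoxemic-phase spectrum using the fast
analytic forward model:

```python
from neuroreflect.inversion import HemoglobinInverter, forward_reflectance_spectrum

inverter = HemoglobinInverter(forward="diffusion").fit()
spectrum = forward_reflectance_spectrum(0.035, 0.065, 2.0, forward="diffusion")
est = inverter.invert(spectrum)
print(f"StO2 = {100 * est.StO2:.1f}%  (truth 35.0%)")
print(f"C_HbO = {est.C_HbO:.4f} mM, C_HbR = {est.C_HbR:.4f} mM")
```

prints

```
StO2 = 35.0%  (truth 35.0%)
C_HbO = 0.0342 mM, C_HbR = 0.0636 mM
```

i.e. the inversion recovers the programmed saturation within a fraction
of a percentage point and the hemoglobin concentrations within a few
percent. With `forward="mc"` the same chain runs against the reference
Monte Carlo transport (a few minutes to build the conversion model at
10⁵ photons per forward run; recovery then lands within a few
percentage points, limited by photon noise — `n_replicates=3` builds
median-bagged model replicates for extra stability).

Cohort tallies from the packaged 24-animal event table:

```bash
$ neuroreflect cohort tally
n_total=24 n_sd=18 hypoxemia|SD=15 (83.3%) heme|SD=14 (77.8%)
```

Other CLI entry points: `neuroreflect mc run`, `invert build-model`,
`invert run`, `classify`, `wave speed`, and `synth
traces|spectra|wave|channels|cohort` for generating inputs.

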