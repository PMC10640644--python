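# spphp — plasmon–phonon-polariton infrared biosensing toolkit

Infrared spectroscopy identifies molecules by their vibrational
fingerprints, and fails when those fingerprints overlap. `spphp`
implements, end to end, the computational machinery of a sensing
scheme that breaks such degeneracies with the molecular *refractive
index*: a localized surface plasmon (LSPP) coupled to a surface phonon
polariton (SPhP) of a polar oxide produces hybridized modes inside the
oxide's Reststrahlen band, and the band-integrated vibrational
intensity of the SPhP,

    ΔI = ∫_{ω_TO}^{ω_LO} D(ω) dω,

responds to the analyte's refractive index change Δn through the
detuning of the plasmonic resonance (redshift Δω = −s·Δn). The
package covers:

* **polariton physics** — Lorentz-oscillator permittivity
  ε(ω) = ε∞ + Σ Sᵢ/(ω₀ᵢ² − ω² − jωγᵢ), Reststrahlen band location,
  the surface-polariton dispersion k = (ω/c)√(ε₁ε₂/(ε₁+ε₂)), and the
  dressed modes ω± of the coupled LSPP–SPhP system in closed form and
  via the radiating-oscillator characteristic equation |H − ωI| = 0;
* **spectral processing** — differential absorbance −1000·log₁₀(R/R₀)
  (mOD), asymmetric-least-squares (Whittaker) baselines, a refractive-
  index-informed *joint* baseline correction, band integration, FWHM,
  figure of merit, normalized frequency shift;
* **synthetic data** — Michaelis–Menten kinetics of the glucose
  enzymatic reaction (GER: glucose → gluconolactone + H₂O₂, catalyzed
  by glucose oxidase), per-reactant vibrational signatures with
  refractive increments, and time-resolved spectra for the coupled
  platform versus a plain nanorod antenna, with noise and baseline
  drift;
* **neural de-overlapping** — a 1714-20-20-5 fully connected ReLU
  regressor (MSE, Adam) that maps one spectrum to five per-reactant
  weights, plus accuracy and separation metrics and the platform
  comparison.

The scientific point: the H₂O₂ O–H band and the enzyme amide band are
spectrally collinear in the generator — no method can split them from
band shape. The coupled platform's narrow in-band SPhP feature encodes
the total refractive index with high contrast, and the species'
different refractive increments then make the degenerate pair
identifiable; the nanorod's broad shift response drowns in baseline
ambiguity, and its network cross-assigns the overlapping bands.

## Worked example

```python
import numpy as np
from spphp.polariton import (DEFAULT_SIO2, DEFAULT_SYSTEM,
                             DEFAULT_SHIFT_SENSITIVITY, default_grid,
                             reststrahlen_band, delta_I_transition_curve)

band = reststrahlen_band(DEFAULT_SIO2)
print(f"Reststrahlen band: {band.omega_to:.1f} - {band.omega_lo:.1f} cm^-1")

tc = delta_I_transition_curve(DEFAULT_SYSTEM, np.linspace(0, 0.4, 40),
                              band, default_grid(), DEFAULT_SHIFT_SENSITIVITY)
print(f"dI = {tc.A:.1f} - {tc.B:.1f} exp(-dn/{tc.c:.3f}),  R^2 = {tc.r_squared:.5f}")
```

prints

```
Reststrahlen band: 1072.3 - 1255.7 cm^-1
dI = 72768.5 - 72500.8 exp(-dn/1.249),  R^2 = 0.99961
```

i.e. the device oxide supports surface phonon polaritons between
ω_TO ≈ 1072 and ω_LO ≈ 1256 cm⁻¹, and the band statistic ΔI (mOD·cm⁻¹)
follows a saturating exponential in the index change Δn almost
perfectly — the refractometric calibration of the platform.

Training the de-overlapper and profiling the reaction
(`python analysis/05_reaction_profiling.py --seed 1`) prints the
validation accuracy of the network (all five outputs within τ = 0.1)
and the predicted enzyme/H₂O₂ weight separation at the 12-minute end
of the reaction, whose designed ground-truth value is 0.50; the
matching nanorod run (`--platform nanorod`) collapses that separation.
The numbered scripts under `analysis/` walk through the full study:
mode structure, transition curve, sensitivity map, joint baseline,
reaction profiling, platform comparison, writing their tables under
`results/`.

A `spphp` console command exposes the same stages
(`spphp simulate`, `generate`, `baseline`, `train`, `predict`,
`compare`, `reproduce`).

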