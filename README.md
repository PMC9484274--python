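# boneeis

Machine-learning-assisted electrochemical impedance spectroscopy (EIS) for
quantifying bone mineral content.

During bone healing the mineral (hydroxyapatite) fraction of the tissue
recovers toward its intact level, and with it the tissue's electrical
impedance. `boneeis` implements an analysis chain that turns impedance
spectra of bone samples into a six-class mineral-content call
(0/20/40/60/80/100 wt%):

1. **Forward model & fitting** — bone spectra follow the equivalent circuit
   `Z(f) = R_b + 1/(1/R_Ct + Q (j 2πf)^α)`: bulk bone resistance `R_b` in
   series with the bone–electrode interface, modelled as a charge-transfer
   resistance `R_Ct` in parallel with a constant phase element (CPE,
   `Z_CPE = 1/(Q (jω)^α)`). Spectra are fitted by multistart Nelder–Mead
   complex least squares with modulus weighting, reporting R² over the
   concatenated real/imaginary components.
2. **Mass balance** — mineral-content labels derive from the wet-weight
   change during demineralization:
   `W_lost = ρ_M · ΔW_wet / (ρ_W − ρ_M)`, with the remaining content
   expressed in wt% of the intact mineral mass.
3. **Classification** — features are `log10|Z|` at the 60 grid frequencies,
   optionally combined with the four fitted circuit parameters; columns are
   z-scored on training rows, reduced by PCA, and classified by logistic
   regression, a ν-SVM, a neural network or a random forest on a stratified
   70/21 train/test split.
4. **Synthetic data** — since no measured spectra are distributed, a seeded
   generator emulates the study conditions (91 samples over six classes,
   circuit parameters trending with mineral content, lognormal inter-sample
   variability, 2% multiplicative spectral noise). See `docs/methods.md`
   for the model, the calibration of the generator defaults, and what the
   synthetic results do and do not show.

## Worked example

```python
import numpy as np
from boneeis import (GeneratorConfig, generate_dataset, fit_spectrum,
                     class_mean_params, circuit_impedance, make_grid)

# noiseless intact-bone spectrum: capacitive low end, resistive high end
spec = circuit_impedance(class_mean_params(100), make_grid())
print(f"|Z|(1 Hz) = {spec.modulus[0]:.3e} ohm, "
      f"phase(1 Hz) = {spec.phase_deg[0]:.1f} deg, "
      f"|Z|(100 kHz) = {spec.modulus[-1]:.3e} ohm")

# fit one noisy synthetic spectrum and recover its circuit parameters
ds = generate_dataset(GeneratorConfig(seed=42))
s = ds.samples[0]          # a 0 wt% (fully demineralized) sample
fit = fit_spectrum(s.spectrum)
print(f"true R_b = {s.true_params.r_b:.3e}, fitted R_b = {fit.params.r_b:.3e}, "
      f"R^2 = {fit.r_squared:.4f}")
```

prints

```
|Z|(1 Hz) = 9.860e+06 ohm, phase(1 Hz) = -57.5 deg, |Z|(100 kHz) = 3.185e+05 ohm
true R_b = 1.026e+04, fitted R_b = 1.022e+04, R^2 = 0.9997
```

— the intact-bone phase magnitude is ≈ 60° at low frequency and the
spectrum becomes purely resistive (`|Z| → R_b`) at high frequency; the
fitted bulk resistance matches the generating value to ~0.4% despite 2%
measurement noise.

The full comparison (both feature sets × four classifiers, mirroring the
study design) runs from the shell:

```sh
boneeis pipeline --seed 7 --out report.json
```

which prints a table of per-model accuracy/precision; with the default
generator the combined-feature ν-SVM classifies the 21 test spectra
essentially perfectly, while impedance-only features do markedly worse —
the equivalent-circuit deconvolution is what makes the classes separable.
Other subcommands: `simulate`, `mineral`, `fit`, `featurize`, `classify`
(see `boneeis <cmd> --help`).

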