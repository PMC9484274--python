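# Methods

## Problem and model

Bone mineral content (the weight fraction of hydroxyapatite remaining in a
cortical bone sample, 0–100 wt%) correlates with the electrical impedance of
the tissue, which can be probed non-destructively by electrochemical
impedance spectroscopy (EIS): a small AC voltage is applied across the
sample and the complex impedance `Z(f)` is recorded over a frequency sweep
(here 60 log-spaced points over 1 Hz–100 kHz, the measurement design used
throughout; the point density is configurable).

The spectra are described by a two-layer equivalent circuit: the bulk bone
tissue contributes a series resistance `R_b`, while the bone–electrode
interface contributes a charge-transfer resistance `R_Ct` in parallel with a
constant phase element (CPE) representing a non-ideal double layer:

    Z(f) = R_b + 1 / (1/R_Ct + Q (j 2 pi f)^alpha)

with `Q` in S·s^alpha and `alpha` in (0, 1] (`alpha = 1` is an ideal
capacitor). The CPE convention `Z_CPE = 1/(Q (j omega)^alpha)` is the
universal one. Phase is stored signed — negative for capacitive behaviour —
and plotted/reported as a magnitude where the Bode convention calls for it.

Physical consequences used as test oracles: `|Z|` is non-increasing in
frequency; `Im Z <= 0` everywhere; `Z -> R_b` as `f -> inf` and
`Z -> R_b + R_Ct` as `f -> 0`; at `alpha = 1` the Nyquist locus is the
closed-form RC semicircle of radius `R_Ct/2` centred at `(R_b + R_Ct/2, 0)`
with its apex at `omega = 1/(R_Ct Q)`.

## Mineral mass balance

Demineralization replaces the dense mineral phase (density `rho_M`, default
3.16 g/cm³ for hydroxyapatite) by buffer (density `rho_W`, default
1.00 g/cm³), under the assumption of volume conservation. The wet-weight
change `dW_wet = w_after − w_before` (non-positive) then determines the
mineral lost:

    V_lost = dW_wet / (rho_W − rho_M),    W_lost = rho_M · V_lost

and the remaining mineral content is `100·(1 − W_lost,cum / W_mineral,0)`
wt%. Both densities are standard physical constants and configurable. The
`boneeis mineral` command treats the last weighing record of each sample as
the fully demineralized endpoint, so trajectories are expressed relative to
the total mineral ultimately removed — consistent with labels defined
against fully demineralized reference samples.

## Synthetic data generator

No measured spectra are distributed with the package; the generator emulates
the study conditions instead. Six classes (0, 20, 40, 60, 80, 100 wt%) with
per-class counts (16, 16, 16, 15, 12, 16) — 91 samples, matching the 70/21
train/test design below. Class-mean circuit parameters follow the observed
parameter-versus-mineral-content trends:

- `R_b`: log-linear from 10 kΩ at 0 wt% to 316 kΩ at 100 wt% (bulk
  resistance falls as resistive mineral is removed);
- `R_Ct`: two plateaus, 500 MΩ at ≥ 80 wt% and 100 MΩ below (the
  interfacial resistance drops after ~20% demineralization, then holds);
- `Q`: two plateaus, 3.0e-8 S·s^alpha at ≥ 80 wt% and 4.5e-8 below (the
  CPE magnitude rises slightly, then stabilizes);
- `alpha = 2/3`, constant.

The magnitudes are calibrated, once, against the qualitative constraints the
measured spectra satisfy: the low-frequency phase magnitude of intact bone
is ≈ 60° at 1 Hz (this requires the CPE to dominate both `R_b` and `R_Ct`
at the low-frequency end, which pins `Q` and the `R_Ct` floor once the
`R_b` scale is fixed), class-mean `|Z|(1 Hz)` increases strictly with
mineral content, and the first principal component of the impedance-only
feature matrix carries ≥ 90% of the variance. With these defaults the
noiseless intact-bone phase at 1 Hz is ≈ 57.5°.

Inter-sample variability is lognormal around the class means with a
coefficient of variation of 0.10 (`alpha` held fixed) — lognormality keeps
parameters positive and the CV parameterization is directly interpretable.
Measurement noise is multiplicative Gaussian, `(1 + eps)` with
`eps ~ N(0, 0.02²)`, applied independently to the real and imaginary
components at each frequency, with `Im Z` clamped to ≤ 0. The generator is
fully determined by its config, including the seed.

What the generator does **not** emulate: electrode drift, contact-pressure
variation, temperature/humidity effects, stray capacitance above 100 kHz,
outliers, or any frequency-correlated noise. Passing tests therefore show
that the pipeline recovers the information the circuit model encodes under
idealized noise — not that it would reach the same accuracy on bench data.

## Circuit fitting

Complex nonlinear least squares with the objective

    S = sum_i w_i |Z_model(f_i) − Z_obs(f_i)|²

minimized by Nelder–Mead over `[log10 R_b, log10 R_Ct, log10 Q, alpha]`
(log-parameterization enforces positivity without constrained optimization;
`alpha` is clamped to (0, 1]). Modulus weighting `w_i = 1/|Z_obs(f_i)|²` is
the default because `|Z|` spans roughly two decades across the grid and an
unweighted fit would ignore the high-frequency structure; unit weighting is
available. The heuristic start reads `R_b` off the high-frequency modulus
plateau, `alpha` off the low-frequency phase (`|theta|/90`), `Q` from the
low-frequency CPE modulus after subtracting `R_b`, and sets `R_Ct` large
(100×|Z| at the lowest frequency) since no low-frequency plateau is visible
in general. Because Nelder–Mead is local, the fit is a seeded multistart
(default 8 starts: the heuristic plus jitters of ±0.5 in log10 space,
±0.1 on alpha) followed by a polish run from the winner; the reported
result is the smallest `S`. Non-convergence is reported via a flag, not an
exception.

Goodness of fit is `R² = 1 − SS_res/SS_tot` over the concatenated real and
imaginary components, with `SS_tot` centred on the per-component means —
one of several possible extensions of R² to complex data; it is documented
here and pinned by tests. On noiseless model-generated spectra the fitter
recovers all four parameters to well within 0.1%; at 2% multiplicative
noise the median relative error of `R_b` stays below 10% and fitted R²
above 0.99. Under the generator defaults `R_Ct` is intentionally much
larger than the CPE modulus everywhere in-grid, so fitted `R_Ct` is weakly
identified on default synthetic spectra (the recovery tests draw truths
from ranges where it is identifiable).

## Features, PCA and classification

Feature encodings: `log10 |Z(f_i)|` per grid frequency (60 columns), and a
combined mode appending `log10 R_b, log10 R_Ct, log10 Q, alpha` from the
per-spectrum fits (64 columns). Logs are used because the resistive
quantities span decades. Columns are z-scored with statistics fitted on
training rows only (zero-variance columns map to zero) — the split is made
before any statistic is computed, so no information leaks from test rows.

PCA is computed on the standardized training matrix; components carry a
deterministic sign convention (largest-magnitude loading entry positive).
The number of retained components is the smallest `k` whose cumulative
explained-variance ratio reaches the threshold (default 0.90), floored at a
per-mode minimum: 1 for impedance-only (where PC1 carries ≥ 90% under the
default generator, and a single component is the study's reduction) and 2
for the combined mode. The floor of 2 is a deliberate design choice: the
circuit contributes two physically independent class-informative directions
— the bulk-resistance trend separating the lower classes and the
interfacial `Q`/`R_Ct` plateau step at 80 wt% — and a strictly 1-D
projection of a six-class problem discards one of them regardless of how
much variance the first component happens to capture.

Split design: 70 training / 21 test spectra with fixed per-class counts
(12, 12, 12, 12, 9, 13) / (4, 4, 4, 3, 3, 3), drawn uniformly without
replacement within each class. Classifiers: multinomial logistic regression
(ridge, C = 1), nu-SVM (NuSVC, nu = 0.5, RBF kernel, scale gamma, native
one-vs-one multiclass), a single-hidden-layer neural network (100 rectified
units, ≤ 1000 iterations) and a random forest (100 trees, unlimited depth).
All hyperparameters are widely used defaults and overridable. Report-level
precision averages per-class precision (column-correct / column-total, 0
for an empty column) weighted by actual class sizes.

One master seed fans out through `numpy.random.SeedSequence` to the
generator, fit restarts, split and classifiers, so a single integer
reproduces an entire run bit-for-bit.

## Numerical choices and problem sizes

- Nelder–Mead: adaptive simplex, per-restart iteration cap 2000, relative
  objective tolerance 1e-10; the polish run tightens `xatol` to 1e-12.
- Degenerate inputs: constant observed spectra make R² undefined
  (degenerate-data error); equal mineral/buffer densities make the mass
  balance degenerate; `|Z_obs| = 0` is rejected under modulus weighting.
- Ties in the PCA sign convention cannot occur for continuous data; the
  flip uses the first largest-magnitude entry.
- Pipeline-level tests run the fitter with 2 restarts and an 800-iteration
  cap — synthetic spectra are near-noiseless and start from the heuristic
  guess, so the reduced effort changes fitted parameters negligibly while
  keeping multi-seed comparisons cheap. Recovery and acceptance tests use
  the default 8 restarts.

## Known limitations

- The generator's parameter scales are calibrated to qualitative features
  of the published spectra, not to measured parameter values (none are
  published numerically); absolute impedance levels are therefore
  illustrative.
- Classification accuracy on synthetic data reflects the generator's class
  structure (a 0.3-decade `R_b` step between adjacent classes against a
  0.10 CV) and should not be read as a forecast of bench performance.
- `R_Ct` is weakly identified on default synthetic spectra (see above); its
  fitted column contributes little beyond noise to the combined features.
- No Kramers–Kronig validity testing, confidence intervals, stray
  capacitance (> 100 kHz) or multi-dispersion tissue models.
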