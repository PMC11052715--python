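# Methods

## Forward model

The simulator treats skin as a stack of plane-parallel layers in one
dimension. Each layer carries a chromophore composition (volume
fractions for water/keratin/lipid, mg dl⁻¹ for solutes), and the
absorption coefficient at wavenumber ν is the concentration-weighted sum
of library spectra, each a set of Gaussian bands plus a slowly varying
linear baseline. Glucose is special-cased: a layer declares which
glucose pool it samples — `blood` (capillary plexus), `isf` (dermal
interstitial fluid) or `none` (superficial layers) — and the
concentration is substituted at run time from the glucose-tolerance-test
state. The initial optoacoustic pressure follows Beer–Lambert:

    p0(z, ν) = Γ · μa(z, ν) · exp(−∫₀ᶻ μa(z', ν) dz'),

mapped to arrival time t = t_surface + z/c, convolved with a zero-phase
Gaussian band-pass whose −6 dB amplitude edges sit at the transducer's
6 and 36 MHz band limits, and perturbed with additive white Gaussian
noise of standard deviation 1.4 % of the record's peak clean amplitude,
scaled by 1/√N for N-pulse averaging (N = 1000 by default; an
explicit-draw mode exists for verifying the averaging statistics).
There is no optical scattering, no acoustic diffraction and no
frequency-dependent acoustic attenuation: the analysis downstream uses
only envelope timing and amplitude, for which this 1-D model is the
minimal faithful forward operator.

**Boundary smoothing.** Real skin layers are not ideal planes: the
epidermal–dermal junction undulates (rete ridges) and hydration grades
from the dry stratum corneum into the dermis, so the composition
profile effectively seen by a focused spot is smooth in depth.
Concentration profiles are therefore blurred with a Gaussian kernel
(`SkinModel.boundary_smoothing_um`, default σ = 18 µm) before the
acoustic step. With ideal slab boundaries the band-limited transducer
sees only isolated edge signals and the fitted 1/e² depth collapses to
the surface lump (~60 µm); with the blur the envelope becomes the
single broad decaying lump the depth convention presumes, with a fitted
1/e² depth of ~110–140 µm. The blur is applied inside the acoustic
forward operator only; `absorption_profile` reports the unblurred
composition.

## Default study conditions

Values the tissue/instrument literature pins down are used directly;
the remaining magnitudes are stylized but physiologically shaped and
frozen as package defaults:

| parameter | default | rationale |
|---|---|---|
| speed of sound c | 1500 m s⁻¹ | soft-tissue convention |
| Grüneisen Γ | 0.2 | dimensionless scale; cancels in all analyses |
| digitizer dt | 1 ns (512 samples) | 7.5 µm gate = 5 samples at c |
| surface arrival | 50 ns | places the surface inside the record |
| transducer band | 6–36 MHz, Gaussian, zero phase | stated detector bandwidth |
| noise | 1.4 % of peak, /√1000 averaging | stated fluctuation level and averaging |
| water background | 100 cm⁻¹ per unit fraction, mild slope | yields an effective probing depth of order 100–150 µm |
| glucose bands | 994/1036/1080/1109 cm⁻¹, FWHM 25 cm⁻¹, 0.020/0.018/0.020/0.012 cm⁻¹ per mg dl⁻¹ | percent-level signal at physiological concentration; 994 least overlapped by interference |
| lactate bands | 1040/1125 cm⁻¹, 9 mg dl⁻¹ | physiological; a minor contributor |
| albumin | featureless sloping background, 2500–4000 mg dl⁻¹ | serum protein as smooth background |
| keratin bands | 1078/1240 cm⁻¹ (epidermis only) | amide III / C–O features overlapping the 1080 glucose band |
| lipid bands | 1165/1100 cm⁻¹ (epidermis only) | sebum esters overlapping 1080/1109 but not 994 |
| epidermis | 0–20 µm; water 0.22, keratin 0.55, lipid 0.15 | thin, relatively dry, glucose-poor |
| dermis | water 0.65, ISF glucose pool | hydrated bulk |
| capillary plexus | 97.5 ± 7.5 µm (15 µm band); water 0.90, blood glucose pool | vessel-targeted measurement volume |
| GTT | baseline 100 mg dl⁻¹, 2 g kg⁻¹ dose, +60 mg dl⁻¹ per g kg⁻¹, τ_rise 15 min, τ_decay 60 min | Bateman bolus peaking ~28 min post-injection at ~220 mg dl⁻¹ |
| ISF kinetics | lag 8 min (perivascular), 25 min (avascular), dilution 0.8 | diffusion-limited equilibration; see below |
| superficial drift | bounded random walk, ±10 % on epidermal water/lipid | humidity/sebum variation over the 160 min test |
| reference glucometer | multiplicative noise, CV 3 % | handheld-meter repeatability |

**Location-dependent ISF kinetics.** ISF near dense capillaries
equilibrates with blood quickly; ISF in capillary-poor tissue receives
glucose by diffusion from distant vessels and lags far behind. The
generator therefore integrates the first-order exchange
dG_i/dt = (G_b − G_i)/τ with τ = 8 min for the vascular location and
τ = 25 min for the avascular one (both diluted ×0.8). This asymmetry is
what makes the avascular point measurably worse than even the ungated
vascular readout: its spectra track a delayed, attenuated copy of blood
glucose, and no static calibration can undo the rise/fall hysteresis
(the best affine map from the 25-min-lagged ISF to blood has an
irreducible RMSE of ~26 mg dl⁻¹ over the test).

**Acquisition protocol.** Five baseline spectra over the 10 min before
injection and 45 spectra over the following 150 min per location, the
sensor alternating between the two locations (1.5 min per spectrum);
100 wavenumbers on the half-open [900, 1300) cm⁻¹ grid at 4 cm⁻¹ steps
(the half-open convention is what makes the count exactly 100).
Reference glucometer draws are slot-synchronized: one sample per
acquisition slot, taken 1.5 min after the first-location spectrum while
the stage moves — 50 references per test, every spectrum within the
1.5 min alignment tolerance. A plain fixed-interval reference grid
cannot simultaneously give 50 samples and cover the 160 min span.

## Signal processing

The envelope is |analytic signal| of the mean-removed trace. The
1/e² penetration depth is read from a bounded least-squares Gaussian
fit to the envelope as c·(center + 2σ − t_surface): the fitted curve
falls to peak·e⁻² at center + 2σ on the deep side. (A "width" reading
of 4σ would double-count the shallow side; the one-sided deep
convention matches how the depth annotates a probing range.) The fit
excludes the first/last 5 % of samples (analytic-signal edge
artifacts), initializes from the max/argmax/threshold-FWHM/first-decile
median, and reports an honest convergence flag; a σ pinned at its bound
marks a degenerate input.

The surface reference is configurable. A threshold rule (first sample
exceeding 5× the pre-signal noise s.d., `estimate_surface_time`) is
provided, but the end-to-end pipeline uses the surface-arrival time
carried in the dataset metadata: the zero-phase transducer model
spreads energy symmetrically *before* the true surface arrival, which
biases any pure onset-threshold estimate early, whereas the
trigger-to-surface delay of the instrument geometry is known in
practice.

Gates are half-open [start, end) in time or depth, so tilings never
double-count a sample; a per-gate spectrum is the envelope maximum
within the gate at each wavenumber.

## Calibration and gate optimization

"Mean scale" preprocessing is implemented as mean-centering of X
columns and y without variance scaling; an autoscaling flag exists
because the phrase admits both readings (default off). PLSR is
single-response NIPALS with deflation of X only — deterministic, no
random initialization; with the maximal number of latent variables the
training fit equals ordinary least squares, which the tests use as an
oracle (scikit-learn's PLSRegression serves as an independent
cross-check only). Leave-one-out cross-validation recomputes the
centering inside every fold; the latent-variable count is the smallest
whose RMSECV is within 2 % of the curve minimum (cap 10), recorded
per gate. Degenerate folds (constant retained y) predict the fold mean
with a warning.

The gate scan moves a 7.5 µm window in 7.5 µm steps over
[0, d_{1/e²}], with d estimated per dataset from the 1080 cm⁻¹
transients (the representative glucose wavenumber); window count is
⌊(range − w)/step⌋ + 1. Selection takes the RMSECV minimum, breaking
exact ties toward the deeper gate (consistent with rejecting
superficial layers) and flagging low confidence when the runner-up is
within 5 %. The "without skin rejection" baseline is a single gate
spanning the full accessible range. Spectrum–reference alignment is
nearest-reference within 1.5 min (the acquisition time), with linear
interpolation available as a flag.

## Error grid

The Parkes consensus grid for type-1 diabetes is embedded as a
versioned JSON asset of published boundary vertices over the
0–550 mg dl⁻¹ domain; zones are shapely polygons tested in increasing
risk order with boundary-inclusive containment, so points exactly on a
boundary take the lower-risk label. The narrative gloss "zone A is
within 20 % of reference" is not used as geometry — the vertex
coordinates govern. Type 2 (and the Clarke grid) are deliberate
extension points, not bundled. Below the identity line the type-1 grid
has no zone E, so maximal under-reading discordance lands in D. AUC
linearity integrates difference spectra trapezoidally on the native
wavenumber grid; requested peaks snap to the nearest grid point
(lower on ties; 994 → 992 on the default grid), recorded in the result.

## What the generator does and does not emulate

Emulated: depth-structured glucose contrast with a capillary layer near
100 µm; delayed/diluted ISF dynamics differing between vascular and
avascular sites; glucose-linear fingerprint bands; slowly varying
water/serum background; structured superficial interference drift;
band-limited detection; pulse-averaged noise; the full acquisition
protocol with alternating locations and a noisy reference series.

Not emulated: optical scattering and fluence inhomogeneity, 3-D
acoustics and diffraction, frequency-dependent acoustic attenuation,
motion and contact-coupling artifacts, inter-animal anatomical
variability beyond the seed-controlled drift/noise, laser wavelength
jitter, and any physiological glucose dynamics beyond the two-pool
bolus model. Passing tests therefore demonstrate that the *analysis*
recovers what this class of layered, drift-corrupted, band-limited data
contains — not that the instrument achieves these error levels in vivo;
simulated RMSECVs (≈5 mg dl⁻¹ gated) are accordingly optimistic
relative to animal recordings.

Two measured behaviours of the default conditions worth knowing:

- The per-gate RMSECV profile has a sharp basin at the capillary layer
  (5–7 mg dl⁻¹ against 13–19 elsewhere), but adjacent 7.5 µm gates
  within the basin differ by fractions of a mg dl⁻¹ — the acoustic
  resolution (≈30–45 µm at this band) genuinely limits single-gate
  localization, and the selected center wobbles by one gate around the
  truth across seeds.
- Increasing the superficial drift amplitude does *not* widen the
  skin-rejection advantage monotonically: the drift is spectrally
  structured (water/lipid shapes), so the calibration partially
  corrects it in superficial readouts, while its multiplicative shadow
  on deep signals is glucose-entangled. The advantage remains large
  (>5 mg dl⁻¹ in median) at every amplitude in the 0–20 % ladder, and
  the deep-gate error itself is insensitive to the ladder (<10 %
  spread).

## Numerical details

- Wavenumber grids are half-open `np.arange(low, high, step)`.
- The ISF lag ODE uses an exact exponential-integrator step with
  piecewise-linear blood on an internal grid (≤0.25 min), stable for
  any lag/step ratio including the lag → 0 limit.
- The window-count formula guards the float division with a 1e-9 slack
  so exact multiples (e.g. 142.5/7.5) are not truncated.
- Dataset tables are written with `%.17g` and read with pandas'
  round-trip float parser, so write → read is bit-exact.
- A single run seed fans out to stage-keyed substreams via
  `SeedSequence([seed, crc32(stage)])`; all derived seeds are < 2³¹.
- Pipeline reports separate a deterministic `payload` (identical across
  reruns of the same config and seed) from a `meta` section carrying
  wall-clock timings.

## Known limitations

- The depth estimator's Gaussian-fit convention is only meaningful for
  single-lump envelopes; strongly multi-modal envelopes (sharp slab
  boundaries, no smoothing) yield a fit centered on the dominant lump.
- LOOCV on a single glucose-tolerance-test time series shares the
  trajectory between folds; smooth confounders (drift) can leak into
  out-of-fold predictions, a property inherent to the design and
  documented by the duplicate-row test.
- The Parkes asset covers the type-1 variant only.
- `simulate_transient`'s noise is referenced to the per-call record
  maximum; records simulated together share one reference level.
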