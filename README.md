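# glucogate

Depth-gated mid-infrared optoacoustic glucose quantification: a tested,
reusable pipeline from raw optoacoustic transients to clinically scored
glucose predictions, together with a seed-controlled synthetic-experiment
generator that emulates in vivo glucose-tolerance-test recordings.

## The problem

Mid-IR spectroscopy can read glucose from its fingerprint absorption
bands (994, 1036, 1080 and 1109 cm⁻¹), but conventional optical
detection only probes the outermost, glucose-poor skin — stratum corneum
and epidermis — whose water, keratin and sebum content drifts over time.
Optoacoustic detection converts absorbed mid-IR pulses into ultrasound
transients, and the acoustic time-of-flight encodes *depth*. Gating the
Hilbert envelope of the transient to a narrow time window therefore
selects a skin layer; choosing the window that overlaps the capillary
plexus rejects the superficial interference ("skin rejection") and reads
blood rather than interstitial-fluid (ISF) glucose.

The pipeline implements that analysis end to end:

1. **`simulate`** — layered-skin Beer–Lambert forward model:
   p₀(z) = Γ μₐ(z) exp(−∫₀ᶻ μₐ), mapped to time by the speed of sound,
   band-limited to the transducer's 6–36 MHz passband, pulse-averaged
   noise, glucose-tolerance-test dynamics (Bateman blood bolus,
   first-order ISF lag), superficial water/lipid drift, and a noisy
   reference glucometer series.
2. **`signals`** — Hilbert envelopes, Gaussian fits, the 1/e²
   penetration depth c·(t_center + 2σ − t_surface), and half-open
   time/depth gates with per-gate spectra (envelope peak per wavenumber).
3. **`pls`** — mean-centered single-response PLSR (NIPALS) with
   leave-one-out cross-validation (RMSECV) and parsimonious
   latent-variable selection; exploratory PCA.
4. **`gating`** — scan a 7.5 µm window in 7.5 µm steps across the
   accessible depth range and select the RMSECV-minimizing gate.
5. **`errorgrid`** — Parkes consensus error grid (type 1), zone
   tabulation, RMSE/Pearson, difference-spectrum and single-peak
   linearity analyses.

## Worked example

```python
import numpy as np
import glucogate as gg

ds = gg.simulate_experiment(seed=1)          # one simulated GTT, two locations
res = gg.DepthGateModel(ds, "P1").fit()      # scan gates at the vascular point
print(res.summary())
```

```
Depth-gated glucose quantification — location P1
==============================================================
accessible depth range      0 – 109.0 um
window / step               7.5 / 7.5 um
selected gate               [97.5, 105.0) um
RMSECV with skin rejection      5.25 mg/dl (n_lv=2)
RMSECV without (bulk gate)     15.62 mg/dl (n_lv=3)
low-confidence selection    False
==============================================================
```

The scan recovers the generator's capillary layer (centered at 97.5 µm):
cross-validated error at the selected gate is ~3× smaller than a single
gate spanning the whole accessible range, because the deep gate rejects
the drifting superficial layers. Scoring the gated predictions on the
Parkes grid:

```python
from glucogate.errorgrid import pceg_report
rep = pceg_report(res.y, np.clip(res.gated_cv.predictions, 0, 550))
print(rep.summary())
```

```
Parkes error grid (parkes-t1), n = 50
  zone A:   50  (100.00%)
  ...
  RMSE: 5.25 mg/dl
```

The same analysis is available from the shell:

```bash
glucogate run --seed 1 --out out/
# P1: gate [97.5, 105.0) um, RMSECV 5.1 (SR) vs 13.2 (bulk) mg/dl, zone A 100% (SR) vs 96%
# P2: gate [7.5, 15.0) um, RMSECV 28.7 (SR) vs 28.7 (bulk) mg/dl, zone A 66% (SR) vs 66%
```

plus the individual verbs `simulate`, `depth-profile`, `gate-spectra`,
`gate-scan`, `quantify` and `evaluate`, each reading/writing plain CSV +
JSON artifacts.

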