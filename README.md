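# graphomotor

Online-handwriting analysis for Parkinson's disease dysgraphia (PDYS)
detection.

PDYS — slow, tremulous, shrinking handwriting — is one of the earliest
motor signs of Parkinson's disease, and a digitizing tablet captures it
noninvasively: pen position *x*[*n*], *y*[*n*], timestamps, the binary
on-surface/in-air pen state *b*[*n*], axial pressure, and the pen's
tilt and azimuth angles. `graphomotor` implements the full analysis
pipeline for such recordings, for researchers in digital biomarkers and
movement-disorder signal analysis:

* **I/O and preprocessing** — SVC-style plain-text pen recordings with
  configurable column order, device-unit normalisation (counts → mm,
  ticks → s), FIR-antialiased resampling to a uniform 133 Hz grid, and
  segmentation into alternating on-surface/in-air strokes.
* **Handcrafted features** — the conventional battery: temporal (DUR,
  DURR, SDUR, SDURR), spatial (WIDTH, HEIGHT, LEN and per-stroke
  variants), kinematic (VEL, AVEL, ACC in xy/horizontal/vertical
  projections, on-surface and in-air), dynamic (PRESS, TILT, AZIM),
  spiral-specific (tightness, smoothness, degree of severity DoS,
  precision index SPI, …) and event counts (interruptions,
  self/inter-stroke crossings, profile-change rates). Series are
  aggregated by median, iqr, ncv = iqr/median, Theil–Sen slope, and —
  for kinematics — the 95th percentile, under the naming convention
  `INF:DIR-FN(HL)`, e.g. `ON:V-VEL(95p)`.
* **Offline images + deep features** — the on-surface trace rendered to
  a 224×224 image (nearest-neighbour, aspect-preserving letterbox) and
  embedded by a pluggable frozen backbone: a seeded random-projection
  extractor by default, an ImageNet-pretrained VGG16 wrapper (last
  conv block, global-average-pooled) when torch is available.
* **Evaluation scenarios** — PD/HC classifiers (XGBoost for handcrafted
  features, L2 logistic regression for deep features) tuned by
  randomized search on balanced accuracy, BACC = (SEN + SPE)/2, under
  nested stratified 5×5 cross-validation, in three multilingual
  scenarios: single language (SL), leave one language out (LOLO), and
  all languages combined (ALC), plus top-10 feature-importance reports.
* **Synthetic cohorts** — a generator of multilingual PD/HC cohorts
  with tunable deficit sizes (bradykinesia, 4–7 Hz tremor,
  micrographia, reduced pressure, extra pen lifts) and a null mode, so
  the entire pipeline is testable without clinical data.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from graphomotor import (EffectProfile, NEUTRAL_PROFILE,
                         extract_feature_vector, simulate_spiral)

pd_rec = simulate_spiral(EffectProfile(velocity_scale=0.6, tremor_amp=1.0,
                                       pressure_scale=0.8), seed=1)
hc_rec = simulate_spiral(NEUTRAL_PROFILE, seed=2)
pd_fv, hc_fv = extract_feature_vector(pd_rec), extract_feature_vector(hc_rec)
for name in ("DoS", "SPI", "PRESS(median)", "ON:AVEL(median)"):
    print(f"{name:18s} PD={pd_fv[name]:8.3f}  HC={hc_fv[name]:8.3f}")
```

prints

```
DoS                PD=   0.012  HC=   0.001
SPI                PD=   0.979  HC=   0.998
PRESS(median)      PD= 409.684  HC= 512.684
ON:AVEL(median)    PD=   0.152  HC=   0.089
```

The tremulous PD spiral deviates ~12× more from its ideal fitted spiral
(DoS), has a lower precision index (SPI), and shows the reduced pen
pressure injected by the profile. Running the scenario layer on a
30-subject-per-language cohort with the same deficits
(`examples/04_evaluate_scenarios.py`) prints

```
scenario language    bacc_fmt     sen_fmt     spe_fmt
      SL       CZ 0.93 ± 0.16 0.97 ± 0.11 0.90 ± 0.32
    LOLO       US        1.00        1.00        1.00

top features in the single-language model:
  0.29  1stSm
  0.28  ON:VEL(iqr)
  0.13  2ndSm
```

i.e. balanced accuracy near 1 within and across languages (the injected
deficit is language-invariant), driven by spiral smoothness and
velocity-variability features.

The `examples/` directory has one short script per capability:
simulation, feature extraction, rendering + deep features, scenario
evaluation, and the raw SVC I/O pipeline.

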