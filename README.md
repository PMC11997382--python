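# nirscmd

Block-design fNIRS motor-imagery analysis for detecting covert command
following (cognitive motor dissociation, CMD) in behaviorally unresponsive
patients.

The package implements the full analysis chain as a tested, reusable
pipeline:

1. **`nirscmd.montage`** — acquisition constants (63 channels, 703/808/850 nm,
   11 Hz, 3 cm separation), the 10-region channel map, and the 300 s
   block-paradigm schedule (50 s baseline, five 20 s task + 20 s rest blocks,
   50 s post-baseline).
2. **`nirscmd.simulate`** — synthetic cohorts with known ground truth:
   double-gamma hemodynamic responses planted on motor-region channels of
   responders, physiological noise (cardiac ~1.1 Hz, respiratory ~0.25 Hz,
   ~0.1 Hz vasomotor waves, low-frequency drift), motion artifacts and
   high-variability channels, mapped to 3-wavelength intensities through the
   same Beer-Lambert forward model the preprocessor inverts.
3. **`nirscmd.preprocess`** — coefficient-of-variation channel screen
   (reject CV > 15%), optical-density conversion, sliding-window motion
   artifact correction with cubic-spline de-trending (SD multiplier 6,
   amplitude threshold 0.5 OD), 0.01–0.1 Hz zero-phase band-pass, and the
   modified Beer-Lambert concentration solve (DPF 6.0).
4. **`nirscmd.features`** — ROI averaging, −5..40 s epoching, baseline
   correction, block averaging, and seven features (mean, peak, variance,
   median, peak-to-peak, skewness, kurtosis) per chromophore from the
   5–20 s windows after the task and rest commands.
5. **`nirscmd.classify`** — per-region RBF-SVM trained on healthy controls,
   (C, γ) searched by a real-coded genetic algorithm with grouped 20-fold
   cross-validation, a 120-subset feature-combination search, and the
   per-patient response decision from the two predicted labels.
6. **`nirscmd.cmdstats`** — confusion matrix against the behavioral
   reference, CMD identification (reference-negative responders), GOS-E
   outcome dichotomization (≥ 4 favorable), exact two-sided Fisher tests by
   integer enumeration, and Bonferroni-corrected pairwise prognosis
   comparisons.

`nirscmd.pipeline.run_synthetic_study` wires all stages end to end;
`nirscmd.snirf` reads/writes SNIRF (HDF5) recordings and CSV side-cars.

## CLI

```bash
nirscmd simulate --n-hc 10 --n-vs 5 --n-mcs-minus 5 --n-mcs-plus 5 \
    --cmd-fraction 0.2 --seed 1 --out data/
nirscmd preprocess --in data/HC001.snirf --out hb.csv --qc-out qc.csv
nirscmd features --in-dir data/ --out features.csv
nirscmd train --features hc_features.csv --roi all --seed 1 --out models/
nirscmd predict --model models/LPMC.json --features features.csv \
    --rule strict --out predictions.csv
nirscmd stats --predictions predictions.csv --metadata data/metadata.csv \
    --roi LPMC --out report.json
```

## Notes

* Extinction coefficients for HbO/HbR at 703/808/850 nm ship as a versioned
  JSON table (`nirscmd/data/extinction_hb.json`); the simulator and the
  inverse solve share it, so round trips are exact by construction and the
  table choice affects absolute scaling only.
* All randomness flows from explicit seeds through splittable generators;
  simulation without a seed is refused.
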