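# dsaflow

Dynamic digital-subtraction-angiography (DSA) radiomics for venous
thrombosis risk stratification, exercised end-to-end on synthetic
moving-thrombus phantoms with known ground truth.

The package implements:

- **phantom** — synthetic 2D+t angiographic sequences: an opacified vein
  with an oscillating/translating thrombus (filling defect), a bolus
  transit delay across the thrombus, late-opacifying collateral channels,
  noise/drift, plus seeded synthetic feature/outcome cohorts. All
  generating parameters are returned as ground truth.
- **preprocess** — baseline subtraction, Gaussian denoising, intensity
  normalization, steady-opacification windowing, and a classical
  threshold + connected-component thrombus/lumen segmentation proxy.
- **optical_flow** — from-scratch Horn–Schunck dense optical flow
  (brightness constancy + α²-weighted smoothness, Jacobi averaging
  iterations; optional incremental warping for ~1 px/frame motions).
- **kinematics** — displacement vectors, displacement velocity (mm/cycle,
  path length over cycle windows), oscillation angle θ (principal
  displacement axis vs vessel axis, folded into [0°, 90°]) and strain rate
  (Frobenius norm of the symmetric velocity-gradient tensor).
- **hemodynamics** — time–intensity curves, contrast transit time Δt,
  pressure-gradient surrogate ΔP = κ·Δt (κ = 1.05 mmHg/s), mean flow
  velocity, normalized venous quantitative flow ratio (vQFR ∈ [0, 1]),
  collateral counting with the >50 %-bypass rule and the collateral flow
  index CFI = N/L.
- **stratify** — threshold flags with frozen boundary semantics
  (velocity ≥ 2.1 mm/cycle, θ > 45°, vQFR ≤ 0.80, CFI > 0.3,
  D-dimer > 5.0 µg/mL, Wells bands 0–1/2–6/≥7), a transparent logistic
  score fusion and high/low stratum assignment.
- **stats** — ROC/AUC (Mann–Whitney, ties half), DeLong's test, Youden
  threshold, diagnostic metrics, relative risk with Katz CIs,
  Hosmer–Lemeshow calibration, decision-curve analysis, seeded bootstrap
  CIs.
- **pipeline / cli** — an end-to-end feature-extraction pipeline
  (TIFF + JSON sidecar in, feature CSV out, per-case error quarantine,
  config-hash provenance) and reporting.

## CLI

```sh
dsaflow simulate sequence --config cfg.yaml --out out/        # phantom TIFF + sidecars
dsaflow simulate cohort --n 200 --seed 1 --out cohort.csv     # synthetic cohort
dsaflow extract --inputs out/ --out features/                 # imaging -> feature CSV
dsaflow stratify --features cohort.csv --out assessed.csv     # flags, score, stratum
dsaflow evaluate roc --data scored.csv                        # also: delong, rr,
dsaflow evaluate rr --events-a 7 --n-a 87 --events-b 17 --n-b 81   # calibration, dca
dsaflow report --features f.csv --assessments a.csv --outcomes o.csv --out rep/
```

Conventions: row-major pixel grids, origin top-left; axis angles in
degrees from the +x (column) axis toward +y (rows); physical units mm, s,
mmHg; the "cycle" of mm/cycle is the configurable `frames_per_cycle`.
The vQFR normalization (`reference_ratio`, default 10 (mm/s)/mmHg) and the
fusion weights in `dsaflow.stratify.DEFAULT_WEIGHTS` are documented
package conventions, calibratable on synthetic cohorts via
`fit_risk_weights`.

## Tests

`tests/` holds unit + property tests per module and
`tests/test_acceptance.py` with one test family per acceptance criterion:
printed-count arithmetic, optical-flow translation recovery (< 0.25 px),
kinematic parameter recovery on a phantom grid (velocity within 15 %,
θ within 5° at 5 % noise), transit-time recovery within one frame period,
exact collateral counting, statistics oracles (brute-force pair counting,
exhaustive Youden scan, seeded bootstrap determinism) and frozen threshold
boundaries.
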