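# marbench

Task-based assessment of CT metal-artifact-reduction (MAR) algorithms.

Metal implants (dental fillings, cochlear and deep-brain stimulator
hardware) corrupt CT projection data through beam hardening and photon
starvation, producing streaks that can hide low-contrast lesions.  Vendors
ship MAR algorithms, but there is no standard, reproducible way to say
whether a given MAR actually helps the clinical task.  `marbench`
implements a fully simulated, seed-reproducible framework that answers a
concrete question: *how does applying MAR change a model observer's
ability to detect a low-contrast signal near metal?*  It is aimed at
imaging scientists and algorithm developers who need quantitative,
task-based evidence rather than image-fidelity metrics or reader scores.

## What it does

1. **Phantom** — a head-like digital object: bone skull, water brain, a
   rotatable inset with a random Gaussian-lump texture, 12 teeth with iron
   fillings, two cochlear and two deep-brain iron implants, and an
   optional disk signal at the center whose attenuation is
   `a × 1.05 × μ_water`, `a ∈ [1.00, 1.06]`, replacing the local
   background.
2. **Acquisition** — polychromatic parallel-beam projection under a
   bundled 120 kVp spectrum with Poisson counting noise, a constant
   scatter floor and Gaussian readout noise; negative-log transform with a
   photon-starvation clip.
3. **Reconstruction** — FBP with a Ram-Lak filter, plus two classical
   sinogram-inpainting MAR variants: **MAR 1** segments metal in the
   sinogram by a fixed log-attenuation threshold; **MAR 2** segments the
   image in HU, forward projects the metal mask, and inpaints the flagged
   bins.  Thresholds are calibrated once at mid-range conditions and
   frozen — deliberately, so the framework can detect when that breaks.
4. **Observer** — a channelized Hotelling observer on ten dense
   difference-of-Gaussians channels over a centered ROI:

       w = Σ̄⁻¹ Δμ̂,   t = wᵀv,
       SNR² = (t̄₂ − t̄₁)² / ½(σ₁² + σ₂²),   AUC = Φ(SNR/√2).

5. **Learning-curve extrapolation** — resubstitution (biased high) and
   hold-out (biased low) AUC over a grid of training sizes N_T ("antler
   plot"), extrapolated by OLS in 1/N_T to the infinitely trained AUC∞
   with error ε = √(ε_b² + ε_v²) from the arm gap (bias) and repetition
   scatter (variance).

The deliverable per study is a *detectability curve*: AUC∞ ± ε per
reconstruction method as a function of signal amplitude or dose.

## Worked example

```bash
python examples/03_observer_antler.py
```

simulates 60 images per class at signal amplitude 1.05 and calibration
dose, and prints the antler arms and extrapolation for plain FBP and
MAR 2:

```
  fbp  NT= 25  resubstitution 0.803  hold-out 0.597
  fbp  NT= 35  resubstitution 0.774  hold-out 0.608
  fbp  NT= 45  resubstitution 0.761  hold-out 0.611
  fbp  AUC_inf = 0.669 +- 0.045 (bias 0.039, variance 0.021)
  mar2 NT= 25  resubstitution 0.951  hold-out 0.877
  mar2 NT= 35  resubstitution 0.941  hold-out 0.891
  mar2 NT= 45  resubstitution 0.943  hold-out 0.892
  mar2 AUC_inf = 0.923 +- 0.014 (bias 0.008, variance 0.012)
```

Read it like this: at every training size the resubstitution AUC is above
the hold-out AUC (the finite-sample bias brackets); as N_T grows the two
arms converge, and their common intercept at 1/N_T → 0 estimates the
infinitely trained observer.  Here the image-domain MAR lifts the
detectability of the 5 %-contrast signal from AUC∞ ≈ 0.67 to ≈ 0.92 —
the kind of statement the framework exists to support.  (Numbers are from
a 60-image demo run with seed 0; the full study uses 200 images per class
and a wider N_T grid.)

Other examples: `01_phantom_and_projection.py` (phantom, beam hardening),
`02_mar_comparison.py` (streak energy of FBP vs MAR 1 vs MAR 2),
`04_detectability_study.py` (end-to-end YAML-configured study).  A thin
CLI wraps the two shell-level entry points:

```bash
marbench run --config study.yaml --out results/
marbench mar --method mar1 --threshold 7.3 --in sino.h5 --out img.tif
```

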