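# Methods

`marbench` measures what a metal-artifact-reduction (MAR) algorithm does to
a clinically meaningful quantity — the detectability of a low-contrast
lesion near metal implants — rather than to image fidelity or subjective
appearance.  Everything is simulated, end to end, under explicit seeds.

## Phantom

A 2-D head-like object assembled from disks and Gaussian lumps (all of
which have analytic Radon transforms):

| element | geometry | attenuation |
|---|---|---|
| skull (outer disk) | r = 12 cm at (0,0) | cortical bone |
| brain (inner disk) | r = 10 cm | water |
| rotatable inset | r = 5.9 cm | 1.05 × water + lump texture |
| teeth | 12 disks r = 0.7 cm on an arc | bone (configurable) |
| dental fillings | r = 0.2 cm at the tooth centers | iron |
| cochlear implants | r = 0.6 cm at (±11, 0) | iron |
| deep-brain implants | r = 0.3 cm at (±1, −5.1), rotate with the inset | iron |
| signal (optional) | r = 0.5 cm at the origin | a × 1.05 × water, a ∈ [1.00, 1.06] |

The inset carries N = 20 Gaussian lumps
`μ_i exp(−π|r − r_i|²/w_i²)` with widths `w_i = 1.3 + 2R` (R standard
normal, clamped at 0.2 cm), centers uniform in `|r_i| < 4.9` cm, and
amplitudes `μ_i = 0.015 μ_water R'` with `R'` uniform on (−1, 1).  The
percent-scale amplitude puts the background variability on the same scale
as the 0–6 % signal contrast; a texture with order-unity water-equivalent
swings would bury every signal amplitude in the study range and compress
the whole detectability axis to chance.  The composite water-equivalent
map is clamped at zero to stay physical.

The signal *replaces* the local background (a removable rod in a physical
phantom): inside the signal disk the lump texture is suppressed and the
attenuation is exactly `a × 1.05 × μ_water(E)`.  Each acquisition rotates
the inset (lumps + deep-brain implants) to a fresh uniform angle; one lump
realization is shared across a study (the physical-phantom convention),
with `resample_lumps` available to redraw it per image.

The production projection path rasterizes per-material thickness maps and
projects them discretely; the analytic per-primitive Radon transforms are
retained as test oracles (the signal's background replacement and the
inset-edge truncation of the texture have no closed form).

## Acquisition model

Parallel-beam geometry, `n_views` angles over [0, π), odd `n_bins` so the
central bin sits on the rotation axis.  Detected counts per bin:

    counts = Poisson( I0 · Σ_E S(E) · exp(−Σ_m μ_m(E) L_m) )
           + Poisson(s0) + Normal(0, σ_r)

with `S(E)` the bundled 120 kVp spectrum (Kramers bremsstrahlung with
2.5 mm Al filtration, 1 keV grid), `μ_m(E)` log-log-interpolated from
bundled tables for water / cortical bone / iron, `s0` a **constant**
scatter mean per bin (independent of the tube output — this is what makes
the log-value ceiling `ln(1 + I0/s0)` dose-dependent), and σ_r = 5 photons
of electronic readout noise.  The log sinogram is
`−ln(max(counts, 1)/(I0 + s0))`; the clip at one count handles photon
starvation behind metal, and the flat field includes the scatter so an air
scan normalizes to zero exactly.

Reconstruction is classical FBP: Ram-Lak (band-limited ramp, no
apodization) filtering at the detector pitch followed by pixel-driven
backprojection with linear interpolation.  Forward projection is
ray-driven (Joseph) with bilinear sampling at one-pixel steps; both
kernels are numba-compiled.  Against the analytic Radon oracle the
discrete projector is accurate to <1 % of the sinogram maximum on a
lump-only phantom at a 1024 grid, and FBP recovers the attenuation
coefficient of a noiseless monochromatic water disk to <0.1 %.

## MAR variants

Both are sinogram inpainting — corrupted bins replaced by 1-D linear
interpolation along the detector within each view (edge runs take the
nearest value) — differing only in segmentation:

* **MAR 1**: threshold the log sinogram directly.
* **MAR 2**: threshold the FBP image in HU (HU reference: the
  spectrum-weighted mean of μ_water(E)), dilate the metal mask by one
  pixel (the standard guard against partial-volume erosion; without it
  grazing rays of the true metal trace escape the forward-projected
  trace), forward project it, and flag bins whose metal path exceeds half
  a pixel.

Thresholds are calibrated **once**, at the mid-range condition (amplitude
1.03, calibration dose), on noiseless scans, and then frozen — the
deliberate fragility whose consequences the framework is built to detect.
The MAR 1 threshold is placed just above the brightest metal-free log
value plus a 3-σ Poisson guard: the value ranges of grazing metal rays and
of metal-free rays through the full teeth arc overlap intrinsically, so
any sinogram threshold must trade missed grazing bins against destroyed
clean bins; the operator keeps the clean bins.  The MAR 2 threshold is the
midpoint between the 99.9th percentile of the metal-free HU image and the
minimum HU over the (edge-eroded) true metal pixels — image domain
separates metal cleanly, which is exactly why MAR 2 outperforms MAR 1.

## Observer and figure of merit

From each reconstruction a centered ROI covering ~6.1 cm is vectorized
(row-major) into g; ten dense difference-of-Gaussians (DDOG) channels
`C_j(ρ) = exp(−½(ρ/(Qσ_j))²) − exp(−½(ρ/σ_j)²)`, `σ_j = σ0 α^j`
(σ0 = 0.005 cycles/pixel at full scale, α = 1.4, Q = 1.67) reduce it to
v = Uᵀg.  The channelized Hotelling observer uses w = Σ̄⁻¹Δμ̂ with the
equal-weight pooled class covariance; the test statistic t = wᵀv is
treated as binormal:

    SNR² = (t̄₂ − t̄₁)² / ½(σ₁² + σ₂²),      AUC = Φ(SNR/√2).

The √2 is forced by consistency: with SNR defined as above, only
Φ(SNR/√2) equals the Mann–Whitney (rank) AUC for Gaussian statistics, and
the suite verifies the two agree to <0.005 at 10⁵ samples per class.  No
internal channel noise is added.

Finite ensembles bias the AUC: resubstitution (test on the training set)
is biased high, hold-out is biased low.  Both are computed over a grid of
training sizes N_T with 50 random subset repetitions each ("antler plot"),
each arm is fit by OLS against 1/N_T, and the mean intercept is the
infinite-training estimate AUC∞ with

    ε_b = |intercept_resub − intercept_holdout| / 2,
    ε_v = sd(per-repetition AUC∞) / √reps,     ε = √(ε_b² + ε_v²).

Repetitions share one ensemble, so ε understates the true uncertainty;
the procedure reports it anyway as its defined error bar.

## Problem sizes and presets

The `full` preset mirrors the reference layout (512×512 images over a
26 cm FOV, 720 views × 729 bins, 121×121 ROI, 1000 images/class, dose
1e6 per bin per view, s0 = 100).  The default working scale — used by the
test-suite, the acceptance script and the examples — is the `desk` preset:
128×128 images, 180 views × 185 bins, 257-pixel raster, 31×31 ROI (the
same 6.1 cm), 200 images/class, N_T ∈ {25, 50, 100, 150}, 50 repetitions.
Channel frequencies scale with the pixel ratio (σ0 = 0.02 cycles/pixel)
so the channels sit on the same physical frequencies.  The dose axis is
in arbitrary per-bin-photon units, so the desk calibration point is set to
8e6 with s0 = 800 (scaled together, preserving the log-domain compression
structure of the full-scale point while landing the observer mid-range),
and the desk dose sweep {8e5, 1.2e6, 1.4e6, 8e6} brackets the
frozen-threshold failure of MAR 1: at 8e5 the scatter ceiling
ln(1 + I0/s0) ≈ 6.9 sits below the threshold and the metal mask is
deterministically empty (MAR 1 silently equals FBP); at 1.2–1.4e6 the mask
is sparse and noise-driven, and MAR 1 falls below FBP; at 8e6 it covers
the corrupted cores and MAR 1 clearly helps.

## What the simulation does and does not show

The generator reproduces the mechanisms that matter for the task — beam
hardening, photon starvation, a scatter floor, rotating-implant streak
randomness, textured backgrounds — but not fan/cone geometry, detector
crosstalk, focal-spot blur, or 3-D partial volume.  At desk scale the FBP
observer is dominated by the dose-independent streak variability of the
rotating deep-brain implants, so its absolute AUC (~0.55–0.67 across the
amplitude grid) sits below a full-scale study's, and the MAR-vs-FBP
separations are wider; the *orderings* (image-domain > sinogram-domain >
none at calibration; sinogram-domain collapsing under dose change) are the
reproducible content.  Absolute reconstructed μ values are
implementation-relative (the energy grid, spectrum and interpolation
scheme are package choices), so comparisons are internal, never absolute
HU.

## Numerical choices and degenerate inputs

Log-log attenuation interpolation is exact at knots and monotone between
them; queries outside [10, 150] keV are errors.  Rasterization uses
pixel-center sampling with strict Euclidean inside tests; ties cannot
occur off a measure-zero set.  Lump widths are clamped (not redrawn) to
keep the per-seed draw count fixed.  Inpainting of a fully masked view
raises (catastrophic segmentation should be loud, not silent).
Resubstitution with N_T equal to the whole ensemble bypasses subsampling
so repeated calls are bit-identical.  The antler grid is trimmed to
N_T < N (hold-out needs a nonempty test set) and needs ≥3 admissible
sizes.  All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; per-image streams are derived from
(master seed, class, image index), or (master seed, image index) in
paired mode.

## Known limitations

* 2-D only; no z-extent, one ROI per acquisition.
* The error model inherits the correlated-repetition underestimate.
* MAR 1's failure window is narrow in dose at desk scale (its AUC deficit
  vs FBP is ~0.01–0.02); detecting it needs the full 200-image ensembles.
* The CHO is a linear observer: background-texture *variance* differences
  between classes (signal replaces texture) are invisible to it except
  through the channel means, so the a = 1.00 floor sits only slightly
  above 0.5.
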