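# Methods

This note records the model, the numerical choices, what the synthetic data
emulate (and what they do not), and the study conditions used by the test
suite and by `scripts/acceptance.py`.

## Signal model and objective

Each voxel contains complex water W and fat F sharing a single effective
decay R2\* (1/s) and a static off-resonance Φ (Hz). For echo time tₙ the
image-space factor is `exp((2πiΦ − R2*)·tₙ)`; the fat spectral dephasing
D(t) = Σₚ aₚ·exp(2πi fₚ t) is evaluated at the **per-sample readout time**,
not the echo time, which deconvolves the off-resonant blurring of fat along
radial spokes. A bipolar readout makes per-sample times direction-dependent;
even echoes traverse the spoke (and time) in reverse.

The data term is the summed squared residual over coils, echoes and samples.
Gradients are analytic: with A = Gᴴr the adjoint-gridded residual and
B = Gᴴ(D̄ r),

* ∂/∂W̄-type complex gradient: 2·conj(C·a)·A (and B for fat),
* ∂/∂R2\*: −2tₙ·Re[ conj(C·a·W)·A + conj(C·a·F)·B ],

where a is the echo factor. All are verified against central finite
differences (relative error < 1e−4 over three step decades).

The ℓ1-TV penalties are smoothed, `sqrt(|d|² + ε)`, so the whole objective
is differentiable for L-BFGS; ε is (1e−6 × map dynamic range)², evaluated at
initialization per map family. Spatial TV is anisotropic with Neumann
boundaries; temporal TV differences along the respiratory-bin axis only
(non-circular). R2\* nonnegativity is enforced by the bound constraint of
L-BFGS-B (the projected variant scipy provides); an exponential
reparameterization `R2* = exp(ρ)` sits behind
`ReconConfig(r2s_parameterization="exp")`.

Stopping: `max_iter` (default 100) or relative cost change below 1e−6.
The optimizer balances variables with the R2\* scale factor
‖∂cost/∂W‖₂/‖∂cost/∂R2\*‖₂ computed once at initialization (the R2\*
gradient carries one more amplitude factor than the W gradient, so the
factor scales inversely with data amplitude; k-space is first normalized to
unit median spoke energy, which pins the factor's scale and makes the
paper-style regularization weights meaningful for this package's data).

## NUFFT

Kaiser–Bessel gridding with oversampling 2.0, kernel width 6, β from the
Beatty closed form. Conventions (the single source of truth): image pixels
at r = (i − N/2)/N FOV units; k in cycles/FOV; forward transform
s(k) = Σ x(r)e^{−2πik·r}. Interpolation coefficients are precomputed per
trajectory into a sparse matrix and reused across coils, echoes and solver
iterations; the adjoint is the exact conjugate transpose (inner-product test
< 1e−6). Density compensation for display/initialization is Ram-Lak (∝|k|)
with the center sample at the equivalent radius 1/4, scaled per spoke by its
angular Voronoi gap (golden-angle spokes are not equispaced), and calibrated
so a uniform disk reconstructs with unit mean. The alias-free region of
radial sampling is the inscribed FOV circle; accuracy statements for gridded
reconstructions refer to that disk.

## Trajectory and calibration

Golden-angle increment 180°·2/(1+√5) (exact irrational value). Echo n is
rotated by (n−1)·1.5° after the bipolar direction flip (composition order is
a config choice; blips reset per view). Gradient delays displace each spoke
along its own traversal direction; per-echo shifts are estimated from
10 calibration lines per polarity along ±kx/±ky by cross-correlating
opposing polarities. The sub-sample lag uses the Fourier phase-slope of the
two line transforms (exact for band-limited lines; a coarse cross-correlation
seeds the integer part), and the even-length index reversal contributes a
known one-sample offset: lag = 1 − 2s. Estimated shifts enter the gridding
coordinates; timing is unchanged.

## Initialization (field map)

Water/fat separation needs a Φ estimate before the fit. Per voxel, the
variable-projection residual of the two-compartment model is evaluated on a
discretized (Φ, R2\*) grid (Φ over ±1/(2ΔTE) in 121 steps, R2\* over
0–300 1/s in 13 steps) built from density-compensated NUFFT echo images.
Spatial smoothness comes from a confidence-ordered region-growing pass that
picks, for each voxel, the local residual minimum closest to its labelled
neighbours; a three-point parabola refines Φ below the grid step. This is a
deliberately simple smoothness heuristic; it is validated by its swap rate
(≤ 5% of liver voxels at 40% PDFF over ten noise seeds), not by equivalence
to any particular discrete-optimization solver. Φ is **not** updated inside
the iterative fit — only W, F, R2\* are optimization variables.

For the motion-resolved and gated variants the initializer runs per
respiratory bin on that bin's own views. Each respiratory state carries its
own mean B0 offset (susceptibility shifts with diaphragm position); a field
map frozen at the motion-averaged state pushes that offset into R2\*
(≈ +20 1/s at ±12 Hz in phantom studies), which is exactly the bias the
motion-resolved reconstruction exists to remove.

## Reconstruction variants and defaults

* averaged: all views, spatial TV, λ = 0 by default (fully sampled data);
  8 virtual coils.
* xd: uniform-count amplitude binning (n_bin = 4), temporal TV with
  λ_W = λ_F = 0.4, λ_R2\* = 0.01, 4 virtual coils. These weights are
  order-of-magnitude choices tied to the unit-median-spoke-energy
  normalization, not transferable constants. The best frame minimizes the
  within-bin navigator variance (ties → lowest bin).
* gated: best frame only; `gated_mode="nufft"` reconstructs it with the
  initializer machinery (NUFFT + image-space separation),
  `gated_mode="model"` runs the model-based fit with λ = 0.

Coil sensitivities are estimated from density-compensated echo-1 coil
images by block-wise (8 px) dominant-eigenvector analysis of the smoothed
coil covariance, phase-referenced to coil 1 and normalized to unit RSS.
Coil compression is partition-wise PCA. Slices are independent after the
inverse FFT along kz; any slice order gives identical results.

## The phantom: what it emulates, and what it does not

A 2-D multi-compartment scene (FOV 256 mm): elliptical liver (defaults
PDFF 3.4%, R2\* 60.5 1/s — clinically used cutoff values), a water-only
vessel and a 20%-fat/95 1/s lesion inside it, a 90%-fat subcutaneous ring,
zero-signal background, a smooth linear+quadratic B0 (±60 Hz), water and
fat phase-aligned so the PDFF ground truth is exact by construction. Coils
are Gaussian-profile loops on a ring with smooth low-order phase. The 2-D
slice with a 64² or 48² grid keeps one full reconstruction in tens of
seconds on one CPU; the FOV was chosen so the 8 mm respiratory excursion
spans ≥ 1.5 pixels while organ-to-motion proportions stay realistic.

Respiration is a quasi-periodic surrogate (sinusoid, drifting sinusoid, or
irregular) driving

1. a rigid translation of the whole object (a per-view k-space phase ramp —
   exact for translation; because the ramp is applied to the coil-weighted
   signal, coils effectively move with the object, a good approximation for
   smooth desk-scale profiles), in-plane for single-partition data and along
   z for multi-partition self-gating studies; and
2. a respiration-correlated uniform B0 offset, default 1.5 Hz/mm of
   displacement — the scale of susceptibility modulation near the diaphragm
   at 3T. Phantom studies show the translation alone leaves the
   motion-averaged R2\* nearly unbiased at 4 mm pixels; it is the
   phase-inconsistency mechanism that elevates apparent R2\* (≈ +11 1/s at
   8 mm excursion), matching the qualitative in-vivo behaviour.

Not emulated: deformable motion, through-plane motion of a 3-D anatomy,
flow/pulsation, spatially varying susceptibility changes, streak sources
outside the FOV, T1 bias (low-flip-angle acquisition is assumed). Passing
phantom tests therefore demonstrates correctness of the operators and the
qualitative motion phenomenology, not in-vivo accuracy.

Maps hold per-pixel signal, so simulating on a 2× finer grid (the
inverse-crime control: same trajectory, phantom and coils built at 2N)
scales k-space amplitudes by 4; PDFF and R2\* are unaffected.

## Study conditions used by tests and the acceptance script

* Static recovery: 64², 400 views, 6 echoes (TE1 = ΔTE = 1.23 ms,
  1090 Hz/px), 8 coils, noiseless → liver-ROI PDFF within 0.5 pp, R2\*
  within 2 1/s.
* Motion bias: 48², 400 views, 8 mm sinusoidal excursion (80-view period),
  1% complex Gaussian noise, three seeds; ROI displaced to each frame's mean
  position. Averaged bias positive; |XD best-frame bias| smaller.
* Self-gating: 48², 160 views, 16 partitions, 8 coils, z-axis motion,
  irregular trace → |corr| > 0.95.
* Calibration: shifts in [−1, 1] samples at SNR 20 → error < 0.05 samples.

Desk-scale grids keep the full suite within a minutes-scale single-CPU run;
the trade-off is coarser pixels than the in-vivo protocol, which is why the
motion experiments quote biases in 1/s rather than reproducing in-vivo
regression slopes.

## Known limitations

* The magnitude-discrimination PDFF can dip slightly below 0 when noise
  puts F in phase opposition to W; the branch rule is applied exactly as
  defined rather than clipped.
* The navigator's 2-D fallback (center-sample magnitude) cannot see pure
  in-plane rigid translation of coil-weighted data (the DC sample is
  translation-invariant); 2-D motion studies therefore inject the known
  trace as the surrogate, while multi-partition data use the full z-profile
  navigator.
* The R2\* scale factor is computed once globally (not per bin).
* Φ is fixed during the iterative fit; residual field errors alias into
  R2\* (quantified in the initializer section).
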