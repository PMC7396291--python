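# starfat

Model-based water/fat separation with R2\* mapping for **free-breathing
multi-echo golden-angle stack-of-stars radial MRI**, plus a moving digital
liver phantom that makes the whole pipeline testable without scanner data.

## The problem

Hepatic fat (proton-density fat fraction, PDFF) and iron (via the effective
transverse relaxation rate R2\*) are quantified with multi-echo gradient-echo
MRI. Conventional Cartesian protocols need breath-holds; radial stack-of-stars
sampling allows free breathing, but respiratory motion mixes inconsistent
magnitude and phase into the echo train and artificially inflates R2\*.
`starfat` implements three reconstructions of the same radial data:

* **motion-averaged** — all views in one fit (spatial-TV regularization,
  zero by default on fully sampled data);
* **motion-resolved "XD"** — views sorted into respiratory bins from a
  self-gating navigator and reconstructed jointly with temporal TV along the
  bin dimension; the frame with the most consistent respiration signal is
  selected;
* **retrospectively gated** — only the best frame's views, via NUFFT +
  image-space separation or the model-based path.

## The model

For coil c and echo time tₙ the forward operator maps the complex water map
W, fat map F and shared decay R2\* to radial k-space,

    E(W, F, R2*)_{c,n} = FT( C_c e^{2πiΦtₙ} e^{−R2*tₙ} W )
                       + D_n · FT( C_c e^{2πiΦtₙ} e^{−R2*tₙ} F ),

with coil sensitivities C_c, field map Φ (Hz), and the six-peak fat
dephasing D evaluated at the **exact readout time of every k-space sample**
(FT is a Kaiser–Bessel gridding NUFFT). The maps solve

    argmin_{W,F,R2*} Σ_{c,n} ‖E(W,F,R2*)_{c,n} − Y_{c,n}‖₂²
        + λ_W‖S(W)‖₁ + λ_F‖S(F)‖₁ + λ_{R2*}‖S(R2*)‖₁

by L-BFGS with analytic gradients (verified against finite differences).
PDFF uses magnitude discrimination per voxel:
`PDFF = |F|/|F+W|` where `|F| ≥ |W|`, else `1 − |W|/|F+W|`.

## Worked example

```python
from starfat import (AcqParams, FatModel, ReconConfig, WaterFatRecon,
                     build_trajectory, make_coils, make_phantom, simulate_kspace)

truth = make_phantom(64)                      # liver PDFF 3.4 %, R2* 60.5 1/s
coils = make_coils(64, 8, seed=2)
traj = build_trajectory(AcqParams(n_read=64, n_proj=400, n_echo=6, fov_mm=256.0))
data = simulate_kspace(truth, coils, traj, FatModel.liver_6peak())

model = WaterFatRecon(data, ReconConfig(variant="averaged"))
result = model.fit()
print(result.summary())

roi = truth.liver_mask(erode=2)
print(f"liver PDFF {100 * result.pdff[roi].mean():.2f} %  "
      f"(truth {100 * truth.pdff_truth[roi].mean():.2f} %)")
print(f"liver R2*  {result.maps.r2s[roi].mean():.1f} 1/s (truth 60.5 1/s)")
```

prints:

```
Water/fat/R2* model-based reconstruction
================================================
variant            : averaged
grid               : 64 x 64
views used         : 400 / 400
coils (compressed) : 8
undersampling      : 0.25
iterations         : 100
final cost         : 10.0831
R2* scale factor   : 1.404e+05
PDFF (support)     : 44.27 % mean
R2* (support)      : 54.5 1/s mean
liver PDFF 3.54 %  (truth 3.40 %)
liver R2*  60.8 1/s (truth 60.5 1/s)
```

The support-wide means average the whole object, including the 90 %-fat
subcutaneous ring, so the liver ROI lines are the quantitative result:
PDFF recovered within 0.5 percentage points and R2\* within 2 1/s on this
noiseless phantom.
An undersampling value below 1 means the 400 views oversample the 64-pixel
base resolution (Nyquist needs 64·π/2 ≈ 101 spokes).

The same pipeline is available from the shell:

```bash
starfat simulate --config scenario.yaml --out raw.h5 --seed 1
starfat calibrate --raw raw.h5
starfat recon --raw raw.h5 --variant xd --out maps/
```

`recon` writes PDFF (%), R2\* (1/s) and |W|/|F| NIfTI volumes (per
respiratory bin for `xd`) and a JSON report with the cost trace, bin counts,
selected frame, estimated k-space shifts and the undersampling factor
(Nyquist spokes = base resolution × π/2).

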