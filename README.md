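# gbm4d

Projection-domain denoising for dynamic PET, built around a guided
block-matching and 4-D transform-domain collaborative filter (GBM4D),
together with everything needed to exercise it end to end: a dynamic-PET
simulator (compartment-model kinetics, Radon projection, Poisson counts),
2D-OSEM reconstruction, and image-quality / time-activity-curve evaluation.

## The problem

A dynamic PET study splits the acquisition into time frames so tracer
kinetics can be recovered per voxel, but each frame then holds only a
fraction of the photon counts and the per-frame sinograms are extremely
noisy. Denoising the *projections* (sinograms) before reconstruction is
attractive because there the noise really is Poisson, whereas after OSEM
reconstruction it is not.

## The method

Sinogram counts `z` are Poisson; the Anscombe transform
`f(z) = 2*sqrt(z + 3/8)` turns them into approximately Gaussian data with
unit variance. The filter then runs two collaborative-filtering passes per
slice, both guided by the **accumulated** sinogram (the sum over the
frames), whose relative noise is much lower than any single frame's:

1. **Guided matching.** For each reference position `x_R`, similar block
   positions are found on the guide image by thresholded-DCT (`Υ'∘T`)
   block distance `d(x_R, x) = ||Υ'(T Z_xR) − Υ'(T Z_x)||² / N²` with
   `d ≤ τ_match`. Matching on the guide rather than on single frames avoids
   the mismatching caused by the distance's `O(σ⁴)` estimator variance.
2. **4-D collaborative filtering.** The `N×N` blocks of every frame at the
   matched positions form an `N×N×|T|×|S|` group. Step 1 applies a
   separable orthonormal 4-D DCT and hard-thresholds at `λ_4D·σ`
   (`λ_4D = 2.8`); step 2 re-matches on the accumulated basic estimate and
   applies empirical Wiener shrinkage `W = |T(ŷ_basic)|² / (|T(ŷ_basic)|² + σ²)`.
3. **Aggregation.** Filtered blocks return to their positions and are
   combined by a weighted average (group reliability × 2-D Kaiser window).

The exact unbiased inverse of the Anscombe transform (closed form) maps the
result back to Poisson means, and each (frame, slice) sinogram is
reconstructed with 2D-OSEM,

    f_j ← f_j / (Σ_{i∈S_b} H_ij) · Σ_{i∈S_b} H_ij p_i / (H f)_i,

using a matched forward/backprojector pair that reproduces the
parallel-beam Radon transform of scikit-image exactly.

Evaluation follows the convention that ground truth is the reconstruction
of the *noiseless* sinogram: per-frame global SSIM (single-moment formula
with `c1 = c2 = 0.01²` on peak-normalized images), PSNR
(`20·log10(peak/RMSE)` dB), and TAC RMSE over 4×4×4-voxel VOIs.

## Worked example

```python
from gbm4d import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(seed=7, sim=SimConfig(size=64, n_slices=2, n_angles=64,
                                           total_counts=5e8 * 2 / 128 * (64 / 128) ** 2))
res = run_pipeline(cfg)
print(res.metrics.pivot(index="method", columns="frame", values="psnr_db").round(2))
```

simulates a 2-slice Shepp–Logan study (8 × 6-min frames, physical decay
only, Poisson noise at the volume-prorated photon budget), denoises it,
reconstructs the noisy / denoised / noiseless branches with OSEM
(20 iterations × 8 subsets) and prints, per frame, the PSNR against the
noiseless-sinogram reconstruction:

```
frame       1      2      3      4      5      6      7      8
method
gbm4d   32.07  32.58  32.58  32.98  32.93  32.75  32.79  32.42
noisy   18.47  18.24  17.80  17.80  17.77  17.54  17.31  17.11
```

The denoised branch gains ~15 dB over the undenoised reconstruction in
every frame (SSIM rises from ~0.78 to ~0.99). The same pipeline is
available from the shell:

```sh
gbm4d simulate --phantom shepp-logan --size 64 --slices 2 --frames 8 \
      --counts 1.5e6 --seed 7 --out sino.npz
gbm4d denoise --in sino.npz --out denoised.npz
gbm4d reconstruct --in denoised.npz --iterations 20 --subsets 8 --out recon.nii.gz
gbm4d run-all --phantom brain --seed 1 --out run/
```

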