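# dwisr — DWI super-resolution from highly sparse k-q space data

Diffusion-weighted MRI (DWI) trades spatial resolution against scan time:
each diffusion-encoding direction (a point in **q-space**) needs its own
k-space acquisition, so high-resolution multi-direction protocols are slow
and motion-sensitive. `dwisr` implements an end-to-end reconstruction chain
that recovers high-resolution DW images from **highly undersampled k-q
acquisitions**, for researchers prototyping sparse acquisition and
reconstruction strategies:

1. **Sampling design** — rotating PROPELLER blades (one single-shot blade
   per diffusion direction), Poisson-disc subsampling with a
   variable-density profile, partial-Fourier ("Hermitian-halved") masks,
   and radial masks.
2. **Low-resolution image formation** — NUFFT forward/adjoint (direct
   nonuniform DFT with an exact adjoint), zero-filling interpolation,
   Hermitian conjugate-symmetry completion, phase-constrained POCS for
   partial Fourier, and an iterative data-consistency cascade
   `x ← DC(refine(x))` with a pluggable refiner (total-variation by
   default). Because DW images from neighboring q-space directions are
   highly correlated, a composite reconstruction fills each direction's
   unsampled k-space with neighbor-blade data weighted by
   `cos²(q-space angle)`.
3. **Deformable registration** — blocks of pixels form a 4-neighbor graph;
   a minimum spanning tree is built over mean-absolute-difference edge
   costs and the discrete displacement labeling minimizing

   `E(w) = Σᵢ S(wᵢ) + κ Σ_(l,m) R(w_l, w_m)`

   (block SSD data term, squared label-difference regularizer) is solved
   *exactly* by two-pass dynamic programming on the tree, coarse-to-fine,
   with sub-voxel labels at the finest level. Accuracy is scored by the
   target registration error (TRE): the mean Euclidean distance between the
   forced and estimated displacement at landmark positions.
4. **Adversarial enhancement stages** — a sub-pixel-convolution SR
   generator (60×60×2 stacked LR frames → one 240×240 HR image), an
   8-convolution Wasserstein critic (no sigmoid, weights clipped to
   ±c = 0.01), an encoder–decoder deblurring generator with perceptual
   content loss (λ = 100), and a 3-D residual-encoder denoising pair for
   Rician magnitude noise (filter sequence 32-64-128-256-128-64-32-1,
   3×3×3 kernels) trained as a WGAN with gradient penalty. The composite SR
   objective is `l_MSE + 10⁻⁶·l_Gen + 0.001·RLT`, where RLT penalizes
   disagreement between registered neighbor frames and the target frame.
   Networks run on an in-package numpy autodiff core (twice-differentiable,
   so the gradient penalty trains through double backprop).
5. **Evaluation** — PSNR / SSIM / MSE with repeat aggregation, TRE, and a
   pipeline driver that runs the whole chain from one seeded config.

Everything runs at desk scale on generated phantoms: an analytic
Shepp–Logan and a diffusion-tensor phantom whose per-direction contrasts
follow `S = S₀·exp(−b gᵀDg)` over anisotropic tissue classes, so no
external data is required.

## Worked example

```bash
python examples/03_partial_fourier_and_cs_recon.py
```

```
partial Fourier (62.5% of samples): recovery PSNR 323.2 dB — machine-precision
exact for a real-valued object
25% sampling: zero-filled 18.46 dB -> DC cascade with TV refiner 21.74 dB
```

The first line is the partial-Fourier limit case: for a zero-phase object,
every removed k-space sample is the conjugate of a kept one, so Hermitian
completion is exact up to floating-point rounding (hundreds of dB). The
second line shows the compressed-sensing cascade recovering ~3 dB over
plain zero-filling at 25 % sampling.

```bash
python examples/06_full_pipeline.py
```

```
             recon: PSNR  32.05 dB  SSIM 0.871
  super_resolution: PSNR  21.91 dB  SSIM 0.442
sparsity-rate sweep:  20% -> 20.88 dB ... 100% -> 22.34 dB
```

Per-stage PSNR is measured against the known phantom; the sweep shows
end-to-end quality rising monotonically with the fraction of k-space
retained. `examples/04_registration_and_tre.py` recovers a forced nonrigid
deformation (TRE 1.86 → 0.71 voxels), and
`examples/05_toy_adversarial_training.py` trains the width-¼ denoiser for
40 steps (~1 min) with a ~4 dB held-out gain.

A thin CLI mirrors the library: `dwisr phantom|mask|recon|register|
evaluate|train|pipeline|fixtures` (see `dwisr --help`).

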