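# Methods

This note records the models, defaults, and design choices behind `dwisr`,
and what the synthetic tests do and do not establish about real scanner
data.

## Phantoms: the study conditions

**Shepp–Logan.** The analytic 10-ellipse head phantom in its
unit-intensity ("modified") parameterization, rasterized so that pixel
`N//2` lies exactly at the origin — the same convention as the centered
FFT grid. Intensities are the closed-form sum of ellipse deltas, in
[0, 1], with an exactly zero background.

**Diffusion-tensor stack.** Multi-direction DW contrast follows the
mono-exponential tensor model `S(g) = S0 · exp(−b gᵀDg)` on a tensor
field with three tissue classes derived from the Shepp–Logan geometry:
background (no signal), an isotropic compartment (D = 2.5·10⁻³ mm²/s · I,
CSF-like), and an anisotropic "fiber" compartment (λ∥ = 1.8·10⁻³,
λ⊥ = 0.3·10⁻³ mm²/s) whose principal axis rotates smoothly across the
image. Default b = 1000 s/mm², 8 directions quasi-uniform on the
hemisphere (golden-spiral; diffusion encoding is antipodally symmetric).
This reproduces the statistical property the reconstruction exploits —
image correlation decaying smoothly with q-space angle — without claiming
anatomical realism.

**Degradations.** Low-resolution formation is (optional motion) → Gaussian
blur → block-average decimation → noise, in that order. Decimation is
block-averaging rather than nearest-neighbor so the operator is a proper
anti-aliased downsampler. The noise level "25 standard deviations" is
interpreted on a 0–255 intensity scale; images are kept in [0, 1]
internally, so the default AWGN σ is 25/255 ≈ 0.098. That scale is a
configuration default, not a claim — the acquisition convention it refers
to is not fixed anywhere authoritative. Rician magnitude noise is
`sqrt((x+n₁)² + n₂²)` with iid Gaussian n₁, n₂; fixture volumes use
σ = 0.1 on the [0, 1] scale (≈ SNR 10, a typical DWI operating point).

**Deformations.** Nonrigid ground truth is a linear combination of
Gaussian radial basis functions (default 4 control points, bandwidth
max(H, W)/4), scaled to a requested peak displacement (default 3 voxels)
and checked against a finite-difference smoothness bound (default 0.5
voxels/voxel); affine deformations cover rotation plus sub-voxel shift.
The exact field is returned with the warped image, so registration error
is measurable everywhere. Warping is backward
(`warped(p) = image(p + field(p))`) with cubic interpolation and reflect
boundaries.

## Sampling

k-space coordinates live in cycles/FOV inside the half-open Nyquist box
[−0.5, 0.5); grids are 0-based with DC at index N//2, and the conjugate
mirror of index i is (−i) mod N in unshifted layout.

* **Blades** are strips of `lines_per_blade` parallel lines through the
  center, rotated in 180°/n increments (Cartesian lines are undirected, so
  180° suffices); samples rotated outside the Nyquist box are dropped.
  One blade per diffusion direction, angle (d·180/n) mod 180.
* **Poisson-disc** subsampling is dart throwing over a random permutation
  with an exhaustive distance check against the kept set; correctness (the
  min-distance invariant) is the contract, speed is not. The density
  profile maps normalized |k| to a relative rate; the default keeps a
  fully sampled core below 8 % of k-max and boosts high frequencies
  linearly (the exact high-frequency law is a config function). Locally
  the exclusion radius is r_min/√rate. If the target fraction is not
  reachable after bounded attempts, the call fails rather than silently
  under-sampling.
* **Partial Fourier** keeps `ceil(f·N)` rows: the self-conjugate extreme
  row plus a contiguous band running to the +k edge, so every removed
  point's Hermitian mirror is kept. Fractions ≤ 0.5 are rejected (the
  symmetric center band would be unrecoverable).
* **Neighbor schedule.** Angular distance on the q-sphere is
  arccos |g_d·g_n| (antipodal symmetry); the `neighbor_window` nearest
  directions form each direction's sharing set, ties resolved to the lower
  index.

## Reconstruction

All on-grid transforms are centered orthonormal FFTs. The NUFFT is a
direct nonuniform DFT evaluated in chunks — O(MN²) but exact, with an
adjoint that is the literal conjugate transpose (the adjoint-identity test
holds to ~10⁻¹⁶). At the matrix sizes this package targets (≤ 128²) the
direct transform is faster than setting up a gridding kernel, and its
exactness makes the operator contracts testable; density compensation is a
pre-weighting option on the adjoint, not part of the adjoint itself.

**Hermitian completion** fills each unsampled point with the conjugate of
its mirror when sampled, leaves it zero otherwise, and reports the
unrecoverable count. For real-valued (zero-phase) objects under a mask
with intact mirror coverage this is exact to floating point — the
partial-Fourier limit case.

**POCS partial Fourier** alternates the data projection (measured samples
restored) with a phase projection onto the smooth reference phase
estimated from the symmetric center band (default radius 12 % of k-max).
Both sets are convex, so the iterate-difference norms are non-increasing.

**Data-consistency cascade.** `x ← DC(refine(x))`, with DC replacing
measured k-space positions (weight 1 = hard replacement) and `refine` a
pluggable image-to-image operator applied to the real and imaginary parts
of the iterate; magnitude is taken only at the final output. The default
refiner is total-variation denoising (weight 0.02), the standard
sparsity prior for compressed sensing: at 25 % sampling it gains ~3 dB
over zero-filling on the Shepp–Logan. A plain Gaussian refiner is provided
for degenerate-case testing but documented as unable to beat zero-filling
(with hard DC it can only attenuate unmeasured content). Trained denoisers
plug into the same hook.

**Neighbor-direction composite.** For direction d the composite k-space
keeps its own blade data exactly and fills positions it does not sample
with neighbor-blade data weighted by cos² of the q-space angle, normalized
over contributors. On the 8-direction tensor phantom with one blade per
direction this gains ~2 dB mean PSNR over no sharing at window 2, more at
wider windows — the correlation-sharing premise, demonstrated rather than
assumed.

## Registration

Pixel blocks (default 6×6) are nodes of a 4-neighbor graph; edge costs are
mean absolute intensity differences between adjacent blocks, and a minimum
spanning tree is built by Kruskal with lexicographic tie-break (verified
against exhaustive Prüfer-sequence enumeration on small grids). Each node
takes a displacement label from a square grid (default range ±3 voxels,
step 1, refined to 0.5 at the finest pyramid level). The data term is the
block SSD under the candidate displacement; the pairwise term is the
squared Euclidean distance between neighbor labels, weighted by κ
(default 0.5). Both functional forms are package choices — picked for
convexity in the labels and testability; the block-size and κ defaults
were calibrated for worst-case landmark-error recovery over many simulated
deformations (regularization must be strong enough to extrapolate motion
into featureless regions, where it is otherwise unobservable). Labels are
enumerated in order of increasing magnitude so that cost ties (featureless
blocks) resolve to the smallest motion.

Inference is exact min-sum dynamic programming on the tree (leaf-to-root
messages, root-to-leaf argmin), verified against exhaustive enumeration
over all 27⁶ assignments on random 6-node trees. Regularization is
evaluated on tree edges, matching the optimizer (grid-neighbor evaluation
is available for reporting). Coarse-to-fine: at each pyramid level the
accumulated field is composed with the level's residual estimate, and the
update is kept only if it does not increase the full-resolution energy —
so the reported energy trace is non-increasing by construction.

TRE is the mean Euclidean distance between the forced and estimated
displacement vectors at landmark positions (bilinear field sampling; the
z-term is zero in 2-D). On ≤ 3-voxel RBF deformations of the 64²
Shepp–Logan the estimated field cuts TRE to ~30 % of the uncorrected
value.

## Networks and losses

The four architectures are built at a configurable width multiplier; the
printed channel counts hold at multiplier 1 and all tests run at ¼.

* SR generator: 9×9 head, 8 residual blocks (conv–BN–LeakyReLU–conv–BN
  with block skip), trunk skip, two ×2 sub-pixel convolution stages, 9×9
  tail, plus a global nearest-upsample skip from the mean of the stacked
  LR frames — residual learning, so training starts from the
  interpolation operating point. Contract: (H, W, 2) → (4H, 4W, 1).
* SR critic: 8 convolutions, channels doubling with depth, strides
  shrinking the maps, global average pool, single linear output, no
  sigmoid. The per-layer channel/stride table is a package default (only
  the count and trends are fixed externally).
* Deblur generator: 5-convolution encoder (strides 1,2,1,2,1), mirrored
  decoder using transposed convolutions, optional identity skip; input
  sides must be divisible by the total stride (4).
* Denoise pair: 3-D generator with filter sequence
  32-64-128-256-128-64-32-1, all kernels 3×3×3, conv → Leaky-ReLU → batch
  norm everywhere except the last stage (conv + Leaky-ReLU only),
  symmetric short connections between width-matched stages, and a global
  residual skip (the net predicts the noise residual); critic with three
  3-D convolutions (32/64/128) and a fully connected scalar.
* Perceptual extractor: a fixed-seed random convolution stack (frozen) —
  a documented surrogate carrying the defining property of perceptual
  losses (distances in a fixed nonlinear feature space); a loader hook
  accepts externally supplied pretrained weights, which are not bundled.
  An identity-kernel variant reduces the perceptual loss to pixel MSE for
  testing.

Loss weights, all in one audited record: clip bound c = 0.01, adversarial
weight 10⁻⁶, registration-consistency (RLT) weight ϱ = 0.001, deblur
content weight λ = 100, gradient-penalty ψ = 10 (no published value;
package default), denoise deltas (1, 0.1, 10⁻³) (no published values;
package defaults, logged in every run manifest). Composites are
accumulated in float64 so each total equals the weighted sum of its logged
components to machine precision. The SR composite is
`l_MSE + 10⁻⁶·l_Gen + ϱ·RLT` with `l_Gen = mean(D(SR) − D(HR))`; RLT sums
squared norms of registered-neighbor disagreement. Three adversarial
modes: `wgan_clip` (weights clamped to ±c after every critic step, 5
critic updates per generator step), `wgan_gp` (penalty
ψ·(‖∇_x̂D(x̂)‖−1)² on uniform interpolates, 1 critic update per generator
step, never clips), and `logistic`.

**Autodiff.** Without a deep-learning framework in the environment, the
networks run on an in-package reverse-mode autodiff core whose primitive
backward passes are themselves graph operations, making every network
twice differentiable — required because the gradient penalty's parameter
gradient backpropagates through an inner input-gradient (double
backprop). Convolutions lower to a cached gather plus one matmul;
transposed convolutions to zero-insertion scatter plus convolution with
the flipped, in/out-swapped kernel. Network compute is float32; loss
accumulation float64. Forward and double-backward passes are verified
against finite differences.

**Toy training.** The published optimizer setting (Adam, lr 10⁻⁵) is the
recorded default, but at desk scale (width ¼, ≤ 200 steps, 16³ volumes /
64² SR pairs, batch 2) that rate cannot move a fresh network; both toy
runs use lr 10⁻³ (denoise: WGAN-GP, 40 steps; SR: weight clipping, 200
steps — higher rates train faster but are not stable across seeds at this
scale). With the residual skips, training starts at the identity /
interpolation baseline and the MSE-dominated composites improve from
there: the denoiser gains ~4 dB over the noisy input on held-out volumes,
the SR generator ~0.3–2.5 dB over nearest-neighbor upsampling depending on
the seed. These runs demonstrate that the losses, penalties, and loops
train the published architectures end to end — not that desk-scale
training reaches publication-scale quality.

## Pipeline

One seeded config drives phantom → degradation → sampling → LR
reconstruction (DC cascade + optional neighbor sharing) → denoise →
register → deblur → super-resolve → evaluate. Default scale: 128² HR
phantom, 8 directions, ×4 SR (32² LR), sizes chosen so the full sweep runs
in seconds. Enhancement stages default to analytic operators (Gaussian
denoiser, unsharp-mask deblurring, cubic-resize SR) with trained-network
checkpoints pluggable; registration aligns every direction to the first.
Whether registration runs before or after denoising is configurable
(default: denoise first); nothing authoritative fixes the order.
Sparsity-rate sweeps use a nested variable-density mask family (one
priority ordering shared across rates), so higher rates strictly add
samples and the PSNR-vs-rate trend is well defined; with a fixed phantom
and seed the end-to-end PSNR is non-decreasing across
{20, 40, 60, 80, 100} %. Every run writes a config-hash manifest and
byte-identical metrics JSON under the same (config, seed).

## Numerical choices and degenerate inputs

* Centered FFTs (orthonormal); magnitude only at final outputs.
* Zero-fill factor ∈ {1, 2}; amplitudes rescaled so aligned samples
  reproduce the original exactly.
* PSNR peak defaults to the reference maximum; identical images report an
  infinite PSNR, serialized as null + flag. SSIM: 7-pixel window,
  constants from the peak.
* Gradient-penalty norms add 10⁻²⁴ inside the square root; below float64
  resolution, so the unit-norm-critic zero-penalty identity is preserved.
* Empty neighbor sets with incomplete coverage warn and fall back to
  own-blade data; label range 0 returns the identity field with its
  energy; infeasible Poisson-disc targets raise.

## Limitations

* Phantoms are 2-D single-coil magnitude objects with smooth synthetic
  motion; no off-resonance, eddy currents, coil sensitivities, or
  anatomical microstructure. Passing tests establish operator correctness
  and the qualitative behavior of the method, not clinical performance.
* The direct NUFFT is O(MN²) and intended for desk-scale grids.
* Desk-scale adversarial training shows trainability, not converged image
  quality; the analytic pipeline stages stand in for fully trained
  networks by default.
* The registration energy is minimized exactly on the spanning tree, not
  on the full grid graph; grid-neighbor energies are reported but not
  optimized.
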