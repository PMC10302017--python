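"""Reconstruct from sparse k-space: Hermitian completion of a half-Fourier
acquisition (exact for zero-phase objects) and the data-consistency cascade
with a total-variation refiner on an undersampled acquisition."""

import numpy as np

from dwisr import (
    KSpace,
    PhantomSpec,
    ReconConfig,
    SamplingMask,
    dc_cascade_recon,
    hermitian_fill,
    make_shepp_logan,
    partial_fourier_mask,
    psnr,
)
from dwisr.recon import fft2c, ifft2c, tv_refiner
from dwisr.sampling import nested_mask_family

sl = make_shepp_logan(PhantomSpec(matrix_size=64))

# half-Fourier acquisition: 62.5 % of rows, conjugate symmetry fills the rest
pf = partial_fourier_mask(SamplingMask(mask=np.ones((64, 64), bool)), 0.625)
k = fft2c(sl) * pf.mask
rec = np.abs(ifft2c(hermitian_fill(KSpace(values=k, support=pf), pf).values))
print(f"partial Fourier (62.5% of samples): recovery PSNR "
      f"{psnr(rec, sl, peak=1.0):.1f} dB — machine-precision exact for a "
      f"real-valued object")

# compressed-sensing style: 25 % variable-density mask, TV-regularized DC loop
mask = nested_mask_family(64, [0.25], seed=1)[0.25]
k = fft2c(sl) * mask.mask
zf = np.abs(ifft2c(k))
cs = dc_cascade_recon(KSpace(values=k, support=mask), mask,
                      ReconConfig(n_dc_iterations=10, denoiser_hook=tv_refiner(0.02)))
print(f"25% sampling: zero-filled {psnr(zf, sl, peak=1.0):.2f} dB -> "
      f"DC cascade with TV refiner {psnr(cs, sl, peak=1.0):.2f} dB")
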