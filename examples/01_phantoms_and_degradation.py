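"""Build the test objects: a Shepp-Logan slice and a multi-direction DWI
stack, then degrade one direction to a low-resolution noisy acquisition."""

import numpy as np

from dwisr import (
    DegradationSpec,
    PhantomSpec,
    degrade_to_lr,
    make_dwi_phantom,
    make_shepp_logan,
)

sl = make_shepp_logan(PhantomSpec(matrix_size=256))
print(f"Shepp-Logan: {sl.shape}, intensities [{sl.min():.2f}, {sl.max():.2f}]")

stack = make_dwi_phantom(PhantomSpec(name="dwi_tensor", matrix_size=64,
                                     n_directions=8, b_value=1000.0, seed=0))
g = stack.q_vectors
c01 = np.corrcoef(stack.images[0].ravel(), stack.images[1].ravel())[0, 1]
ang01 = np.degrees(np.arccos(abs(g[0] @ g[1])))
print(f"DWI stack: {stack.images.shape}, b = {stack.b_value:.0f} s/mm^2")
print(f"directions 0-1 are {ang01:.1f} degrees apart; image correlation {c01:.3f}")
print("  (nearby q-space directions give highly correlated contrasts —")
print("   the redundancy that neighbor-direction sharing exploits)")

deg = DegradationSpec(blur_sigma=1.0, downsample_factor=4, noise_sigma=25 / 255)
lr = degrade_to_lr(stack.images[0], deg, seed=0)
print(f"degraded direction 0: {stack.images[0].shape} -> {lr.shape} "
      f"(blur sigma 1 px, 4x decimation, AWGN sigma 25/255)")
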