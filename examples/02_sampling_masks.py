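"""Design k-q sampling patterns: PROPELLER blades with one blade per
diffusion direction, Poisson-disc subsampling, and a partial-Fourier half."""

import numpy as np

from dwisr import (
    kq_schedule,
    partial_fourier_mask,
    poisson_subsample,
    propeller_blades,
    radial_mask,
)
from dwisr.sampling import blades_to_mask, min_pairwise_distance

n = 64
blades = propeller_blades(n_blades=8, lines_per_blade=12, samples_per_line=n,
                          grid_size=n)
union = blades_to_mask(blades, n)
print(f"8 blades of 12 lines on a {n} grid: union covers "
      f"{100 * union.fraction_sampled:.1f}% of k-space")

sched = kq_schedule(n_directions=8, neighbor_window=2)
print(f"blade angles (deg): {np.round(sched.blade_angles, 1).tolist()}")
print(f"q-space neighbors of direction 0: {sched.neighbors[0]}")

pd = poisson_subsample(n, target_fraction=0.1, r_min=2.0, seed=0)
print(f"Poisson-disc mask: fraction {pd.fraction_sampled:.3f}, "
      f"min pairwise distance {min_pairwise_distance(pd):.2f} px (>= r_min = 2)")

pf = partial_fourier_mask(union, 0.625)
print(f"partial Fourier at 62.5%: union fraction {union.fraction_sampled:.3f} "
      f"-> {pf.fraction_sampled:.3f} (Hermitian mirror recoverable)")

rm = radial_mask(n_lines=60, aperture_deg=90.0, grid_size=n)
print(f"radial mask, 60 projections in a 90-degree aperture: "
      f"fraction {rm.fraction_sampled:.3f}")
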