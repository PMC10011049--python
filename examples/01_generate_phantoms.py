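"""Generate a small cohort of synthetic phantoms and inspect their anatomy.

Each phantom is a brain-like ellipsoid with two dark cavities and a thin
bright curvilinear target inside each; the printed numbers show that the
target occupies a fraction of a percent of the volume and that its volume
varies across subjects (which later makes volume-correlation statistics
meaningful).
"""

import numpy as np

from chpseg import PhantomParams, generate_cohort

pairs = generate_cohort(5, PhantomParams(shape=(96, 96, 96)), seed=42)
for i, (vol, mask) in enumerate(pairs):
    n = int(mask.grid.sum())
    frac = 100.0 * n / mask.grid.size
    target_mean = vol.grid[mask.grid == 1].mean()
    print(f"subject {i}: target {n:5d} voxels ({frac:.3f} % of the volume), "
          f"mean target intensity {target_mean:.2f}")
print("\nTarget volumes differ across subjects while staying sparse — the "
      "regime in which a coarse-to-fine cascade pays off.")
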