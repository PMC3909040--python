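"""Generate a synthetic BOLD cohort with planted midbrain-caudate coupling.

Builds the default phantom (18 x 24 x 10 grid, 1.8 x 1.8 x 3.45 mm voxels),
a 16-subject two-session cohort (8 low / 8 high working-memory span,
placebo vs bromocriptine counterbalanced), and simulates five-minute runs
(150 timepoints, TR = 2 s) in which a slab of caudate voxels carries an
inverted-U correlation pattern with the midbrain seed over the four
drug-by-span cells.
"""

import numpy as np

from midbrainfc import (
    EffectSpec,
    balanced_cohort_design,
    make_phantom_geometry,
    simulate_cohort,
)

geometry = make_phantom_geometry()
design = balanced_cohort_design(n_low=8, n_high=8, rng_seed=42)
effect = EffectSpec()  # r per cell: 0.1 placebo/low, 0.5 drug/low, 0.5 placebo/high, 0.1 drug/high

runs, truth = simulate_cohort(geometry, design, effect, n_timepoints=150,
                              tr=2.0, rng_seed=42)

print(f"phantom grid {geometry.shape}, voxel {geometry.voxel_size} mm")
for name in ("midbrain_seed", "caudate_headbody", "caudate_tail",
             "white_matter", "csf"):
    print(f"  {name}: {geometry.region_size(name)} voxels")
print(f"simulated {len(runs)} runs "
      f"({len(design.subject_ids)} subjects x 2 sessions), "
      f"{runs[0].n_timepoints} timepoints each")
print("planted caudate classes:",
      {c: int(truth.mask(c).sum())
       for c in ("dopaminergic_invertedU", "connected_constant", "null")})
print("seed couplings per design cell:",
      {k: round(v, 3) for k, v in truth.couplings["a_cells"].items()})
# The couplings are solved so the population seed-voxel correlation equals
# the planted r of each cell; larger coupling = stronger connectivity.
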