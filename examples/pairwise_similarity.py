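"""Gromov-Wasserstein lower-bound comparison of two isosurface shapes.

Compares a small and a large dipole field: 100 points are sampled on each
signed isosurface, the TLB lower bound on the Gromov-Wasserstein distance
between the point clouds is computed, and the procedure repeats to build
the distance histogram used by the clustering stage.
"""

import numpy as np

from epsim import (dh_potential_grid, gw_lower_bound, gw_upper_bound,
                   pair_histogram, pairwise_distances, sample_surface_points,
                   signed_isosurfaces)
from epsim.synthetic_data import make_archetype_structure

surfaces = {}
for name, scale in (("small", 6.0), ("large", 14.0)):
    s = make_archetype_structure("dipole", scale, label=name)
    surfaces[name] = signed_isosurfaces(dh_potential_grid(s))

rng = np.random.default_rng(0)
a = pairwise_distances(sample_surface_points(surfaces["small"]["+"], 100, rng))
b = pairwise_distances(sample_surface_points(surfaces["large"]["+"], 100, rng))
for kind in ("SLB", "FLB", "TLB"):
    print(f"{kind}: {gw_lower_bound(a, b, kind):.3f} A")
print(f"coupling upper bound (identity pairing): {gw_upper_bound(a, b):.3f} A")

hist = pair_histogram(surfaces["small"], surfaces["large"],
                      ("small", "large"), n_points=100, n_reps=100, seed=0)
print(f"\nrepeated subsampling ({hist.n_reps} reps): "
      f"mean {hist.samples.mean():.3f} A, sd {hist.samples.std():.3f} A")

self_hist = pair_histogram(surfaces["small"], surfaces["small"],
                           ("small", "small"), n_points=100, n_reps=100, seed=0)
print(f"self-comparison baseline:            "
      f"mean {self_hist.samples.mean():.3f} A, sd {self_hist.samples.std():.3f} A")

# The lower bounds measure how differently distances are distributed inside
# the two shapes (0 for congruent shapes).  The cross-pair mean sits far
# above the self-comparison baseline, which reflects pure subsampling noise.
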