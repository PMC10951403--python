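"""Build a labelled texture/scramble image set and summarize its statistics.

Generates four procedural texture families (20 exemplars would be the full
design; 8 keep this demo fast), phase-scrambles each exemplar, computes the
740-coefficient Portilla-Simoncelli statistics vector per image, reduces each
statistics group by PCA, and measures the normalized texture-scramble
distance per family in the 2-D energy subspace — the quantity that predicts
which families are hard to tell from their scrambles.
"""

import numpy as np

from texgeom.psstats import compute_ps_statistics, reduce_statistics, stat_cluster_geometry
from texgeom.synth import make_full_image_set

imgs = make_full_image_set(n_exemplars=8, rng_seed=11, size=64)
print(f"image set: {len(imgs)} images "
      f"({len(imgs.families)} families x 8 exemplars x texture/scramble x 2 rotations)")

stats = [compute_ps_statistics(im) for im in imgs]
print(f"statistics per image: {len(stats[0])} coefficients in groups",
      {g: len(getattr(stats[0], g)) for g in ("marginal", "spectral", "linear_cc", "energy_cc")})

reduced = reduce_statistics(stats)
print("retained variance per group (<= 8 PCs):",
      {g: round(v, 2) for g, v in reduced.explained_variance.items()})

pts = reduced.matrix[:, reduced.group_blocks["energy_cc"]][:, :2]
man = imgs.manifest()
print("\nnormalized texture-scramble distance in the 2-PC energy subspace:")
for fam in imgs.families:
    m = (man.family == fam).to_numpy()
    geom = stat_cluster_geometry(pts[m], man.stim_class[m].to_numpy())
    print(f"  {fam:10s} {geom.distances[('scramble', 'texture')]:.2f}")
print("(small distance = the family's higher-order structure barely differs"
      " from spectrally matched noise)")
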