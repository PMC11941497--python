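"""Quantify the proliferation gradient around hair follicles.

Bins gated basal cells into half-open distance-to-follicle groups,
prints the mean BrdU per group (rapid cyclers dilute their label, so the
near-follicle group should be dimmest), and verifies that the
label-retaining cluster keeps its distance.
"""

import numpy as np

import epidermap as em
from epidermap.spatial import kde_integral

ds = em.generate_dataset(n=2000, pattern_strength=1.0, seed=1)
res = em.analyze_dataset(ds, seed=1)
g = res.gated

grouping = em.bin_by_hf_distance(g)
print("distance-to-follicle groups (µm), mean marker intensities:")
print(grouping.summary.round(2).to_string(index=False))
low = grouping.summary.set_index("group")["mean_brdu"].idxmin()
print(f"\nlowest mean BrdU in group {low}: cells within 100 µm of a follicle "
      "cycle fastest and have diluted their label most.")

c3 = g.loc[g["cluster"] == 3]
print(f"\ncluster-3 (label-retaining) cells: n={len(c3)}, "
      f"min distance to follicle = {c3['dist_hf'].min():.0f} µm "
      "(planted exclusion zone is 750 µm).")

xg, yg, dens = em.kde_density(g["dist_hf"], g["brdu_mean"])
print(f"BrdU-vs-distance KDE integral: {kde_integral(xg, yg, dens):.3f} "
      "(a proper density integrates to 1).")
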