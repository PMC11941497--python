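"""Discover the four proliferation archetypes from a synthetic section.

Runs the full analysis (geometric covariates, basal filter, BrdU/Ki67
gating, double-negative removal, k selection, k-means, archetype
matching) and prints the k-selection diagnostics, the per-cluster
profile, and how well the recovered labels agree with the planted truth.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import epidermap as em

ds = em.generate_dataset(n=2000, pattern_strength=1.0, seed=1)
res = em.analyze_dataset(ds, seed=1)
model = res.model

print("k selection (WSS elbow vs mean silhouette):")
for k in sorted(model.silhouette_by_k):
    marker = " <- chosen" if k == model.chosen_k else ""
    print(f"  k={k}: WSS={model.wss_by_k[k]:8.0f}  silhouette={model.silhouette_by_k[k]:.3f}{marker}")
print(f"elbow suggests k={model.elbow_k}, silhouette k={model.silhouette_k}; "
      f"joint policy takes k={model.chosen_k}")

gated = res.gated
profile = em.cluster_space_profile(gated)
print("\nper-cluster profile (archetype-matched labels):")
print(profile.summary.round(2).to_string(index=False))
print("  cluster 3 = label-retaining (high BrdU, thin epidermis);")
print("  cluster 4 = large nuclei in thick (rete-ridge) epidermis.")

ari = adjusted_rand_score(gated["true_archetype"], gated["cluster"].astype(int))
print(f"\nadjusted Rand index vs planted archetypes: {ari:.3f} "
      "(1.0 would be perfect recovery)")
print(f"thickness omnibus across clusters: {profile.thickness_test.test_name}, "
      f"p = {profile.thickness_test.p_value:.2e}")
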