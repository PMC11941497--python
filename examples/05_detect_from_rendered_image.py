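"""Segment nuclei from a rendered image and compare to ground truth.

Renders a sparse synthetic section to a multi-channel image, runs the
classical detector (Otsu + watershed), and matches detections to the
generator's ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

import epidermap as em
from epidermap.datatypes import TissueParams

params = TissueParams(section_length=1500.0, hf_positions=(), pixel_size=0.5)
ann = em.generate_tissue_geometry(params)
ds = em.generate_nuclei(
    ann, em.default_archetypes(), n=50, pattern_strength=0.0, seed=7,
    params=params, min_separation=16.0,
)
img, mask = em.render_section_image(ds, params=params)
print(f"rendered image: {img.shape[0]} channels, {img.shape[1]}x{img.shape[2]} px")

labels, table = em.detect_nuclei_simple(img, pixel_size=params.pixel_size)
print(f"detected {len(table)} objects (ground truth: {len(ds.nuclei)})")

offset = np.array([ds.nuclei.centroid_x.min() - 20, ds.nuclei.centroid_y.min() - 20])
tree = cKDTree(table[["centroid_x", "centroid_y"]].to_numpy() + offset)
d, idx = tree.query(ds.nuclei[["centroid_x", "centroid_y"]].to_numpy())
matched = (d < 2.0).sum()
print(f"matched within 2 µm: {matched}/{len(ds.nuclei)} "
      f"(median centroid error {np.median(d):.2f} µm)")
corr = np.corrcoef(table.iloc[idx]["area"], ds.nuclei["area"])[0, 1]
print(f"area correlation detected vs planted: r = {corr:.2f} — the classical "
      "detector is adequate on clean synthetic renders.")
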