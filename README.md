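# epidermap

Quantitative analysis of proliferation patterning in the epidermal basal
layer from per-nucleus microscopy measurements.

## The problem

The interfollicular epidermis renews from proliferating keratinocytes in
its basal layer, and their cycling behaviour is spatially organised:
slow-cycling, label-retaining cells (high retained BrdU after a pulse)
sit in the thin inter-ridge regions far from hair follicles, while
rapidly dividing progenitors concentrate near follicles and large,
actively cycling nuclei occupy the thick rete ridges.  `epidermap` turns
per-nucleus measurement tables (the export dialect of QuPath-style image
analysis: centroids, area, circularity, per-channel Min/Median/Mean/SD/Max
intensities) and tissue annotations (basement membrane, epidermal
surface, follicles, as GeoJSON) into that spatial story:

1. **Geometric covariates** — per-nucleus distance to the basement
   membrane `d_bm`, to the epidermal surface `d_s`, and to the nearest
   follicle `d_HF`; the per-nucleus epidermal-thickness proxy
   `T = d_bm + d_s` (large `T` ⇔ rete-ridge position); exclusion of
   upper-layer nuclei (`d_bm` above a cutoff); invagination/evagination
   categories from a per-section median split of `T`.
2. **Marker gating** — BrdU+/Ki67+ calls by Otsu thresholding of
   `log(1 + I_mean)` (a two-component Gaussian mixture and manual cutoffs
   are available); BrdU−/Ki67− double negatives are removed.
3. **Cluster discovery** — k-means on the standardized feature vector
   `(log BrdU_mean, log Ki67_mean, area, circularity)`, with the cluster
   count chosen jointly by the Elbow rule (maximal second difference of
   the within-cluster sum of squares) and the Silhouette rule (maximal
   mean silhouette `s(i) = (b_i − a_i)/max(a_i, b_i)`); clusters are given
   stable identities by matching their median z-profiles against the four
   archetype signatures.
4. **Spatial statistics** — half-open distance-to-follicle groups with
   per-group intensity and composition summaries, 2-D kernel-density maps
   of BrdU against follicle distance, per-cluster thickness profiles, and
   marker contrasts between invaginations and evaginations.
5. **Statistics** — a four-test normality battery (Shapiro–Wilk, KS,
   D'Agostino–Pearson, Anderson–Darling) gating one-way ANOVA + Tukey HSD
   vs Kruskal–Wallis + Dunn (Bonferroni); Dixon's Q outlier test; Pearson
   correlation; Welch/Student t-tests.

Because raw imaging data of this kind is rarely shareable, the package
ships a first-class **synthetic-epidermis generator** that plants the
full structure — an undulating basement membrane (rete ridges), follicle
capsules, and four nucleus archetypes with known feature distributions
and spatial rules — so the whole pipeline can be exercised and scored
against ground truth, including a regeneration time-course (PG40 → PG110)
in which the spatial pattern switches on gradually.

It is intended for quantitative biologists analysing basal-layer
proliferation from immunofluorescence sections, and for method developers
who need a ground-truthed benchmark for niche-mapping pipelines.

## Worked example

```bash
python examples/02_cluster_discovery.py
```

prints (abridged):

```
k selection (WSS elbow vs mean silhouette):
  k=3: WSS=    2998  silhouette=0.389
  k=4: WSS=    1855  silhouette=0.475 <- chosen
  k=5: WSS=    1596  silhouette=0.447
elbow suggests k=2, silhouette k=4; joint policy takes k=4

per-cluster profile (archetype-matched labels):
 cluster   n  fraction  median_thickness  median_dist_hf  mean_brdu  mean_ki67
       1 607      0.35            194.20          495.45      44.97      55.27
       2 495      0.28            192.20          928.06      54.77      55.93
       3 283      0.16            163.10         1296.74     247.86      88.63
       4 358      0.21            234.84         1005.02      55.26     124.78

adjusted Rand index vs planted archetypes: 0.965
```

Four clusters are recovered: cluster 3 (high BrdU, median thickness
163 µm, median follicle distance 1297 µm) is the label-retaining
population in thin inter-ridge epidermis far from follicles; cluster 4
(large nuclei, thickness 235 µm) occupies the rete ridges; clusters 1–2
spread uniformly and differ in nuclear shape.  The adjusted Rand index
scores the recovered labels against the generator's hidden truth.

The other examples cover simulation and file export (`01`), the
follicle-distance gradient (`03` — mean BrdU is lowest within 100 µm of a
follicle, and no label-retaining cell is seen closer than 750 µm), the
regeneration time-course (`04`), and nuclei detection from rendered
images (`05`).  A thin CLI exposes the same stages
(`epidermap simulate | ingest | run | demo | spatial`).

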