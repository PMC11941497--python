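# Methods

## Coordinate and measurement conventions

All coordinates are micrometres in the image convention (origin top-left,
y increasing downward, i.e. toward the dermis).  Intensities are
arbitrary fluorescence units; every analysis step is invariant to their
scale after gating (log thresholding) and standardization (z-scores).
Circularity is `4πA/P²`; the detector estimates perimeter with the
Crofton formula, which keeps rasterized disks above 0.95 and 4:1 ellipses
below 0.6 across the sizes we render.

## Synthetic epidermis

### Geometry

A section is a strip of length `L` (default 12 mm — the scale of a
stitched panorama, and necessary to place 2000 basal nuclei at ~7 µm
spacing with room for both the follicle-proximal and follicle-remote
niches).  The basement membrane is `y(x) = A sin(2πx/λ)` sampled at ≤1 µm
(defaults `A` = 50 µm, `λ` = 500 µm); the epidermal surface is flat at
`y = −T₀` (`T₀` = 200 µm), so local epidermal thickness is `T₀ + A sin`,
ranging peak-to-peak over `2A`.  All relief is carried by the membrane
because the thickness covariate is what the analysis consumes.  Follicles
are vertical capsules of radius 60 µm crossing the membrane at
x = 1500/6000/10500 µm.  Invariants: `A ≥ 0`, `T₀ > 2A`, `λ > 0`.

### Placement

Nuclei are placed by Poisson-disk dart throwing along the membrane arc
(minimum centroid separation 4 µm, roughly the quasi-double-row packing
of basal nuclei) with the centroid offset toward the surface by
U(1, 8) µm — at most one nucleus diameter, so the default basal cutoff
retains everything the generator plants.  Requests beyond the packing
capacity raise an error naming the capacity.

### Archetypes

Four archetypes with mixture weights 0.35/0.30/0.15/0.20 (clusters 1–2
dominant).  Morphology: areas 40/25/40/60 µm² (SD 20%), circularity 0.90
(SD 0.04) for the round archetypes and 0.70 (SD 0.06) for the elongated
one.  Intensities are log-normal with natural-log parameters; the
label-retaining archetype's BrdU geometric mean sits `e^1.5` above the
low mode (log 5.5 vs 4.0, SD 0.2).  Qualitative Ki67 levels become
log-normal continua: "Low" at log 4.0 (SD 0.25), the label-retaining
archetype's variable level as one broad component at log 4.4 (SD 0.45),
the rete-ridge archetype at log 4.8 (SD 0.25).  Cell-cycle state varies
continuously, so we deliberately avoid planting discrete intensity
sub-modes inside an archetype: separability should come from the four
archetypes, not from artifacts of the generative mixture.  (Two-mode
Ki67 mixtures remain available through `ki67_high_weight`.)

Three further generative choices matter downstream:

- **Quiescent double negatives.**  Negativity is correlated within a
  cell: a `quiescent_frac` (0.18/0.18/0/0.12 per archetype) draws
  *background* intensity (log 2.0, SD 0.45) in both channels at once.
  These are exactly the cells the double-negative filter removes.  This
  models cells neither labelled at the pulse nor currently cycling, and
  it gives the intensity histograms a background class large enough
  (~15%) for a valley-seeking threshold to find.
- **Rapid-cycling tail.**  30% of archetype-1 cells are rapid cyclers:
  BrdU from a broad component at log 3.2 (SD 0.5) truncated above at the
  low-mode mean — label dilution can only reduce retained BrdU — and
  always Ki67-positive.
- **Truncated draws.**  Area and log-intensity draws are truncated
  symmetrically at ±2 SD (mean-preserving).  Nuclear features are
  biologically bounded; without the truncation, rare joint extremes
  (e.g. a rete-ridge nucleus at −3 SD area with +2.5 SD BrdU) read as
  label-retaining cells and blur the planted spatial exclusions.

### Spatial rules and the pattern dial

Each nucleus obeys its archetype's placement rule with probability
`pattern_strength`, else is placed uniformly.  Rules: archetype 3 prefers
membrane points below the median thickness and at least 750 µm from
every follicle boundary; archetype 4 prefers above-median thickness;
archetype 1's rapid tail is placed within 100 µm of a follicle; archetype
2 is uniform.  At `pattern_strength = 0` placement is uniform and the
thickness–archetype correlation vanishes.

### Time course

`generate_timecourse` emulates regeneration: PG40 has
`pattern_strength = 0`, relief scaled to 25%, and quiescence scaled to
50% (more cycling); PG75 is intermediate (0.5 / 60% / 75%); PG110 is the
full homeostatic state.  The three datasets share one deterministic seed
stream.  Early-timepoint quiescence is kept at half of homeostatic, not
lower, so the negative class stays resolvable by the gating method at
every timepoint.

### Rendering

`render_section_image` rasterizes each nucleus as an ellipse (axes solved
from area and circularity via the Ramanujan perimeter approximation,
random orientation) filled with its per-channel mean, blurred (σ = 1 px)
and overlaid with Gaussian background noise; the label mask is returned
as ground truth.  Rendering requires non-overlapping nuclei at the
configured pixel size (use a larger `min_separation` when generating
datasets intended for rendering).

### What the generator does not emulate

No suprabasal differentiation, dermal papillae or hair-cycle biology; no
staining vignettes, optical blur beyond the fixed kernel, or panorama
stitching seams; per-nucleus Min/Median/SD/Max are plausible ratios of
the drawn mean rather than products of a pixel-level model (only the
mean enters any analysis).  Passing tests therefore demonstrate that the
pipeline recovers the statistical and spatial structure it targets, not
that it is robust to every artifact of real sections.

## Pipeline choices

- **Basal filter**: `d_bm ≤ 15 µm` (≈ one basal-nucleus diameter) by
  default, configurable and logged; nuclei above it are flagged
  `excluded_upper`.
- **Relief categories**: per-section median split of the thickness proxy;
  ties and below-median go to evagination; parameter-free and robust to
  section-to-section thickness differences.  Constant-thickness sections
  are degenerate and warned about.
- **Follicle distance**: boundary distance to the nearest follicle
  polygon, 0 inside, NaN when a section has no follicles (then
  follicle-distance analyses refuse to run rather than silently skip).
- **Gating**: Otsu on `log1p(mean intensity)`, per section by default
  (staining background varies between slides); a global threshold, a
  two-component Gaussian mixture cut at equal posterior, and manual
  cutoffs are available.  A constant intensity vector yields all-negative
  with a warning.  On log scale the positive set is invariant to
  rescaling the units.
- **Clustering space**: the feature matrix is
  `(BrdU_mean, Ki67_mean, area, circularity)`; intensities are
  log-transformed before z-scoring because fluorescence is log-normal —
  on the raw scale the high-intensity tails dominate the within-cluster
  variance and k-means fragments them.  k-means++ with `n_init = 20`
  restarts, fixed seed; candidate k = 2..8 (WSS additionally evaluated at
  1 and 9 so the elbow's second difference covers the interior).
- **k policy**: if Elbow and Silhouette agree, take it; otherwise take
  the Silhouette k and log the disagreement.  On these data the raw
  second-difference elbow always lands at k = 2 (the label-retention axis
  removes most variance first); the silhouette curve peaks cleanly at 4,
  which is why it is the deciding criterion.  Exact ties go to the
  smallest k.
- **Archetype matching**: per-cluster median z-profiles scored against
  the signature matrix (+1 high / −1 low / 0 medium-mixed over the four
  features, elongated = low circularity); the one-to-one assignment is
  enumerated exactly (24 permutations at k = 4).  Surplus clusters each
  take their individually best signature with a warning; identical
  profiles raise an ambiguity error.
- **Distance groups**: half-open edges `[0, 100, 250, 500, 750, ∞)` µm —
  100 and 750 are the biologically anchored radii, the interior edges are
  round and configurable.
- **KDE**: Gaussian kernel, Scott bandwidth, evaluated on a padded
  regular grid so the trapezoid integral is 1 within 2%.
- **Statistics**: "normal" means all four tests pass at α = 0.05
  (configurable as any-k-of-4); groups too small or constant fall to the
  nonparametric branch with a warning.  Dunn's z-tests use tie-corrected
  rank variances and Bonferroni adjustment by default (Holm available).
  The KS test runs against the fitted normal; fitting and testing on the
  same sample makes it conservative (no Lilliefors correction).  Dixon's
  Q is the two-sided r10 variant with the published α = 0.05 table
  (n = 3..30), flagging at most one point per pass.  t-tests are Welch by
  default; the pooled variant is a flag.

## Problem sizes and determinism

Default analyses use n = 2000 nuclei per section (n = 1200–1500 for
multi-section studies such as the time course), k-candidates 2..8, and
10-seed repetition for recovery properties; these sizes give stable
estimates (cluster-count selection and archetype matching are identical
across the seeds we run) while keeping a full simulation-plus-analysis
cycle in seconds.  Every random draw flows from one integer seed through
`numpy.random.Generator`; repeated runs with the same configuration are
bitwise identical, and the pipeline writes its effective configuration
and hash next to every output.

## Known limitations

The classical detector (Otsu + watershed) is adequate on clean synthetic
renders but is not a substitute for learned segmentation on real tissue.
The archetype-signature matching assumes the four-archetype biology; on
data with genuinely different structure the signature scores will be
ambiguous and the mapping should be treated as exploratory.  Distances
are Euclidean in the section plane, not geodesic within the tissue.
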