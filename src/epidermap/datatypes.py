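"""Shared domain containers for the basal-layer proliferation pipeline.

Coordinates are real-valued micrometres in the image convention: origin at
the top-left of the section, y increasing downward (toward the dermis).
All intensity values are arbitrary fluorescence units (a.u.); the pipeline
is scale-invariant after standardization.

Nucleus tables are plain :class:`pandas.DataFrame` objects using the
canonical column names in :data:`COLUMNS`; the dataclasses here hold
geometry, generative parameters and fitted-model state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

#: canonical nucleus-table columns (per-channel intensity columns are
#: "<channel>_<stat>" with stat in min/median/mean/sd/max)
COLUMNS = dict(
    nucleus_id="nucleus_id",
    centroid_x="centroid_x",
    centroid_y="centroid_y",
    area="area",
    perimeter="perimeter",
    circularity="circularity",
    dist_bm="dist_bm",
    dist_surface="dist_surface",
    dist_hf="dist_hf",
    epi_thickness="epi_thickness",
    relief="relief",
    brdu_pos="brdu_pos",
    ki67_pos="ki67_pos",
    basal="basal",
    excluded_upper="excluded_upper",
    cluster="cluster",
    archetype="archetype",
    section_id="section_id",
    site="site",
    timepoint="timepoint",
)

#: the four features used for clustering, in fixed order
CLUSTER_FEATURES = ("brdu_mean", "ki67_mean", "area", "circularity")

INTENSITY_STATS = ("min", "median", "mean", "sd", "max")


class ParameterError(ValueError):
    """Invalid user-supplied parameter (geometry, thresholds, counts)."""


@dataclass(frozen=True)
class TissueParams:
    """Geometry of one simulated skin section.

    The basement membrane undulates as ``y(x) = A sin(2 pi x / wavelength)``
    (rete ridges are the downward excursions, where the epidermis is
    locally thick); the epidermal surface is flat at ``y = -mean_thickness``.

    Parameters
    ----------
    section_length : float
        Lateral extent of the section, µm.
    mean_thickness : float
        Mean epidermal thickness T0, µm.  Must exceed twice the relief
        amplitude so thickness stays positive everywhere.
    relief_amplitude : float
        Amplitude A of the basement-membrane undulation, µm.
    relief_wavelength : float
        Spatial period of the undulation, µm.
    hf_positions : sequence of float
        x-coordinates (µm) of hair-follicle axes.
    hf_radius : float
        Radius of the vertical capsule representing each follicle, µm.
    pixel_size : float
        µm per pixel used when rendering images.
    """

    section_length: float = 12_000.0
    mean_thickness: float = 200.0
    relief_amplitude: float = 50.0
    relief_wavelength: float = 500.0
    hf_positions: tuple[float, ...] = (1_500.0, 6_000.0, 10_500.0)
    hf_radius: float = 60.0
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_thickness <= 0 or self.relief_wavelength <= 0:
            raise ParameterError("mean_thickness and relief_wavelength must be positive")
        if self.relief_amplitude < 0:
            raise ParameterError("relief_amplitude must be non-negative")
        if self.mean_thickness <= 2 * self.relief_amplitude:
            raise ParameterError(
                "mean_thickness must exceed 2*relief_amplitude to keep thickness positive"
            )
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        for x in self.hf_positions:
            if not 0 <= x <= self.section_length:
                raise ParameterError(f"hf_position {x} outside [0, {self.section_length}]")


@dataclass(frozen=True)
class SpatialRule:
    """Placement rule for one archetype.

    kind:
        'uniform'          — no spatial preference;
        'prefer_thick'     — biased toward locally thick epidermis (rete ridges);
        'prefer_thin'      — biased toward locally thin epidermis (inter-ridges);
    exclude_hf_min_dist:
        if set, enforced placements keep >= this distance (µm) from every
        hair-follicle boundary;
    enrich_hf_max_dist:
        if set, enforced placements of the archetype's rapid-cycling tail
        fall within this distance (µm) of a follicle boundary.
    """

    kind: str = "uniform"
    exclude_hf_min_dist: Optional[float] = None
    enrich_hf_max_dist: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "prefer_thick", "prefer_thin"):
            raise ParameterError(f"unknown spatial rule kind {self.kind!r}")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one of the four basal-cell archetypes.

    BrdU and Ki67 signal intensities are log-normal (natural-log mean/SD in
    a.u.).  ``ki67_high_weight`` sets the fraction of Ki67-positive cells
    drawn from the high mode; 0 gives a purely low-mode ("Low") archetype
    and 1 a unimodal archetype centred on ``ki67_high_logmean``.
    A ``quiescent_frac`` of cells is double negative — neither labelled at
    the pulse nor currently cycling — and draws background intensity in
    both channels; these are the cells the double-negative filter removes.
    A ``rapid_tail_frac`` > 0 marks that fraction of cells as rapidly
    cycling: their BrdU signal is drawn around ``rapid_tail_logmean``
    (label diluted by extra divisions), they are always Ki67-positive, and
    the spatial rule's follicle enrichment applies to them.
    """

    archetype_id: int
    mixture_weight: float
    brdu_mean_log: float
    brdu_sd_log: float
    ki67_low_logmean: float
    ki67_high_logmean: float
    ki67_sd_log: float
    ki67_high_weight: float
    area_mean: float
    area_sd: float
    circularity_mean: float
    circularity_sd: float
    brdu_pos_prob: float = 1.0
    ki67_pos_prob: float = 1.0
    quiescent_frac: float = 0.0
    rapid_tail_frac: float = 0.0
    rapid_tail_logmean: float = 0.0
    rapid_tail_sd_log: float = 0.5
    spatial_rule: SpatialRule = field(default_factory=SpatialRule)

    def __post_init__(self) -> None:
        if self.archetype_id not in (1, 2, 3, 4):
            raise ParameterError("archetype_id must be in {1,2,3,4}")
        if not 0 <= self.mixture_weight <= 1:
            raise ParameterError("mixture_weight must lie in [0,1]")
        if self.circularity_mean + 2 * self.circularity_sd > 1 + 1e-9:
            raise ParameterError("circularity_mean + 2*sd must not exceed 1")


@dataclass
class AnnotationSet:
    """Named tissue geometry for one section.

    basement_membrane / epidermal_surface: one or more polylines (µm);
    hair_follicles: zero or more polygons; epidermis: the closed region
    between the two border polylines.
    """

    basement_membrane: list[LineString]
    epidermal_surface: list[LineString]
    hair_follicles: list[Polygon]
    epidermis: Polygon

    def __post_init__(self) -> None:
        if not self.basement_membrane:
            raise ParameterError("at least one basement-membrane polyline required")
        if not self.epidermal_surface:
            raise ParameterError("at least one epidermal-surface polyline required")
        for line in list(self.basement_membrane) + list(self.epidermal_surface):
            if len(line.coords) < 2:
                raise ParameterError("polylines need at least 2 vertices")
        if not self.epidermis.is_valid:
            raise ParameterError("epidermis polygon must be simple (non-self-intersecting)")


@dataclass
class GatingResult:
    """Outcome of intensity-based positivity calling for one channel."""

    channel: str
    threshold: float  # a.u., on the raw intensity scale
    method: str  # otsu | gmm2 | manual
    n_positive: int
    n_negative: int
    degenerate: bool = False

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass
class ClusterModel:
    """Fitted k-means state plus the k-selection diagnostics."""

    feature_names: tuple[str, ...]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    k_candidates: tuple[int, ...]
    wss_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    elbow_k: int
    silhouette_k: int
    chosen_k: int
    centroids: np.ndarray  # standardized space, shape (k, n_features)
    labels: np.ndarray  # 0-based k-means labels per row
    archetype_map: dict[int, int]  # k-means label -> archetype id
    seed: int
    n_init: int

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "k_candidates": list(self.k_candidates),
            "wss_by_k": {str(k): v for k, v in self.wss_by_k.items()},
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
            "elbow_k": self.elbow_k,
            "silhouette_k": self.silhouette_k,
            "chosen_k": self.chosen_k,
            "centroids": self.centroids.tolist(),
            "archetype_map": {str(k): v for k, v in self.archetype_map.items()},
            "seed": self.seed,
            "n_init": self.n_init,
        }


@dataclass
class StatResult:
    """One statistical comparison: test identity, statistic, p, post-hoc."""

    test_name: str
    statistic: float
    p_value: float
    groups: Sequence[str] = ()
    post_hoc: Optional["pd.DataFrame"] = None  # noqa: F821 - forward ref
    normality_verdicts: Optional[dict] = None
    chosen_branch: Optional[str] = None  # anova_tukey | kw_dunn
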