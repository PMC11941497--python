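"""Geometric covariates of basal nuclei relative to tissue annotations.

Distances are Euclidean in the section plane (µm), matching the
distance-to-annotation semantics of interactive annotation tools: a
point's distance to a polyline is the minimum over its segments
(endpoint-clamped), and its distance to a hair-follicle polygon is the
boundary distance, zero inside.  The per-nucleus epidermal-thickness
proxy is the sum of the distances to the basement membrane and to the
epidermal surface; nuclei in locally thick epidermis sit in rete ridges
(invaginations), nuclei in locally thin epidermis in inter-ridges
(evaginations).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

from .datatypes import AnnotationSet, ParameterError

log = logging.getLogger(__name__)

#: default basal-layer cutoff: one basal-nucleus diameter from the membrane
DEFAULT_MAX_DIST_BM = 15.0


def point_to_polyline_distance(point: tuple[float, float], polyline) -> float:
    """Minimum Euclidean distance (µm) from a point to a polyline."""
    line = polyline if isinstance(polyline, LineString) else LineString(polyline)
    if line.length == 0:
        raise ParameterError("degenerate zero-length polyline")
    return float(line.distance(Point(point)))


def _min_distance(points, geometries) -> np.ndarray:
    return np.min([shapely.distance(points, g) for g in geometries], axis=0)


def compute_covariates(table: pd.DataFrame, annotations: AnnotationSet) -> pd.DataFrame:
    """Append dist_bm, dist_surface, dist_hf and epi_thickness columns.

    ``dist_hf`` is NaN when the annotation set contains no follicles
    (e.g. abdominal sections).  When several polylines of a class exist,
    the nearest one is used.
    """
    pts = shapely.points(
        np.column_stack([table["centroid_x"].to_numpy(), table["centroid_y"].to_numpy()])
    )
    out = table.copy()
    out["dist_bm"] = _min_distance(pts, annotations.basement_membrane)
    out["dist_surface"] = _min_distance(pts, annotations.epidermal_surface)
    if annotations.hair_follicles:
        out["dist_hf"] = _min_distance(pts, annotations.hair_follicles)
    else:
        out["dist_hf"] = np.nan
    out["epi_thickness"] = out["dist_bm"] + out["dist_surface"]
    return out


def epidermal_thickness(nucleus, annotations: AnnotationSet) -> float:
    """Per-nucleus thickness proxy: dist to membrane + dist to surface."""
    p = Point(nucleus["centroid_x"], nucleus["centroid_y"])
    d_bm = min(line.distance(p) for line in annotations.basement_membrane)
    d_surf = min(line.distance(p) for line in annotations.epidermal_surface)
    return float(d_bm + d_surf)


def distance_to_hf(nucleus, annotations: AnnotationSet) -> float:
    """Boundary distance (µm) to the nearest follicle; 0 inside; NaN if none."""
    if not annotations.hair_follicles:
        return float("nan")
    p = Point(nucleus["centroid_x"], nucleus["centroid_y"])
    return float(min(poly.distance(p) for poly in annotations.hair_follicles))


def basal_layer_filter(
    table: pd.DataFrame,
    max_dist_bm: float = DEFAULT_MAX_DIST_BM,
) -> tuple[pd.DataFrame, dict]:
    """Flag and retain basal nuclei; exclude the upper epidermal layers.

    Nuclei farther than ``max_dist_bm`` µm from the basement membrane are
    flagged ``excluded_upper`` and dropped from the returned table (they
    carry unreliable marker signal from out-of-layer background).
    Returns the retained table plus an exclusion report.
    """
    if "dist_bm" not in table.columns:
        raise ParameterError("dist_bm not computed; run compute_covariates first")
    basal = table["dist_bm"].to_numpy() <= max_dist_bm
    flagged = table.copy()
    flagged["basal"] = basal
    flagged["excluded_upper"] = ~basal
    report = {
        "n_input": int(len(table)),
        "n_retained": int(basal.sum()),
        "n_excluded_upper": int((~basal).sum()),
        "max_dist_bm": float(max_dist_bm),
    }
    log.info(
        "basal filter: retained %d / %d nuclei (cutoff %.1f µm)",
        report["n_retained"], report["n_input"], max_dist_bm,
    )
    return flagged.loc[basal].reset_index(drop=True), report


def classify_relief(table: pd.DataFrame) -> pd.DataFrame:
    """Categorize nuclei as invagination (rete ridge) vs evagination.

    Per section, nuclei with epidermal thickness above the section median
    are invaginations; ties and below-median go to evaginations.  With
    flat geometry every nucleus lands in the evagination category and a
    degeneracy warning is emitted.
    """
    if "epi_thickness" not in table.columns:
        raise ParameterError("epi_thickness not computed; run compute_covariates first")
    out = table.copy()
    group_key = out["section_id"] if "section_id" in out.columns else pd.Series(0, index=out.index)
    relief = pd.Series(index=out.index, dtype=object)
    for section, idx in out.groupby(group_key).groups.items():
        th = out.loc[idx, "epi_thickness"]
        if len(idx) < 10:
            log.warning("section %s has only %d basal nuclei; relief split is noisy", section, len(idx))
        med = th.median()
        if th.nunique() == 1:
            log.warning("section %s: constant thickness; relief split is degenerate", section)
        relief.loc[idx] = np.where(th > med, "invagination", "evagination")
    out["relief"] = relief
    return out
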