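"""Synthetic epidermis generator with planted archetype structure.

Emulates a vertical section through interfollicular epidermis: an
undulating basement membrane (rete ridges = locally thick epidermis), a
flat epidermal surface, vertical hair-follicle (HF) capsules, and a basal
layer of nuclei drawn from four generative archetypes:

1. mixed-phenotype cells, spread uniformly; a rapid-cycling tail with
   diluted (low) BrdU concentrates near follicles,
2. small elongated nuclei, uniform (low BrdU, low Ki67),
3. label-retaining cells: high BrdU, preferring thin (inter-ridge)
   epidermis and excluded from a radius around follicles,
4. large nuclei preferring thick (rete-ridge) epidermis.

A ``pattern_strength`` dial in [0, 1] sets the probability that each
nucleus obeys its archetype's spatial rule; 0 reproduces the spatially
unpatterned state of early regeneration, 1 the fully patterned
homeostatic state.  Every dataset carries hidden ground-truth columns
(``true_archetype``, ``true_brdu_pos``, ``true_ki67_pos``,
``true_rapid_tail``) so downstream recovery can be scored.

All randomness flows from a single integer seed through
:class:`numpy.random.Generator`; identical (parameters, seed) give
bitwise-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon

from .datatypes import (
    AnnotationSet,
    ArchetypeSpec,
    ParameterError,
    SpatialRule,
    TissueParams,
)

# log-normal parameters (natural log, a.u.) of the non-specific background
# signal measured in nuclei negative for a channel
BACKGROUND_LOGMEAN = 2.0
BACKGROUND_SDLOG = 0.45

#: maximum distance (µm) from a planted centroid to the basement membrane
BASAL_JITTER = 8.0

#: minimum centroid separation (µm) enforced by the Poisson-disk placement;
#: slightly below one nucleus diameter, approximating the tight quasi-double
#: row packing of basal nuclei in section
MIN_SEPARATION = 4.0

TIMEPOINTS = ("PG40", "PG75", "PG110")


def default_archetypes() -> list[ArchetypeSpec]:
    """The four default archetypes (mixture weights 0.35/0.30/0.15/0.20).

    Intensity scales are arbitrary units; contrasts are what matter.  The
    "high" BrdU geometric mean sits e^1.5 above the "low" one; nuclear
    areas are 25/40/60 µm² (SD 20%); circularity 0.90 (round) vs 0.70
    (elongated).  The qualitative Ki67 levels are rendered as log-normal
    continua: "Low" centred at log 4.0, the label-retaining archetype's
    variable "High/Low" as one broad component centred at log 4.4, and
    the rete-ridge archetype's "Low/High" centred at log 4.8 — cells vary
    continuously through the cycle rather than occupying two discrete
    states.  Archetypes 1, 2 and 4 carry a quiescent (BrdU-/Ki67-)
    fraction; archetype 1 additionally carries a rapid-cycling low-BrdU
    tail that concentrates near follicles when the pattern is on.
    """
    return [
        ArchetypeSpec(
            archetype_id=1, mixture_weight=0.35,
            brdu_mean_log=4.0, brdu_sd_log=0.2,
            ki67_low_logmean=4.0, ki67_high_logmean=4.8, ki67_sd_log=0.25,
            ki67_high_weight=0.0,
            area_mean=40.0, area_sd=8.0,
            circularity_mean=0.90, circularity_sd=0.04,
            quiescent_frac=0.18,
            rapid_tail_frac=0.30, rapid_tail_logmean=3.2, rapid_tail_sd_log=0.5,
            spatial_rule=SpatialRule("uniform", enrich_hf_max_dist=100.0),
        ),
        ArchetypeSpec(
            archetype_id=2, mixture_weight=0.30,
            brdu_mean_log=4.0, brdu_sd_log=0.2,
            ki67_low_logmean=4.0, ki67_high_logmean=4.8, ki67_sd_log=0.25,
            ki67_high_weight=0.0,
            area_mean=25.0, area_sd=5.0,
            circularity_mean=0.70, circularity_sd=0.06,
            quiescent_frac=0.18,
            spatial_rule=SpatialRule("uniform"),
        ),
        ArchetypeSpec(
            archetype_id=3, mixture_weight=0.15,
            brdu_mean_log=5.5, brdu_sd_log=0.2,
            ki67_low_logmean=4.0, ki67_high_logmean=4.4, ki67_sd_log=0.45,
            ki67_high_weight=1.0,
            area_mean=40.0, area_sd=8.0,
            circularity_mean=0.90, circularity_sd=0.04,
            quiescent_frac=0.0,
            spatial_rule=SpatialRule("prefer_thin", exclude_hf_min_dist=750.0),
        ),
        ArchetypeSpec(
            archetype_id=4, mixture_weight=0.20,
            brdu_mean_log=4.0, brdu_sd_log=0.2,
            ki67_low_logmean=4.0, ki67_high_logmean=4.8, ki67_sd_log=0.25,
            ki67_high_weight=1.0,
            area_mean=60.0, area_sd=12.0,
            circularity_mean=0.90, circularity_sd=0.04,
            quiescent_frac=0.12,
            spatial_rule=SpatialRule("prefer_thick"),
        ),
    ]


@dataclass
class SyntheticDataset:
    """One generated section: geometry, nucleus table and provenance."""

    annotations: AnnotationSet
    nuclei: pd.DataFrame
    params: TissueParams
    archetypes: list[ArchetypeSpec]
    timepoint: str = "homeostasis"
    pattern_strength: float = 1.0
    seed: int = 0

    @property
    def planted_ki67_fraction(self) -> float:
        return float(self.nuclei["true_ki67_pos"].mean())


def generate_tissue_geometry(params: TissueParams, seed: int | None = None) -> AnnotationSet:
    """Build the annotation geometry for one section.

    The basement membrane is sampled at <= 1 µm steps as
    ``y = A sin(2 pi x / wavelength)``; the surface is the flat polyline
    ``y = -T0``; follicles are vertical capsules of radius ``hf_radius``
    crossing the membrane; the epidermis region is the closed polygon
    between the two borders.  Deterministic; ``seed`` is accepted for
    interface symmetry only.
    """
    L = params.section_length
    n_pts = max(int(math.ceil(L)) + 1, 2)
    x = np.linspace(0.0, L, n_pts)
    y_bm = params.relief_amplitude * np.sin(2 * np.pi * x / params.relief_wavelength)
    bm = LineString(np.column_stack([x, y_bm]))
    surface = LineString([(0.0, -params.mean_thickness), (L, -params.mean_thickness)])

    ring = np.vstack(
        [
            np.column_stack([x, y_bm]),
            [[L, -params.mean_thickness], [0.0, -params.mean_thickness]],
        ]
    )
    epidermis = Polygon(ring)

    hfs = []
    top = -params.mean_thickness
    bottom = params.relief_amplitude + 3 * params.hf_radius
    for hx in params.hf_positions:
        axis = LineString([(hx, top), (hx, bottom)])
        hfs.append(axis.buffer(params.hf_radius, quad_segs=16))

    return AnnotationSet(
        basement_membrane=[bm],
        epidermal_surface=[surface],
        hair_follicles=hfs,
        epidermis=epidermis,
    )


def _membrane_candidates(annotations: AnnotationSet, params: TissueParams, step: float = 2.0):
    """Dense samples along the membrane with local thickness and HF distance."""
    bm = annotations.basement_membrane[0]
    arc = np.arange(0.0, bm.length, step)
    pts = shapely.line_interpolate_point(bm, arc)
    xs = shapely.get_x(pts)
    ys = shapely.get_y(pts)
    d_surf = np.min(
        [shapely.distance(pts, line) for line in annotations.epidermal_surface], axis=0
    )
    thickness = d_surf  # candidate sits on the membrane, so dist_bm = 0
    if annotations.hair_follicles:
        d_hf = np.min(
            [shapely.distance(pts, poly) for poly in annotations.hair_follicles], axis=0
        )
    else:
        d_hf = np.full(xs.shape, np.inf)
    return xs, ys, thickness, d_hf


def _rule_mask(rule: SpatialRule, thickness: np.ndarray, d_hf: np.ndarray) -> np.ndarray:
    med = np.median(thickness)
    mask = np.ones(thickness.shape, dtype=bool)
    if rule.kind == "prefer_thin":
        mask &= thickness < med
    elif rule.kind == "prefer_thick":
        mask &= thickness > med
    if rule.exclude_hf_min_dist is not None:
        mask &= d_hf >= rule.exclude_hf_min_dist
    return mask


def generate_nuclei(
    annotations: AnnotationSet,
    archetypes: list[ArchetypeSpec],
    n: int,
    pattern_strength: float,
    seed: int,
    params: TissueParams | None = None,
    timepoint: str = "homeostasis",
    section_id: str = "S1",
    site: str = "head",
    min_separation: float = MIN_SEPARATION,
) -> SyntheticDataset:
    """Place ``n`` basal nuclei and draw their features archetype-wise.

    Placement is Poisson-disk along the basement membrane (minimum
    centroid separation :data:`MIN_SEPARATION`) with the centroid offset
    toward the surface by at most :data:`BASAL_JITTER` µm.  Each nucleus
    draws an archetype by mixture weight; with probability
    ``pattern_strength`` the archetype's spatial rule constrains the
    placement, otherwise placement is uniform along the membrane.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    weights = np.array([a.mixture_weight for a in archetypes], float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ParameterError("archetype mixture weights must sum to 1")
    if params is None:
        params = TissueParams()

    rng = np.random.default_rng(seed)
    xs, ys, thickness, d_hf = _membrane_candidates(annotations, params)
    n_cand = xs.size
    capacity = int(0.9 * 2 * annotations.basement_membrane[0].length / min_separation)
    if n > capacity:
        raise ParameterError(
            f"requested {n} nuclei exceeds non-overlapping placement capacity "
            f"~{capacity} for this section"
        )

    masks = {}
    for spec in archetypes:
        masks[spec.archetype_id] = _rule_mask(spec.spatial_rule, thickness, d_hf)
        if spec.spatial_rule.enrich_hf_max_dist is not None:
            masks[(spec.archetype_id, "tail")] = d_hf <= spec.spatial_rule.enrich_hf_max_dist

    arch_idx = rng.choice(len(archetypes), size=n, p=weights)

    # greedy dart throwing with a 1-D occupancy grid keyed on x
    cell = min_separation
    occupied: dict[int, list[tuple[float, float]]] = {}
    chosen = np.empty(n, dtype=int)
    off = np.empty(n)
    enforce = rng.random(n) < pattern_strength
    tail_flags = np.zeros(n, dtype=bool)
    for i in range(n):
        spec = archetypes[arch_idx[i]]
        is_tail = spec.rapid_tail_frac > 0 and rng.random() < spec.rapid_tail_frac
        tail_flags[i] = is_tail
        if enforce[i]:
            if is_tail and (spec.archetype_id, "tail") in masks:
                mask = masks[(spec.archetype_id, "tail")]
            else:
                mask = masks[spec.archetype_id]
            pool = np.flatnonzero(mask)
            if pool.size == 0:
                pool = np.arange(n_cand)
        else:
            pool = None  # uniform
        placed = False
        for _ in range(500):
            j = int(pool[rng.integers(pool.size)]) if pool is not None else int(rng.integers(n_cand))
            d = rng.uniform(1.0, BASAL_JITTER)
            px, py = xs[j], ys[j] - d
            key = int(px // cell)
            ok = True
            for k in (key - 1, key, key + 1):
                for qx, qy in occupied.get(k, ()):
                    if (px - qx) ** 2 + (py - qy) ** 2 < min_separation**2:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                occupied.setdefault(key, []).append((px, py))
                chosen[i] = j
                off[i] = d
                placed = True
                break
        if not placed:
            raise ParameterError(
                f"could not place nucleus {i + 1}/{n} without overlap; "
                f"placement capacity ~{capacity} nuclei for this section"
            )

    cx = xs[chosen]
    cy = ys[chosen] - off
    th = thickness[chosen]
    dhf = d_hf[chosen]

    rows = _draw_features(rng, [archetypes[k] for k in arch_idx], tail_flags)
    table = pd.DataFrame(rows)
    table.insert(0, "nucleus_id", np.arange(1, n + 1))
    table["centroid_x"] = cx
    table["centroid_y"] = cy
    table["true_archetype"] = [archetypes[k].archetype_id for k in arch_idx]
    table["true_rapid_tail"] = tail_flags
    # offsetting toward the surface trades dist_bm for dist_surface, so the
    # per-nucleus thickness proxy equals the membrane-point thickness
    table["true_thickness"] = th
    table["true_dist_hf"] = dhf
    table["section_id"] = section_id
    table["site"] = site
    table["timepoint"] = timepoint

    return SyntheticDataset(
        annotations=annotations,
        nuclei=table,
        params=params,
        archetypes=list(archetypes),
        timepoint=timepoint,
        pattern_strength=pattern_strength,
        seed=seed,
    )


def _channel_stats(rng: np.random.Generator, mean: np.ndarray, prefix: str) -> dict:
    """Within-nucleus pixel summaries derived from the drawn mean signal."""
    n = mean.size
    spread = 0.15 * mean
    return {
        f"{prefix}_mean": mean,
        f"{prefix}_sd": spread * rng.uniform(0.8, 1.2, n),
        f"{prefix}_min": mean * rng.uniform(0.45, 0.65, n),
        f"{prefix}_median": mean * rng.uniform(0.92, 1.0, n),
        f"{prefix}_max": mean * rng.uniform(1.35, 1.7, n),
    }


def _tnorm(rng: np.random.Generator, mu: float, sd: float, width: float = 2.0) -> float:
    """Normal draw truncated symmetrically at ``mu ± width*sd``.

    Nuclear features are biologically bounded; the symmetric truncation
    keeps the planted mean exact while removing implausible extremes.
    """
    for _ in range(20):
        x = rng.normal(mu, sd)
        if abs(x - mu) <= width * sd:
            return x
    return float(np.clip(x, mu - width * sd, mu + width * sd))


def _draw_features(
    rng: np.random.Generator, specs: list[ArchetypeSpec], tails: np.ndarray
) -> dict:
    n = len(specs)
    area = np.empty(n)
    circ = np.empty(n)
    brdu = np.empty(n)
    ki67 = np.empty(n)
    dapi = np.exp(rng.normal(5.0, 0.15, n))
    brdu_pos = np.empty(n, dtype=bool)
    ki67_pos = np.empty(n, dtype=bool)
    for i, spec in enumerate(specs):
        area[i] = max(_tnorm(rng, spec.area_mean, spec.area_sd), 5.0)
        circ[i] = float(np.clip(rng.normal(spec.circularity_mean, spec.circularity_sd), 0.2, 1.0))
        quiescent = (not tails[i]) and rng.random() < spec.quiescent_frac
        if quiescent:
            brdu_pos[i] = ki67_pos[i] = False
            brdu[i] = math.exp(rng.normal(BACKGROUND_LOGMEAN, BACKGROUND_SDLOG))
            ki67[i] = math.exp(rng.normal(BACKGROUND_LOGMEAN, BACKGROUND_SDLOG))
            continue
        if tails[i]:
            brdu_pos[i] = True
            # label dilution bounds a rapid cycler's retained BrdU below the
            # undivided low mode: truncate the tail draw at brdu_mean_log
            draw = rng.normal(spec.rapid_tail_logmean, spec.rapid_tail_sd_log)
            for _ in range(20):
                if draw <= spec.brdu_mean_log:
                    break
                draw = rng.normal(spec.rapid_tail_logmean, spec.rapid_tail_sd_log)
            brdu[i] = math.exp(min(draw, spec.brdu_mean_log))
            ki67_pos[i] = True
        else:
            brdu_pos[i] = rng.random() < spec.brdu_pos_prob
            mu = spec.brdu_mean_log if brdu_pos[i] else BACKGROUND_LOGMEAN
            sd = spec.brdu_sd_log if brdu_pos[i] else BACKGROUND_SDLOG
            brdu[i] = math.exp(_tnorm(rng, mu, sd))
            ki67_pos[i] = rng.random() < spec.ki67_pos_prob
        if ki67_pos[i]:
            high = rng.random() < spec.ki67_high_weight
            mu = spec.ki67_high_logmean if high else spec.ki67_low_logmean
            ki67[i] = math.exp(_tnorm(rng, mu, spec.ki67_sd_log))
        else:
            ki67[i] = math.exp(_tnorm(rng, BACKGROUND_LOGMEAN, BACKGROUND_SDLOG))
    perimeter = np.sqrt(4 * np.pi * area / circ)
    out = {
        "area": area,
        "perimeter": perimeter,
        "circularity": circ,
        "true_brdu_pos": brdu_pos,
        "true_ki67_pos": ki67_pos,
    }
    out.update(_channel_stats(rng, dapi, "dapi"))
    out.update(_channel_stats(rng, brdu, "brdu"))
    out.update(_channel_stats(rng, ki67, "ki67"))
    return out


def generate_dataset(
    n: int = 2000,
    pattern_strength: float = 1.0,
    seed: int = 0,
    params: TissueParams | None = None,
    archetypes: list[ArchetypeSpec] | None = None,
    **kwargs,
) -> SyntheticDataset:
    """Convenience wrapper: geometry + nuclei in one call (default preset)."""
    params = params or TissueParams()
    archetypes = archetypes or default_archetypes()
    ann = generate_tissue_geometry(params)
    return generate_nuclei(
        ann, archetypes, n=n, pattern_strength=pattern_strength, seed=seed,
        params=params, **kwargs,
    )


def _scale_quiescence(spec: ArchetypeSpec, multiplier: float) -> ArchetypeSpec:
    """Early regeneration has fewer quiescent cells (higher Ki67+ fraction)."""
    return replace(spec, quiescent_frac=spec.quiescent_frac * multiplier)


def generate_timecourse(
    base_params: TissueParams | None = None,
    seed: int = 0,
    n: int = 2000,
    archetypes: list[ArchetypeSpec] | None = None,
) -> dict[str, SyntheticDataset]:
    """Three-timepoint regeneration series (PG40 / PG75 / PG110).

    Early regeneration (PG40) has no spatial pattern, barely
    distinguishable relief (amplitude scaled to 25%) and elevated Ki67
    positivity; PG75 is intermediate; PG110 carries the full homeostatic
    pattern.  All three draw from one deterministic seed stream.
    """
    base_params = base_params or TissueParams()
    archetypes = archetypes or default_archetypes()
    stages = {
        "PG40": dict(pattern=0.0, relief=0.25, quiescence=0.5),
        "PG75": dict(pattern=0.5, relief=0.6, quiescence=0.75),
        "PG110": dict(pattern=1.0, relief=1.0, quiescence=1.0),
    }
    child_seeds = np.random.SeedSequence(seed).generate_state(len(stages)) % (2**31)
    out = {}
    for (name, cfg), s in zip(stages.items(), child_seeds):
        p = replace(base_params, relief_amplitude=base_params.relief_amplitude * cfg["relief"])
        specs = [_scale_quiescence(a, cfg["quiescence"]) for a in archetypes]
        ann = generate_tissue_geometry(p)
        out[name] = generate_nuclei(
            ann, specs, n=n, pattern_strength=cfg["pattern"], seed=int(s),
            params=p, timepoint=name,
        )
    return out


def _ellipse_axes(area: float, circularity: float) -> tuple[float, float]:
    """Semi-axes (a >= b, µm) of an ellipse with given area and circularity."""
    from scipy.optimize import brentq

    def circ_of(q: float) -> float:
        a = math.sqrt(area / (math.pi * q))
        b = a * q
        h = ((a - b) / (a + b)) ** 2
        p = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        return 4 * math.pi * area / p**2

    c = min(circularity, 0.999)
    if circ_of(1e-3) > c:
        q = 1e-3
    else:
        q = brentq(lambda t: circ_of(t) - c, 1e-3, 1.0)
    a = math.sqrt(area / (math.pi * q))
    return a, a * q


def render_section_image(
    dataset: SyntheticDataset,
    channels: tuple[str, ...] = ("dapi", "brdu", "ki67"),
    params: TissueParams | None = None,
    noise_sd: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a dataset into a multi-channel image plus a label mask.

    Each nucleus becomes an ellipse (axes solved from area and
    circularity, random orientation) filled with its per-channel mean
    intensity, lightly blurred for soft edges, with additive Gaussian
    background noise.  Returns ``(image[C, H, W] float32, mask[H, W] int32)``
    where mask pixels hold ``nucleus_id``.
    """
    from skimage.draw import ellipse as draw_ellipse
    from skimage.filters import gaussian

    params = params or dataset.params
    if params.pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    px = params.pixel_size
    tab = dataset.nuclei
    pad = 20.0
    x0 = float(tab["centroid_x"].min() - pad) if len(tab) else 0.0
    y0 = float(tab["centroid_y"].min() - pad) if len(tab) else 0.0
    x1 = float(tab["centroid_x"].max() + pad) if len(tab) else pad
    y1 = float(tab["centroid_y"].max() + pad) if len(tab) else pad
    W = int(math.ceil((x1 - x0) / px)) + 1
    H = int(math.ceil((y1 - y0) / px)) + 1
    img = np.zeros((len(channels), H, W), dtype=np.float32)
    mask = np.zeros((H, W), dtype=np.int32)
    rng = np.random.default_rng(dataset.seed + 1)

    for row in tab.itertuples():
        a, b = _ellipse_axes(row.area, row.circularity)
        rr, cc = draw_ellipse(
            (row.centroid_y - y0) / px,
            (row.centroid_x - x0) / px,
            a / px,
            b / px,
            shape=mask.shape,
            rotation=rng.uniform(0, math.pi),
        )
        if mask[rr, cc].any():
            raise ParameterError(
                "nuclei overlap at the configured pixel_size; regenerate with "
                "fewer nuclei or a smaller pixel size"
            )
        mask[rr, cc] = row.nucleus_id
        for ci, ch in enumerate(channels):
            img[ci, rr, cc] = getattr(row, f"{ch}_mean")

    for ci in range(len(channels)):
        img[ci] = gaussian(img[ci], sigma=1.0, preserve_range=True)
        img[ci] += rng.normal(0.0, noise_sd, size=(H, W))
    return img, mask
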