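"""Readers and writers for the QuPath measurement-export dialect.

QuPath exports per-detection measurement tables whose headers carry the
unit, e.g. ``Nucleus: Area µm^2`` or ``BrdU: Nucleus: Mean``, and
annotation geometry as GeoJSON FeatureCollections whose features are
classified by name.  This module maps that dialect onto the package's
canonical nucleus-table columns (``area``, ``brdu_mean`` ...) and
:class:`~epidermap.datatypes.AnnotationSet`, converting units to µm/µm².

Only the decimal point is accepted as the decimal separator; tables
written with a comma-decimal locale are rejected with a clear error
rather than silently misparsed.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon, shape, mapping

from .datatypes import AnnotationSet, ParameterError

log = logging.getLogger(__name__)

MICRON = "µm"

# fixed (non-channel) header <-> canonical column
_FIXED_HEADERS = {
    "Object ID": "nucleus_id",
    f"Centroid X {MICRON}": "centroid_x",
    f"Centroid Y {MICRON}": "centroid_y",
    f"Nucleus: Area {MICRON}^2": "area",
    f"Nucleus: Perimeter {MICRON}": "perimeter",
    "Nucleus: Circularity": "circularity",
    "Nucleus: Solidity": "solidity",
    f"Nucleus: Max diameter {MICRON}": "max_diameter",
    f"Nucleus: Min diameter {MICRON}": "min_diameter",
    f"Distance to annotation BasementMembrane {MICRON}": "dist_bm",
    f"Distance to annotation EpidermalSurface {MICRON}": "dist_surface",
    f"Distance to annotation HairFollicle {MICRON}": "dist_hf",
    "Image": "section_id",
}

_STAT_MAP = {"Min": "min", "Median": "median", "Mean": "mean", "Std.Dev.": "sd", "Max": "max"}
_CHANNEL_RE = re.compile(r"^(?P<channel>[^:]+): Nucleus: (?P<stat>Min|Median|Mean|Std\.Dev\.|Max)$")

REQUIRED = ("centroid_x", "centroid_y", "area", "circularity")

_LENGTH_FACTORS = {MICRON: 1.0, "um": 1.0, "mm": 1000.0}


def _unit_scale(header: str, pixel_size: float | None) -> float:
    """Length/area unit factor implied by a header suffix (µm is 1)."""
    m = re.search(r"(µm|um|mm|px)(\^2)?$", header)
    if not m:
        return 1.0
    unit, sq = m.group(1), m.group(2)
    if unit == "px":
        if pixel_size is None:
            raise ParameterError(
                f"column {header!r} is in pixels; pass pixel_size to convert to {MICRON}"
            )
        f = pixel_size
    else:
        f = _LENGTH_FACTORS[unit]
    return f * f if sq else f


def _canonical_name(header: str) -> str | None:
    if header in _FIXED_HEADERS:
        return _FIXED_HEADERS[header]
    # tolerate 'um' for 'µm'
    normalized = header.replace("um^2", f"{MICRON}^2").replace(" um", f" {MICRON}")
    if normalized in _FIXED_HEADERS:
        return _FIXED_HEADERS[normalized]
    m = _CHANNEL_RE.match(header)
    if m:
        ch = re.sub(r"\W+", "", m.group("channel")).lower()
        return f"{ch}_{_STAT_MAP[m.group('stat')]}"
    return None


_NUMERIC_PREFIXES = (
    "centroid_", "area", "perimeter", "circularity", "solidity",
    "max_diameter", "min_diameter", "dist_",
)


def _is_numeric_column(name: str) -> bool:
    return name.startswith(_NUMERIC_PREFIXES) or re.search(
        r"_(min|median|mean|sd|max)$", name
    ) is not None


_COMMA_DECIMAL = re.compile(r"^-?\d+,\d+$")


def read_qupath_measurements(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Read a QuPath measurement export (CSV or TSV) into a nucleus table.

    Columns are mapped from the QuPath dialect (or an explicit
    ``column_map`` of header -> canonical name), units converted to µm /
    µm², and rows with unparseable numeric cells dropped with a logged
    count.  Unrecognized columns are kept under sanitized names so
    ground-truth or custom annotations survive a round trip.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    if raw.empty or raw.shape[1] == 0:
        raise ParameterError(f"{path}: empty measurement table")

    rename: dict[str, str] = {}
    scales: dict[str, float] = {}
    for header in raw.columns:
        if column_map and header in column_map:
            name = column_map[header]
        else:
            name = _canonical_name(header)
        if name is None:
            name = re.sub(r"\W+", "_", header.strip()).strip("_").lower()
        rename[header] = name
        scales[name] = _unit_scale(header, pixel_size)

    table = raw.rename(columns=rename)
    missing = [c for c in REQUIRED if c not in table.columns]
    if missing:
        raise ParameterError(
            f"{path}: missing required column(s) {missing} after probing the "
            "QuPath dialect (e.g. 'Centroid X µm', 'Nucleus: Area µm^2'); "
            "pass column_map to supply a custom mapping"
        )

    bad_rows = np.zeros(len(table), dtype=bool)
    for col in table.columns:
        if not _is_numeric_column(col):
            continue
        s = table[col].astype(str).str.strip()
        if s.str.match(_COMMA_DECIMAL).any():
            raise ParameterError(
                f"{path}: column {col!r} uses comma decimal separators; "
                "export the table with a point-decimal locale"
            )
        values = pd.to_numeric(s, errors="coerce")
        bad_rows |= values.isna() & s.notna() & (s != "") & (s.str.lower() != "nan")
        table[col] = values * scales.get(col, 1.0)
    if bad_rows.any():
        log.warning("dropped %d row(s) with unparseable numeric cells", int(bad_rows.sum()))
        table = table.loc[~bad_rows].reset_index(drop=True)
    if len(table) == 0:
        raise ParameterError(f"{path}: no parseable rows")

    for col in ("true_brdu_pos", "true_ki67_pos", "true_rapid_tail"):
        if col in table.columns:
            table[col] = table[col].astype(str).str.lower().isin(("true", "1"))
    for col in ("nucleus_id", "true_archetype"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce").astype("Int64")
    return table


def write_qupath_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a nucleus table using QuPath-dialect headers (CSV)."""
    inverse = {v: k for k, v in _FIXED_HEADERS.items()}
    stat_inverse = {v: k for k, v in _STAT_MAP.items()}
    headers = {}
    for col in table.columns:
        if col in inverse:
            headers[col] = inverse[col]
            continue
        m = re.match(r"^(dapi|brdu|ki67|[a-z0-9]+)_(min|median|mean|sd|max)$", col)
        if m and _is_numeric_column(col):
            ch = {"dapi": "DAPI", "brdu": "BrdU", "ki67": "Ki67"}.get(
                m.group(1), m.group(1).upper()
            )
            headers[col] = f"{ch}: Nucleus: {stat_inverse[m.group(2)]}"
        else:
            headers[col] = col
    table.rename(columns=headers).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# GeoJSON annotations

_CLASS_NAMES = {
    "BasementMembrane": "basement_membrane",
    "EpidermalSurface": "epidermal_surface",
    "HairFollicle": "hair_follicles",
    "Epidermis": "epidermis",
}


def write_annotations_geojson(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as a classified FeatureCollection (µm)."""

    def feature(geom, name):
        return {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"classification": {"name": name}},
        }

    features = (
        [feature(g, "BasementMembrane") for g in annotations.basement_membrane]
        + [feature(g, "EpidermalSurface") for g in annotations.epidermal_surface]
        + [feature(g, "HairFollicle") for g in annotations.hair_follicles]
        + [feature(annotations.epidermis, "Epidermis")]
    )
    doc = {"type": "FeatureCollection", "metadata": {"units": MICRON}, "features": features}
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_annotations_geojson(
    path: str | Path, pixel_size: float | None = None
) -> AnnotationSet:
    """Read classified annotation geometry from a GeoJSON FeatureCollection.

    Features are routed by ``properties.classification.name``; several
    basement-membrane or surface segments are allowed; hair follicles are
    optional.  If the collection declares pixel units, coordinates are
    scaled by ``pixel_size``.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise ParameterError(f"{path}: expected a GeoJSON FeatureCollection")
    scale = 1.0
    units = (doc.get("metadata") or {}).get("units", MICRON)
    if units in ("px", "pixel", "pixels"):
        if pixel_size is None:
            raise ParameterError(f"{path}: coordinates are in pixels; pass pixel_size")
        scale = pixel_size

    buckets: dict[str, list] = {v: [] for v in _CLASS_NAMES.values()}
    for feat in doc.get("features", []):
        name = ((feat.get("properties") or {}).get("classification") or {}).get("name")
        if name not in _CLASS_NAMES:
            continue
        geom = shape(feat["geometry"])
        if scale != 1.0:
            import shapely.affinity as aff

            geom = aff.scale(geom, xfact=scale, yfact=scale, origin=(0, 0))
        if isinstance(geom, LineString) and len(geom.coords) < 2:
            raise ParameterError(f"{path}: {name} polyline has fewer than 2 vertices")
        buckets[_CLASS_NAMES[name]].append(geom)

    if not buckets["basement_membrane"] or not buckets["epidermal_surface"]:
        raise ParameterError(
            f"{path}: both BasementMembrane and EpidermalSurface features are "
            "required (epidermal thickness is undefined without them)"
        )
    if buckets["epidermis"]:
        epidermis = buckets["epidermis"][0]
    else:
        # reconstruct the region between the borders if it was not exported
        from shapely.ops import unary_union

        epidermis = unary_union(
            [g.buffer(1.0) for g in buckets["basement_membrane"] + buckets["epidermal_surface"]]
        ).convex_hull
    return AnnotationSet(
        basement_membrane=buckets["basement_membrane"],
        epidermal_surface=buckets["epidermal_surface"],
        hair_follicles=buckets["hair_follicles"],
        epidermis=epidermis if isinstance(epidermis, Polygon) else Polygon(epidermis),
    )


# ---------------------------------------------------------------------------
# OME-TIFF

def write_ome_tiff(
    image: np.ndarray,
    path: str | Path,
    channel_names: tuple[str, ...],
    pixel_size: float,
) -> None:
    """Write a (C, Y, X) image as OME-TIFF with channel names and µm calibration."""
    import tifffile

    tifffile.imwrite(
        path,
        image.astype(np.float32),
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(channel_names)},
            "PhysicalSizeX": pixel_size,
            "PhysicalSizeXUnit": MICRON,
            "PhysicalSizeY": pixel_size,
            "PhysicalSizeYUnit": MICRON,
        },
        ome=True,
    )


def read_ome_tiff(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an OME-TIFF written by :func:`write_ome_tiff`; returns (image, meta)."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        image = tf.asarray()
        meta: dict = {}
        if tf.ome_metadata:
            m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
            if m:
                meta["pixel_size"] = float(m.group(1))
            meta["channel_names"] = re.findall(r'Channel[^>]*Name="([^"]+)"', tf.ome_metadata)
    return image, meta
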