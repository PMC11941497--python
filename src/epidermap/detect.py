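"""Classical nuclei detection for synthetic renders.

A deliberately simple detector: Gaussian smoothing, a global Otsu
threshold on the DAPI channel, hole filling, then a watershed split
seeded on distance-transform maxima.  Per-object features mirror the
measurement-table contract: area (µm²), perimeter (Crofton estimate,
µm), circularity ``4*pi*A/P^2``, centroid (µm), and Min / Median / Mean /
SD / Max intensity over the object mask for every channel.

This is not a learned segmenter and makes no attempt at parity with
star-convex neural models on real tissue; it exists so rendered
synthetic images can be pushed through the full pipeline with known
ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .datatypes import ParameterError


def detect_nuclei_simple(
    image: np.ndarray,
    pixel_size: float,
    dapi_channel: int = 0,
    channel_names: tuple[str, ...] = ("dapi", "brdu", "ki67"),
    smooth_sigma: float = 1.0,
    min_area: float = 8.0,
    min_peak_distance: float = 3.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei in a (C, Y, X) image and measure per-object features.

    Parameters
    ----------
    image : ndarray, shape (C, Y, X)
        Multi-channel image; ``dapi_channel`` indexes the nuclear stain.
    pixel_size : float
        µm per pixel; converts pixel measurements to µm/µm².
    min_area : float
        Objects smaller than this (µm²) are dropped.
    min_peak_distance : float
        Minimum distance (µm) between watershed seeds.

    Returns
    -------
    (labels, table)
        Integer label mask and one table row per detected object.
    """
    if image.ndim != 3:
        raise ParameterError("expected a (C, Y, X) multi-channel image")
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")

    dapi = image[dapi_channel].astype(float)
    smoothed = gaussian(dapi, sigma=smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:  # constant image: nothing to detect
        return np.zeros(dapi.shape, dtype=np.int32), _empty_table(channel_names)
    thresh = threshold_otsu(smoothed)
    binary = smoothed > thresh
    binary = ndi.binary_fill_holes(binary)

    distance = ndi.distance_transform_edt(binary)
    min_dist_px = max(int(round(min_peak_distance / pixel_size)), 1)
    peaks = peak_local_max(
        distance, min_distance=min_dist_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(ndi.binary_dilation(markers > 0, iterations=1))
    labels = watershed(-distance, markers=markers, mask=binary).astype(np.int32)

    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        area = prop.area * pixel_size**2
        if area < min_area:
            continue
        perimeter = prop.perimeter_crofton * pixel_size
        circ = min(4 * np.pi * area / perimeter**2, 1.0) if perimeter > 0 else np.nan
        cy, cx = prop.centroid
        row = {
            "nucleus_id": next_id,
            "centroid_x": cx * pixel_size,
            "centroid_y": cy * pixel_size,
            "area": area,
            "perimeter": perimeter,
            "circularity": circ,
        }
        mask = labels[prop.slice] == prop.label
        for ci, name in enumerate(channel_names):
            values = image[ci][prop.slice][mask]
            row[f"{name}_min"] = float(values.min())
            row[f"{name}_median"] = float(np.median(values))
            row[f"{name}_mean"] = float(values.mean())
            row[f"{name}_sd"] = float(values.std())
            row[f"{name}_max"] = float(values.max())
        rows.append(row)
        keep[prop.label] = next_id
        next_id += 1

    relabeled = keep[labels]
    return relabeled, pd.DataFrame(rows) if rows else _empty_table(channel_names)


def _empty_table(channel_names: tuple[str, ...]) -> pd.DataFrame:
    cols = ["nucleus_id", "centroid_x", "centroid_y", "area", "perimeter", "circularity"]
    for name in channel_names:
        cols += [f"{name}_{s}" for s in ("min", "median", "mean", "sd", "max")]
    return pd.DataFrame(columns=cols)
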