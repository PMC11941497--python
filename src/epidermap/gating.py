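"""Marker-positivity gating and assembly of the clustering matrix.

Positivity for a channel is called by thresholding its mean nuclear
intensity.  The default method applies Otsu's criterion to
``log1p(mean)`` — deterministic and parameter-free, and because the log
turns intensity rescaling into a near-shift, the resulting positive set
is invariant to the arbitrary units of the acquisition.  A
two-component Gaussian-mixture threshold (``gmm2``) and a manual cutoff
are available for sensitivity analysis.

Nuclei negative for both BrdU and Ki67 carry no proliferation signal
and are removed before clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .datatypes import CLUSTER_FEATURES, GatingResult, ParameterError

log = logging.getLogger(__name__)


def _otsu_threshold_log(values: np.ndarray) -> float:
    t_log = threshold_otsu(np.log1p(values))
    return float(np.expm1(t_log))


def _gmm2_threshold_log(values: np.ndarray, seed: int = 0) -> float:
    from scipy.optimize import brentq
    from sklearn.mixture import GaussianMixture

    x = np.log1p(values).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(x)
    mu = gm.means_.ravel()
    lo, hi = np.sort(mu)

    def posterior_diff(t: float) -> float:
        resp = gm.predict_proba(np.array([[t]]))[0]
        order = np.argsort(mu)
        return resp[order[1]] - resp[order[0]]

    if lo == hi:
        t_log = lo
    else:
        try:
            t_log = brentq(posterior_diff, lo, hi)
        except ValueError:  # posteriors do not cross between the means
            t_log = (lo + hi) / 2
    return float(np.expm1(t_log))


def call_positivity(
    table: pd.DataFrame,
    channel: str,
    method: str = "otsu",
    manual_threshold: float | None = None,
    per_section: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[GatingResult]]:
    """Flag ``<channel>_pos`` by intensity thresholding of ``<channel>_mean``.

    By default the threshold is computed per section (staining background
    varies between slides); set ``per_section=False`` for one global
    threshold.  A constant intensity vector yields an all-negative call
    with a degeneracy warning, since no separation exists.
    """
    col = f"{channel}_mean"
    if col not in table.columns:
        raise ParameterError(f"column {col!r} not present")
    if method not in ("otsu", "gmm2", "manual"):
        raise ParameterError(f"unknown gating method {method!r}")
    if method == "manual" and manual_threshold is None:
        raise ParameterError("manual gating requires manual_threshold")

    out = table.copy()
    flags = np.zeros(len(out), dtype=bool)
    results = []
    if per_section and "section_id" in out.columns:
        groups = list(out.groupby("section_id").groups.items())
    else:
        groups = [("all", out.index)]
    for section, idx in groups:
        values = out.loc[idx, col].to_numpy(dtype=float)
        degenerate = np.ptp(values) == 0
        if degenerate:
            log.warning(
                "%s/%s: constant intensity vector; calling all nuclei negative", section, channel
            )
            thr = float(values[0]) if len(values) else 0.0
            pos = np.zeros(len(values), dtype=bool)
        else:
            if method == "otsu":
                thr = _otsu_threshold_log(values)
            elif method == "gmm2":
                thr = _gmm2_threshold_log(values, seed=seed)
            else:
                thr = float(manual_threshold)
            pos = values > thr
        flags[out.index.get_indexer(idx)] = pos
        results.append(
            GatingResult(
                channel=channel, threshold=thr, method=method,
                n_positive=int(pos.sum()), n_negative=int(len(pos) - pos.sum()),
                degenerate=bool(degenerate),
            )
        )
    out[f"{channel}_pos"] = flags
    return out, results


def filter_double_negatives(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop nuclei negative for both BrdU and Ki67 (no proliferation signal)."""
    for col in ("brdu_pos", "ki67_pos"):
        if col not in table.columns:
            raise ParameterError(f"positivity flag {col!r} missing; run call_positivity first")
    keep = table["brdu_pos"].to_numpy() | table["ki67_pos"].to_numpy()
    report = {
        "n_input": int(len(table)),
        "n_retained": int(keep.sum()),
        "n_double_negative": int((~keep).sum()),
    }
    if report["n_retained"] == 0:
        raise ParameterError(
            "all nuclei are BrdU-/Ki67- double negatives; review gating thresholds"
        )
    log.info(
        "double-negative filter: retained %d / %d nuclei", report["n_retained"], report["n_input"]
    )
    return table.loc[keep].reset_index(drop=True), report


def select_clustering_features(
    table: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble the fixed clustering matrix [brdu_mean, ki67_mean, area, circularity].

    Rows with any non-finite value in the four features are dropped with a
    logged count.  Returns the (n, 4) matrix and the matching table rows.
    """
    missing = [c for c in CLUSTER_FEATURES if c not in table.columns]
    if missing:
        raise ParameterError(f"clustering feature column(s) missing: {missing}")
    X = table.loc[:, list(CLUSTER_FEATURES)].to_numpy(dtype=float)
    finite = np.isfinite(X).all(axis=1)
    if not finite.all():
        log.warning("dropping %d row(s) with non-finite clustering features", int((~finite).sum()))
    return X[finite], table.loc[finite].reset_index(drop=True)
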