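"""k-means discovery of basal-cell archetypes and its diagnostics.

The four clustering features (BrdU mean, Ki67 mean, nuclear area,
circularity) are z-scored and clustered with k-means (k-means++
initialization, best of ``n_init`` restarts by within-cluster sum of
squares).  The cluster count is selected jointly: the Elbow rule picks
the k with the largest second difference of the WSS curve, the
Silhouette rule the k with the highest mean silhouette; when they
disagree the silhouette choice wins (it is the sharper criterion on
these data) and the disagreement is logged.

Recovered clusters are given stable identities by matching their median
z-score profiles against the four archetype signatures (label-retaining
inter-ridge cells, large rete-ridge cells, small elongated cells, mixed
cells) with an exhaustive one-to-one assignment, so cluster numbers are
comparable across sections and timepoints.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import CLUSTER_FEATURES, ClusterModel, ParameterError

log = logging.getLogger(__name__)

#: archetype signatures over (brdu_mean, ki67_mean, area, circularity):
#: +1 high, -1 low, 0 medium / mixed; "elongated" = low circularity
ARCHETYPE_SIGNATURES = {
    1: np.array([-1.0, -1.0, 0.0, 1.0]),   # low BrdU/Ki67, medium round
    2: np.array([-1.0, -1.0, -1.0, -1.0]),  # small elongated
    3: np.array([1.0, 0.0, 0.0, 1.0]),      # high BrdU (label-retaining)
    4: np.array([-1.0, 0.0, 1.0, 1.0]),     # large nuclei
}

DEFAULT_K_CANDIDATES = tuple(range(2, 9))


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column z-scores; returns (Z, means, sds)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(X).all():
        raise ParameterError("standardize requires finite values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        zero = np.flatnonzero(sds == 0).tolist()
        raise ParameterError(f"zero-variance column(s) {zero}; cannot standardize")
    return (X - means) / sds, means, sds


def kmeans_fit(
    X: np.ndarray, k: int, seed: int = 0, n_init: int = 20
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` k-means++ fit; returns (labels, centroids, WSS)."""
    X = np.asarray(X, dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ParameterError(f"k={k} exceeds the {n_distinct} distinct points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed).fit(X)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def select_k_elbow(wss_by_k: dict[int, float]) -> int:
    """Interior k maximizing the second difference of the WSS curve.

    Requires at least three consecutive candidate k.  Exact ties go to
    the smallest k with a logged warning.
    """
    ks = sorted(wss_by_k)
    if len(ks) < 3:
        raise ParameterError("elbow selection needs >= 3 consecutive k values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ParameterError("elbow selection needs consecutive k values")
    curvature = {
        k: (wss_by_k[k - 1] - wss_by_k[k]) - (wss_by_k[k] - wss_by_k[k + 1])
        for k in ks[1:-1]
    }
    best = max(curvature.values())
    winners = [k for k in sorted(curvature) if curvature[k] == best]
    if len(winners) > 1:
        log.warning("elbow tie among k=%s; taking the smallest", winners)
    return winners[0]


def select_k_silhouette(
    X: np.ndarray, k_candidates=DEFAULT_K_CANDIDATES, seed: int = 0, n_init: int = 20,
    sample_size: int | None = None,
) -> tuple[int, dict[int, float]]:
    """k maximizing the mean silhouette (Euclidean); per-k scores returned."""
    X = np.asarray(X, dtype=float)
    scores: dict[int, float] = {}
    for k in k_candidates:
        if not 2 <= k <= len(X) - 1:
            raise ParameterError(f"k={k} outside [2, n-1]")
        labels, _, _ = kmeans_fit(X, k, seed=seed, n_init=n_init)
        scores[k] = float(
            silhouette_score(X, labels, sample_size=sample_size, random_state=seed)
        )
    best = max(scores.values())
    winners = [k for k in sorted(scores) if scores[k] == best]
    return winners[0], scores


def choose_k(elbow_k: int, silhouette_k: int, forced_k: int | None = None) -> int:
    """Joint selection policy: agreement wins; otherwise silhouette, logged."""
    if forced_k is not None:
        return forced_k
    if elbow_k != silhouette_k:
        log.info(
            "elbow (k=%d) and silhouette (k=%d) disagree; taking silhouette",
            elbow_k, silhouette_k,
        )
    return silhouette_k


def match_archetypes(labels: np.ndarray, Z: np.ndarray) -> dict[int, int]:
    """Assign archetype identities to k-means clusters by signature matching.

    Scores each cluster's median z-profile against each archetype
    signature (dot product) and takes the one-to-one assignment with
    maximal total agreement, enumerated exactly over the 24 permutations
    when k=4.  With k != 4 only the best-scoring injective assignment of
    clusters to archetypes is returned, with a warning.
    """
    uniq = np.unique(labels)
    profiles = {c: np.median(Z[labels == c], axis=0) for c in uniq}
    arch_ids = sorted(ARCHETYPE_SIGNATURES)
    if len(uniq) != 4:
        log.warning("matching %d clusters onto 4 archetype signatures", len(uniq))

    score = {
        (c, a): float(profiles[c] @ ARCHETYPE_SIGNATURES[a]) for c in uniq for a in arch_ids
    }
    for c1, c2 in itertools.combinations(uniq, 2):
        if np.allclose(profiles[c1], profiles[c2]):
            raise ParameterError(
                f"clusters {c1} and {c2} have identical median profiles; "
                "archetype assignment is ambiguous"
            )
    n_assign = min(len(uniq), len(arch_ids))
    best_assign, best_total = None, -np.inf
    for subset in itertools.combinations(uniq, n_assign):
        for perm in itertools.permutations(arch_ids, n_assign):
            total = sum(score[(c, a)] for c, a in zip(subset, perm))
            if total > best_total:
                best_total, best_assign = total, dict(zip(subset, perm))
    mapping = {int(c): int(a) for c, a in best_assign.items()}
    # surplus clusters (k > 4) each take their individually best signature
    for c in uniq:
        if int(c) not in mapping:
            mapping[int(c)] = int(max(arch_ids, key=lambda a: score[(c, a)]))
    return mapping


def pca_project(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First two principal components of the standardized feature matrix.

    Returns (scores (n, 2), loadings (2, p) orthonormal rows, variance
    explained fractions).
    """
    pca = PCA(n_components=2)
    scores = pca.fit_transform(np.asarray(Z, dtype=float))
    return scores, pca.components_, pca.explained_variance_ratio_


def fit_cluster_model(
    X: np.ndarray,
    k_candidates=DEFAULT_K_CANDIDATES,
    seed: int = 0,
    n_init: int = 20,
    forced_k: int | None = None,
    silhouette_sample_size: int | None = None,
    log_intensities: bool = True,
) -> ClusterModel:
    """Full clustering stage: transform, standardize, sweep k, select, fit, match.

    Fluorescence intensities are log-normal, so by default the two
    intensity columns are log-transformed before z-scoring; area and
    circularity enter on their natural scale.
    """
    X = np.asarray(X, dtype=float)
    feature_names = list(CLUSTER_FEATURES)
    if log_intensities:
        X = X.copy()
        X[:, :2] = np.log(X[:, :2])
        feature_names[:2] = [f"log_{c}" for c in feature_names[:2]]
    Z, means, sds = standardize(X)
    ks = sorted(set(k_candidates) | {min(k_candidates) - 1, max(k_candidates) + 1})
    ks = [k for k in ks if k >= 1]
    wss = {}
    for k in ks:
        _, _, w = kmeans_fit(Z, k, seed=seed, n_init=n_init)
        wss[k] = w
    elbow_k = select_k_elbow(wss)
    sil_k, sil = select_k_silhouette(
        Z, k_candidates, seed=seed, n_init=n_init, sample_size=silhouette_sample_size
    )
    k = choose_k(elbow_k, sil_k, forced_k)
    labels, centroids, _ = kmeans_fit(Z, k, seed=seed, n_init=n_init)
    archetype_map = match_archetypes(labels, Z)
    return ClusterModel(
        feature_names=tuple(feature_names),
        feature_means=means,
        feature_sds=sds,
        k_candidates=tuple(k_candidates),
        wss_by_k=wss,
        silhouette_by_k=sil,
        elbow_k=elbow_k,
        silhouette_k=sil_k,
        chosen_k=k,
        centroids=centroids,
        labels=labels,
        archetype_map=archetype_map,
        seed=seed,
        n_init=n_init,
    )
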