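"""End-to-end orchestration: geometry covariates, gating, clustering, space.

:func:`analyze_section` is the library entry point: it takes a nucleus
table plus annotations and carries them through covariate computation,
basal-layer filtering, relief classification, BrdU/Ki67 gating,
double-negative removal, feature assembly, k selection, k-means and
archetype matching.  :func:`run_pipeline` wraps it (and the simulation
presets) as a reproducible run directory with config echo, summary
tables and a log — the shell-facing counterpart used by the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import gating as gating_mod
from . import geometry as geometry_mod
from . import spatial as spatial_mod
from .datatypes import AnnotationSet, ClusterModel, ParameterError
from .synthetic import SyntheticDataset, TissueParams, generate_dataset, generate_timecourse

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    measurements: str | None = None
    annotations: str | None = None
    preset: str | None = None  # homeostasis | timecourse (simulate instead of read)
    n: int = 2000
    pattern_strength: float = 1.0
    pixel_size: float | None = None
    max_dist_bm: float = geometry_mod.DEFAULT_MAX_DIST_BM
    gating_method: str = "otsu"
    manual_thresholds: dict = field(default_factory=dict)
    per_section_gating: bool = True
    k: str | int = "auto"
    k_min: int = 2
    k_max: int = 8
    seed: int = 0
    n_init: int = 20
    hf_edges: tuple = spatial_mod.DEFAULT_HF_EDGES
    out_dir: str = "epidermap_run"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hf_edges"] = [float(e) for e in self.hf_edges]
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        if "hf_edges" in data:
            data["hf_edges"] = tuple(float(e) for e in data["hf_edges"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SectionResult:
    """Everything :func:`analyze_section` computed for one section."""

    table: pd.DataFrame  # basal nuclei; cluster label NA for non-gated rows
    model: ClusterModel | None
    reports: dict
    pca_scores: np.ndarray | None = None
    pca_loadings: np.ndarray | None = None
    pca_variance: np.ndarray | None = None

    @property
    def gated(self) -> pd.DataFrame:
        return self.table.loc[self.table["cluster"].notna()]


def analyze_section(
    table: pd.DataFrame,
    annotations: AnnotationSet,
    max_dist_bm: float = geometry_mod.DEFAULT_MAX_DIST_BM,
    gating_method: str = "otsu",
    manual_thresholds: dict | None = None,
    per_section_gating: bool = True,
    k_candidates=cluster_mod.DEFAULT_K_CANDIDATES,
    forced_k: int | None = None,
    seed: int = 0,
    n_init: int = 20,
    cluster_labels: bool = True,
) -> SectionResult:
    """Run the full per-section analysis on a nucleus table.

    Returns the basal-layer table augmented with geometric covariates,
    relief categories, positivity flags and archetype-matched cluster
    labels (NA for nuclei excluded as double negatives), plus the fitted
    :class:`ClusterModel` and stage reports.
    """
    reports: dict = {}
    work = geometry_mod.compute_covariates(table, annotations)
    work, reports["basal_filter"] = geometry_mod.basal_layer_filter(work, max_dist_bm)
    work = geometry_mod.classify_relief(work)

    manual_thresholds = manual_thresholds or {}
    gating_results = {}
    for channel in ("brdu", "ki67"):
        work, res = gating_mod.call_positivity(
            work,
            channel,
            method=gating_method,
            manual_threshold=manual_thresholds.get(channel),
            per_section=per_section_gating,
            seed=seed,
        )
        gating_results[channel] = res
    reports["gating"] = gating_results

    gated, reports["double_negative_filter"] = gating_mod.filter_double_negatives(work)

    work["cluster"] = pd.Series(pd.NA, index=work.index, dtype="Int64")
    model = None
    pca_scores = pca_loadings = pca_var = None
    if cluster_labels:
        X, matched = gating_mod.select_clustering_features(gated)
        model = cluster_mod.fit_cluster_model(
            X,
            k_candidates=k_candidates,
            seed=seed,
            n_init=n_init,
            forced_k=forced_k,
        )
        archetype_labels = np.array([model.archetype_map[l] for l in model.labels])
        lookup = pd.Series(archetype_labels, index=matched["nucleus_id"].to_numpy())
        mask = work["nucleus_id"].isin(lookup.index)
        work.loc[mask, "cluster"] = work.loc[mask, "nucleus_id"].map(lookup).astype("Int64")
        Xt = X.copy()
        if model.feature_names[0].startswith("log_"):
            Xt[:, :2] = np.log(Xt[:, :2])
        Z = (Xt - model.feature_means) / model.feature_sds
        pca_scores, pca_loadings, pca_var = cluster_mod.pca_project(Z)
    return SectionResult(
        table=work,
        model=model,
        reports=reports,
        pca_scores=pca_scores,
        pca_loadings=pca_loadings,
        pca_variance=pca_var,
    )


def analyze_dataset(dataset: SyntheticDataset, **kwargs) -> SectionResult:
    """Shorthand: :func:`analyze_section` on a synthetic dataset."""
    return analyze_section(dataset.nuclei, dataset.annotations, **kwargs)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(
                    f"stage '{name}' failed: {exc} "
                    f"(fix the stage input or config and re-run)"
                ) from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run per config; returns the output directory.

    Every output directory carries the effective config (YAML) and its
    hash; identical configs give byte-identical summary tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("epidermap")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _write_config(config: RunConfig, out: Path) -> None:
    effective = config.to_dict()
    effective["config_hash"] = config.config_hash()
    (out / "config.yaml").write_text(yaml.safe_dump(effective), encoding="utf-8")


def _run(config: RunConfig, out: Path) -> None:
    from .qupath_io import read_annotations_geojson, read_qupath_measurements

    _write_config(config, out)
    k_candidates = tuple(range(config.k_min, config.k_max + 1))
    forced_k = None if config.k == "auto" else int(config.k)

    with _stage("input"):
        if config.preset == "timecourse":
            datasets = generate_timecourse(seed=config.seed, n=config.n)
            sections = {tp: (ds.nuclei, ds.annotations) for tp, ds in datasets.items()}
        elif config.preset in ("homeostasis", "simulate", None) and config.measurements is None:
            ds = generate_dataset(
                n=config.n, pattern_strength=config.pattern_strength, seed=config.seed
            )
            sections = {"homeostasis": (ds.nuclei, ds.annotations)}
        else:
            if not config.measurements or not config.annotations:
                raise ParameterError("measurements and annotations paths are both required")
            table = read_qupath_measurements(config.measurements, pixel_size=config.pixel_size)
            ann = read_annotations_geojson(config.annotations, pixel_size=config.pixel_size)
            sections = {"input": (table, ann)}

    processed: dict[str, SectionResult] = {}
    for name, (table, ann) in sections.items():
        with _stage(f"analyze[{name}]"):
            processed[name] = analyze_section(
                table,
                ann,
                max_dist_bm=config.max_dist_bm,
                gating_method=config.gating_method,
                manual_thresholds=config.manual_thresholds,
                per_section_gating=config.per_section_gating,
                k_candidates=k_candidates,
                forced_k=forced_k,
                seed=config.seed,
                n_init=config.n_init,
            )

    with _stage("spatial"):
        for name, res in processed.items():
            res.table.to_csv(out / f"nuclei_{name}.csv", index=False)
            if res.model is not None:
                (out / f"cluster_model_{name}.json").write_text(
                    json.dumps(res.model.to_dict(), indent=1), encoding="utf-8"
                )
            gated = res.gated
            if gated["dist_hf"].notna().any():
                grouping = spatial_mod.bin_by_hf_distance(gated, edges=config.hf_edges)
                grouping.summary.to_csv(out / f"hf_groups_{name}.csv", index=False)
            profile = spatial_mod.cluster_space_profile(gated)
            profile.summary.to_csv(out / f"cluster_profile_{name}.csv", index=False)

    if len(processed) > 1:
        with _stage("timecourse"):
            tc = spatial_mod.timecourse_summary({n: r.table for n, r in processed.items()})
            tc.per_timepoint.to_csv(out / "timecourse.csv", index=False)
            tc.cluster_profiles.to_csv(out / "timecourse_clusters.csv", index=False)
            tc.composition.to_csv(out / "timecourse_composition.csv", index=False)
    log.info("run complete: %s", out)
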