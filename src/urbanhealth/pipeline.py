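"""End-to-end orchestration: raster in, cluster map and statistics out.

Stages run in a fixed order — tiling, boundary/white filtering, areal
linkage of tract indexes onto kept tiles, feature extraction, silhouette
k-means, association statistics, optional human-agreement analysis, and
cluster-map export.  Every artifact is written to the output directory in
a plain text format and listed, with its SHA-256 checksum, in a run
manifest; identical configuration and seeds reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import areal, clustering, embedding, stats, tiling
from .geo import read_geojson_features, read_geojson_geometry, read_raster, write_geojson_features

__all__ = ["PipelineConfig", "run_pipeline", "export_cluster_map"]

log = logging.getLogger("urbanhealth.pipeline")


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds of one pipeline run."""

    raster_path: str
    boundary_path: str
    tracts_path: str
    indexes_path: str
    rater_labels_path: str | None = None
    tile_size: int = tiling.DEFAULT_TILE_SIZE
    min_inside: float = tiling.DEFAULT_MIN_INSIDE
    max_white: float = tiling.DEFAULT_MAX_WHITE
    white_threshold: int = tiling.DEFAULT_WHITE_THRESHOLD
    extractor: str = "baseline-histogram"
    k_min: int = clustering.DEFAULT_K_MIN
    k_max: int = clustering.DEFAULT_K_MAX
    n_reruns: int = clustering.DEFAULT_N_RERUNS
    seeds: dict[str, int] = field(
        default_factory=lambda: {"kmeans": 0, "tsne": 0, "embedding": 0}
    )
    out_dir: str = "out"

    def __post_init__(self) -> None:
        if not (0 <= self.min_inside <= 1 and 0 <= self.max_white <= 1):
            raise ValueError("filter thresholds must lie in [0, 1]")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        doc = tomllib.loads(Path(path).read_text())
        flat: dict = {}
        for section in ("inputs", "params", "output"):
            flat.update(doc.get(section, {}))
        flat.update({k: v for k, v in doc.items() if not isinstance(v, dict)})
        if "seeds" in doc:
            flat["seeds"] = dict(doc["seeds"])
        return cls(**flat)


def _extractor_by_name(name: str) -> embedding.ExtractorSpec:
    if name == "baseline-histogram":
        return embedding.baseline_extractor()
    raise ValueError(f"unknown extractor {name!r}")


def export_cluster_map(tiles, labels, path: str | Path) -> None:
    """Write one polygon feature per kept tile with its cluster id.

    Excluded tiles carry no feature, so the map shows them uncolored.
    """
    if len(tiles) != len(labels):
        raise ValueError("labels must cover all kept tiles")
    feats = [
        (
            {
                "tile_id": t.tile_id,
                "cluster": int(lab),
                "greenness": embedding.greenness(t),
            },
            t.footprint,
        )
        for t, lab in zip(tiles, labels)
    ]
    write_geojson_features(path, feats)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_tracts(config: PipelineConfig) -> areal.TractTable:
    feats = read_geojson_features(config.tracts_path)
    tract_ids = [str(props["tract_id"]) for props, _ in feats]
    polygons = [geom for _, geom in feats]
    values = pd.read_csv(config.indexes_path, dtype={"tract_id": str}).set_index("tract_id")
    values = values.select_dtypes(include=[np.number])
    return areal.TractTable(tract_ids=tract_ids, polygons=polygons, values=values)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    # --- tiling & filtering ---------------------------------------------
    s = stage("tiling")
    raster = read_raster(config.raster_path)
    boundary = read_geojson_geometry(config.boundary_path)
    tiles = tiling.split_raster(raster, config.tile_size, config.white_threshold)
    kept = tiling.filter_tiles(tiles, boundary, config.min_inside, config.max_white)
    if not kept:
        raise RuntimeError("tiling: no tiles survive the filters")
    manifest_df = tiling.tile_manifest(tiles, kept)
    done(s)

    # --- areal linkage ---------------------------------------------------
    s = stage("areal_linkage")
    tracts = _load_tracts(config)
    block_idx = areal.link_blocks(kept, tracts)
    artifacts["block_indexes"] = out / "block_indexes.csv"
    block_idx.to_csv(artifacts["block_indexes"], index=False)
    done(s)

    # --- embedding -------------------------------------------------------
    s = stage("embedding")
    extractor = _extractor_by_name(config.extractor)
    features = embedding.extract_features(kept, extractor)
    artifacts["features"] = out / "features.csv"
    features.to_frame().to_csv(artifacts["features"], index=False)
    artifacts["features_meta"] = out / "features_meta.json"
    artifacts["features_meta"].write_text(
        json.dumps(
            {
                "extractor": extractor.name,
                "dimension": extractor.dimension,
                "deterministic": extractor.deterministic,
                "seeds": config.seeds,
            },
            indent=2,
        )
    )
    done(s)

    # --- clustering ------------------------------------------------------
    s = stage("clustering")
    green = np.array([embedding.greenness(t) for t in kept])
    result = clustering.kmeans_grid_search(
        features,
        k_min=config.k_min,
        k_max=config.k_max,
        n_reruns=config.n_reruns,
        seed=config.seeds.get("kmeans", 0),
        greenness_scores=green,
    )
    kept_labels = pd.Series(result.labels, index=[t.tile_id for t in kept])
    manifest_df["cluster"] = manifest_df["tile_id"].map(kept_labels).astype("Int64")
    artifacts["tile_manifest"] = out / "tile_manifest.csv"
    manifest_df.to_csv(artifacts["tile_manifest"], index=False)
    artifacts["silhouette"] = out / "silhouette_by_k.csv"
    result.silhouette_by_k.to_csv(artifacts["silhouette"], index=False)
    tsne_map = clustering.tsne_diagnostic(
        features, result.labels, seed=config.seeds.get("tsne", 0)
    )
    artifacts["tsne"] = out / "tsne_coordinates.csv"
    pd.DataFrame(
        {
            "tile_id": features.tile_ids,
            "tsne_x": tsne_map.coordinates[:, 0],
            "tsne_y": tsne_map.coordinates[:, 1],
            "cluster": result.labels,
        }
    ).to_csv(artifacts["tsne"], index=False)
    done(s)

    # --- association statistics -----------------------------------------
    s = stage("association_stats")
    indicators = [c for c in tracts.indicators if c != "dominant_archetype"]
    labels = result.labels
    artifacts["chi2_summary"] = out / "chi2_summary.csv"
    stats.chi2_summary_table(block_idx, labels, indicators).to_csv(
        artifacts["chi2_summary"], index=False
    )
    # univariate multinomial regression per indicator (continuous value),
    # listwise deletion per variable
    uni_rows = []
    for ind in indicators:
        fit = stats.fit_multinomial(block_idx[[ind]], labels, baseline=1)
        tab = fit.table[fit.table["term"] == ind].copy()
        tab.insert(0, "variable", ind)
        tab["aic"] = fit.aic
        tab["converged"] = fit.converged
        uni_rows.append(tab)
    artifacts["univariate_or"] = out / "univariate_or.csv"
    pd.concat(uni_rows, ignore_index=True).to_csv(artifacts["univariate_or"], index=False)
    # multivariate backward stepwise on tertile dummies, group-wise removal
    dummies, groups = [], {}
    for ind in indicators:
        _, cats = stats.discretize_tertiles(block_idx[ind].to_numpy())
        dd = stats.tertile_dummies(cats, ind)
        dd[np.isnan(cats)] = np.nan
        dummies.append(dd)
        groups[ind] = list(dd.columns)
    design = pd.concat(dummies, axis=1)
    selected, final_fit, step_log = stats.backward_stepwise_aic(
        groups, design, labels, baseline=1
    )
    artifacts["stepwise_log"] = out / "stepwise_log.csv"
    step_log.to_csv(artifacts["stepwise_log"], index=False)
    artifacts["multivariate_or"] = out / "multivariate_or.csv"
    final_fit.table.to_csv(artifacts["multivariate_or"], index=False)
    done(s)

    # --- agreement (optional) -------------------------------------------
    agreement_summary = None
    if config.rater_labels_path:
        s = stage("agreement")
        ratings = pd.read_csv(config.rater_labels_path)
        if "rater_id" in ratings.columns:
            pooled = agr.pool_rater_labels(ratings)
        else:
            pooled = ratings.set_index("tile_id")["category"]
        joined = kept_labels.rename("cluster").to_frame().join(
            pooled.rename("human"), how="inner"
        ).dropna()
        confusion = agr.build_confusion(
            joined["human"].astype(int), joined["cluster"].astype(int)
        )
        kappa = agr.cohen_kappa(confusion)
        artifacts["confusion"] = out / "confusion_matrix.csv"
        pd.DataFrame(confusion.counts).to_csv(artifacts["confusion"])
        artifacts["kappa"] = out / "kappa.json"
        agreement_summary = {
            "n_rated": confusion.n,
            "coverage": confusion.n / len(kept),
            "po": kappa.po,
            "pe": kappa.pe,
            "kappa": kappa.kappa,
            "kappa_max": kappa.kappa_max,
            "p_value": kappa.p_value,
            "interpretation": agr.kappa_interpretation(kappa.kappa),
        }
        artifacts["kappa"].write_text(json.dumps(agreement_summary, indent=2))
        done(s)

    # --- cluster map -----------------------------------------------------
    s = stage("cluster_map")
    artifacts["cluster_map"] = out / "cluster_map.geojson"
    export_cluster_map(kept, result.labels, artifacts["cluster_map"])
    done(s)

    manifest = {
        "config": {
            k: (v if not isinstance(v, Path) else str(v))
            for k, v in vars(config).items()
        },
        "n_tiles": len(tiles),
        "n_kept": len(kept),
        "chosen_k": result.chosen_k,
        "stages": list(timings),
        "timings_s": timings,
        "agreement": agreement_summary,
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in artifacts.items()},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
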