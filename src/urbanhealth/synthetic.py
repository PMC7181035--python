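"""Synthetic city generator for end-to-end testing of the analysis pipeline.

Real inputs — aerial imagery, a city boundary, census-tract polygons and
per-tract small-area health estimates — are large and not redistributable,
so this module fabricates a city with the statistical structure the
analysis assumes:

* a georeferenced RGB raster assembled from procedural textures of four
  landscape archetypes (1 = green areas, 2 = residential with small
  houses, 3 = industrial, 4 = residential with large buildings), laid out
  in contiguous tile-aligned patches;
* tract polygons forming an exact tile-aligned partition of the boundary
  (rectangular cells perturbed by random merging), each tract carrying
  indicator values drawn from a Normal centred on its dominant archetype's
  mean;
* a designated "gradient" indicator whose archetype means increase
  strictly from green to heavily built areas, so cluster-health gradients
  are planted and recoverable.

Everything is driven by a single seed; the same configuration and seed
reproduce the city bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .areal import TractTable
from .geo import GeoRaster, WorldTransform, write_geojson_features, write_raster

__all__ = [
    "ArchetypeSpec",
    "SyntheticCityConfig",
    "SyntheticCity",
    "default_archetypes",
    "generate_tile_texture",
    "generate_city",
    "simulate_rater_labels",
    "write_city",
    "GRADIENT_INDICATOR",
]

GRADIENT_INDICATOR = "phys_unhealthy_days"

# per-archetype means on a crude-prevalence-like scale; the gradient
# indicator rises strictly from green (1) to large buildings (4)
_DEFAULT_INDEX_MEANS = {
    GRADIENT_INDICATOR: [2.5, 3.5, 4.5, 5.5],
    "chol_screening": [82.0, 78.0, 74.0, 70.0],
    "obesity": [22.0, 26.0, 27.5, 31.0],
}
_DEFAULT_INDEX_SD = 0.7

# base color, block palette, block edge (px at a 256-pixel tile), target
# fraction of the tile covered by blocks, and per-pixel noise amplitude
_TEXTURES = {
    1: dict(base=(62, 142, 58), blocks=[(40, 110, 42), (80, 165, 72)],
            block_size=24, coverage=0.30, noise=18),
    2: dict(base=(168, 158, 148), blocks=[(190, 120, 90), (205, 168, 142), (150, 96, 72)],
            block_size=10, coverage=0.40, noise=12),
    3: dict(base=(126, 124, 130), blocks=[(92, 92, 104), (158, 156, 160), (110, 108, 118)],
            block_size=24, coverage=0.40, noise=6),
    4: dict(base=(52, 50, 58), blocks=[(30, 28, 34), (96, 94, 102), (16, 14, 20)],
            block_size=32, coverage=0.50, noise=26),
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """One landscape archetype: its procedural texture and indicator levels."""

    archetype_id: int
    texture_params: dict
    index_means: dict[str, float]
    index_sd: float

    def __post_init__(self) -> None:
        if not 1 <= self.archetype_id <= 4:
            raise ValueError("archetype_id must be in 1..4")
        if self.index_sd <= 0:
            raise ValueError("index_sd must be > 0")


def default_archetypes() -> list[ArchetypeSpec]:
    """The four bundled archetypes with a strict gradient in the gradient indicator."""
    return [
        ArchetypeSpec(
            archetype_id=a,
            texture_params=_TEXTURES[a],
            index_means={k: v[a - 1] for k, v in _DEFAULT_INDEX_MEANS.items()},
            index_sd=_DEFAULT_INDEX_SD,
        )
        for a in (1, 2, 3, 4)
    ]


@dataclass
class SyntheticCityConfig:
    raster_rows: int = 5120
    raster_cols: int = 5120
    gsd: float = 2.0  # metres per pixel
    tile_size: int = 256
    n_tracts: int = 100
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.raster_rows < self.tile_size or self.raster_cols < self.tile_size:
            raise ValueError("raster must be at least one tile in each dimension")
        if self.raster_rows % self.tile_size or self.raster_cols % self.tile_size:
            raise ValueError("raster dimensions must be multiples of tile_size")
        if self.n_tracts < 1:
            raise ValueError("n_tracts must be >= 1")
        if self.gsd <= 0:
            raise ValueError("gsd must be > 0")
        ids = [a.archetype_id for a in self.archetypes]
        if len(set(ids)) != len(ids):
            raise ValueError("archetype ids must be unique")


@dataclass
class SyntheticCity:
    raster: GeoRaster
    boundary: Polygon
    tracts: TractTable
    truth_labels: np.ndarray  # (n_tile_rows, n_tile_cols) archetype ids
    tile_size: int
    config: SyntheticCityConfig


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def generate_tile_texture(
    archetype: ArchetypeSpec, rng_state, size: int = 256
) -> np.ndarray:
    """Procedural size × size × 3 texture for one archetype.

    A flat base color with per-pixel noise, overlaid with randomly placed
    square "blocks" from the archetype palette; block edge and count scale
    with the tile size.  Deterministic for a fixed rng state.
    """
    rng = _as_rng(rng_state)
    p = archetype.texture_params
    scale = size / 256
    img = np.empty((size, size, 3), dtype=np.int16)
    img[:] = np.array(p["base"], dtype=np.int16)
    edge = max(2, int(round(p["block_size"] * scale)))
    # enough blocks to hit the target coverage; many small blocks keep the
    # per-tile palette mix stable, so tiles of one archetype form a single
    # unimodal cloud in feature space rather than palette-defined sub-clusters
    n_blocks = max(8, int(round(p["coverage"] * size * size / edge**2)))
    palette = np.array(p["blocks"], dtype=float)
    for _ in range(n_blocks):
        r = int(rng.integers(0, max(1, size - edge)))
        c = int(rng.integers(0, max(1, size - edge)))
        color = palette[int(rng.integers(0, len(palette)))]
        jitter = rng.normal(0, 6, size=3)
        img[r : r + edge, c : c + edge] = np.clip(color + jitter, 0, 255).astype(np.int16)
    img += rng.integers(-p["noise"], p["noise"] + 1, size=img.shape, dtype=np.int16)
    return np.clip(img, 0, 255).astype(np.uint8)


def _archetype_layout(
    n_rows: int, n_cols: int, archetype_ids: list[int], rng: np.random.Generator
) -> np.ndarray:
    """Contiguous patches: each tile cell takes the archetype of its nearest seed."""
    k = len(archetype_ids)
    anchor_fracs = {
        1: [(0.5, 0.5)],
        2: [(0.5, 0.25), (0.5, 0.75)],
        3: [(0.25, 0.25), (0.25, 0.75), (0.75, 0.5)],
        4: [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)],
    }
    fracs = anchor_fracs.get(k) or [
        (float(rng.uniform(0.1, 0.9)), float(rng.uniform(0.1, 0.9))) for _ in range(k)
    ]
    seeds = np.array(
        [
            (
                fr * n_rows + rng.uniform(-0.1, 0.1) * n_rows,
                fc * n_cols + rng.uniform(-0.1, 0.1) * n_cols,
            )
            for fr, fc in fracs
        ]
    )
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
    nearest = np.argmin(d2, axis=2)
    return np.array(archetype_ids)[nearest]


def _tract_partition(
    n_rows: int, n_cols: int, n_tracts: int, rng: np.random.Generator
) -> np.ndarray:
    """Tile-cell -> tract-index map: a rectangular grid merged down to n_tracts."""
    if n_tracts > n_rows * n_cols:
        raise ValueError(
            f"n_tracts={n_tracts} exceeds the {n_rows * n_cols} placeable cells"
        )
    tr = min(n_rows, max(1, int(round(math.sqrt(n_tracts * n_rows / n_cols)))))
    tc = min(n_cols, math.ceil(n_tracts / tr))
    while tr * tc < n_tracts:
        if tr < n_rows:
            tr += 1
        elif tc < n_cols:
            tc += 1
        else:  # pragma: no cover - excluded by the placeable-cells check
            raise AssertionError
    row_edges = np.linspace(0, n_rows, tr + 1).round().astype(int)
    col_edges = np.linspace(0, n_cols, tc + 1).round().astype(int)
    cell = np.empty((n_rows, n_cols), dtype=int)
    for i in range(tr):
        for j in range(tc):
            cell[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]] = i * tc + j
    # merge random adjacent tract pairs until exactly n_tracts remain
    labels = cell.copy()
    current = sorted(set(labels.ravel().tolist()))
    while len(current) > n_tracts:
        a = int(rng.choice(current))
        mask = labels == a
        right = np.zeros_like(mask)
        right[:, 1:] = mask[:, :-1]
        down = np.zeros_like(mask)
        down[1:, :] = mask[:-1, :]
        left = np.zeros_like(mask)
        left[:, :-1] = mask[:, 1:]
        up = np.zeros_like(mask)
        up[:-1, :] = mask[1:, :]
        neighbours = sorted(
            set(labels[(right | down | left | up) & ~mask].ravel().tolist())
        )
        if not neighbours:
            continue
        b = int(rng.choice(neighbours))
        labels[labels == b] = a
        current = sorted(set(labels.ravel().tolist()))
    # relabel densely 0..n_tracts-1 in first-appearance order
    remap = {}
    for v in labels.ravel():
        if v not in remap:
            remap[v] = len(remap)
    return np.vectorize(remap.get)(labels)


def _cells_polygon(
    mask: np.ndarray, transform: WorldTransform, tile_size: int
) -> Polygon | MultiPolygon:
    boxes = [
        transform.pixel_extent(
            i * tile_size, (i + 1) * tile_size, j * tile_size, (j + 1) * tile_size
        )
        for i, j in zip(*np.nonzero(mask))
    ]
    return unary_union(boxes)


def generate_city(config: SyntheticCityConfig) -> SyntheticCity:
    """Build the full synthetic city from one configuration.

    Deterministic: the same config (seed included) returns an identical
    city.  Tract indicator values are Normal(mean of the tract's dominant
    archetype, index_sd); missing values are injected at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    ts = config.tile_size
    n_rows, n_cols = config.raster_rows // ts, config.raster_cols // ts
    archetype_by_id = {a.archetype_id: a for a in config.archetypes}
    layout = _archetype_layout(n_rows, n_cols, sorted(archetype_by_id), rng)

    pixels = np.empty((config.raster_rows, config.raster_cols, 3), dtype=np.uint8)
    for i in range(n_rows):
        for j in range(n_cols):
            tex = generate_tile_texture(archetype_by_id[layout[i, j]], rng, size=ts)
            pixels[i * ts : (i + 1) * ts, j * ts : (j + 1) * ts] = tex

    transform = WorldTransform(
        pixel_size_x=config.gsd, pixel_size_y=-config.gsd,
        origin_x=config.gsd / 2, origin_y=-config.gsd / 2,
    )
    raster = GeoRaster(pixels=pixels, transform=transform)
    boundary = raster.footprint()

    tract_map = _tract_partition(n_rows, n_cols, config.n_tracts, rng)
    tract_ids, polygons, dominant = [], [], []
    for t in range(config.n_tracts):
        mask = tract_map == t
        tract_ids.append(f"tract_{t:04d}")
        polygons.append(_cells_polygon(mask, transform, ts))
        arch_ids, counts = np.unique(layout[mask], return_counts=True)
        dominant.append(int(arch_ids[np.argmax(counts)]))

    indicators = list(next(iter(archetype_by_id.values())).index_means)
    values = {}
    for ind in indicators:
        means = np.array([archetype_by_id[d].index_means[ind] for d in dominant])
        sds = np.array([archetype_by_id[d].index_sd for d in dominant])
        v = rng.normal(means, sds)
        if config.missing_rate > 0:
            v[rng.random(len(v)) < config.missing_rate] = np.nan
        values[ind] = v
    values_df = pd.DataFrame(values, index=pd.Index(tract_ids, name="tract_id"))
    values_df["dominant_archetype"] = dominant

    tracts = TractTable(tract_ids=tract_ids, polygons=polygons, values=values_df)
    return SyntheticCity(
        raster=raster, boundary=boundary, tracts=tracts,
        truth_labels=layout, tile_size=ts, config=config,
    )


def simulate_rater_labels(
    machine_labels, agreement_rate: float, n_categories: int = 4, seed: int = 0
) -> np.ndarray:
    """Synthetic human ratings: agree with the machine label with a fixed
    probability, otherwise pick a different category uniformly."""
    m = np.asarray(machine_labels, dtype=int)
    rng = np.random.default_rng(seed)
    out = m.copy()
    flip = rng.random(len(m)) >= agreement_rate
    for i in np.nonzero(flip)[0]:
        others = [c for c in range(1, n_categories + 1) if c != m[i]]
        out[i] = int(rng.choice(others))
    return out


def write_city(city: SyntheticCity, out_dir: str | Path) -> dict[str, Path]:
    """Persist the city: PNG raster + world file, GeoJSON boundary and
    tracts, and a per-tract indicator CSV keyed by tract_id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "raster": out_dir / "city.png",
        "boundary": out_dir / "boundary.geojson",
        "tracts": out_dir / "tracts.geojson",
        "indexes": out_dir / "indexes.csv",
        "truth": out_dir / "truth_labels.csv",
    }
    write_raster(paths["raster"], city.raster)
    write_geojson_features(paths["boundary"], [({"name": "city"}, city.boundary)])
    write_geojson_features(
        paths["tracts"],
        [({"tract_id": tid}, poly)
         for tid, poly in zip(city.tracts.tract_ids, city.tracts.polygons)],
    )
    city.tracts.values.drop(columns=["dominant_archetype"], errors="ignore").to_csv(
        paths["indexes"]
    )
    n_rows, n_cols = city.truth_labels.shape
    pd.DataFrame(
        {
            "tile_id": [f"tile_{i:04d}_{j:04d}" for i in range(n_rows) for j in range(n_cols)],
            "archetype": city.truth_labels.ravel(),
        }
    ).to_csv(paths["truth"], index=False)
    return paths
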