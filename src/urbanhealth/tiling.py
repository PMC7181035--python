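"""Subdivide a georeferenced raster into square tiles and filter them.

A city raster is cut into a grid of fixed-size square tiles (ceiling rule on
both dimensions, so edge tiles may overhang the raster).  Edge tiles are
zero-padded to full size; padded pixels are excluded from the tile footprint
and counted as white.  Tiles are then filtered jointly on the fraction of
their footprint inside the city boundary (default minimum 0.9) and the
fraction of white pixels (default maximum 0.1), white being all three
channels at or above a near-saturation threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon

from .geo import GeoRaster, WorldTransform, write_raster

__all__ = [
    "Tile",
    "grid_dimensions",
    "tile_world_transform",
    "split_raster",
    "inside_fraction",
    "white_fraction",
    "filter_tiles",
    "compute_inside_fractions",
    "tile_manifest",
    "write_tiles",
]

DEFAULT_TILE_SIZE = 256
DEFAULT_MIN_INSIDE = 0.9
DEFAULT_MAX_WHITE = 0.1
DEFAULT_WHITE_THRESHOLD = 250


@dataclass
class Tile:
    """One fixed-size square block of the parent raster.

    ``pixels`` is always tile_size × tile_size × 3, zero-padded at raster
    edges; ``footprint`` covers only the true (unpadded) extent.
    """

    tile_id: str
    row_index: int
    col_index: int
    pixels: np.ndarray
    transform: WorldTransform
    footprint: Polygon
    n_padded: int = 0
    inside_fraction: float = field(default=float("nan"))
    white_fraction: float = field(default=float("nan"))


def grid_dimensions(
    raster_rows: int, raster_cols: int, tile_size: int = DEFAULT_TILE_SIZE
) -> tuple[int, int]:
    """Number of tile rows and columns covering the raster (ceiling rule)."""
    if raster_rows < 1 or raster_cols < 1 or tile_size < 1:
        raise ValueError("raster dimensions and tile size must be positive")
    return (math.ceil(raster_rows / tile_size), math.ceil(raster_cols / tile_size))


def tile_world_transform(
    parent: WorldTransform, row_index: int, col_index: int,
    tile_size: int = DEFAULT_TILE_SIZE,
) -> WorldTransform:
    """World transform of the tile at grid position (row_index, col_index).

    The tile's origin is the center of its own top-left pixel, i.e. the
    parent origin shifted by a whole number of pixels.
    """
    if parent.rotation_x != 0 or parent.rotation_y != 0:
        raise ValueError("rotated parent transforms are unsupported")
    return WorldTransform(
        pixel_size_x=parent.pixel_size_x,
        pixel_size_y=parent.pixel_size_y,
        origin_x=parent.origin_x + col_index * tile_size * parent.pixel_size_x,
        origin_y=parent.origin_y + row_index * tile_size * parent.pixel_size_y,
    )


def white_fraction(
    tile: Tile, white_threshold: int = DEFAULT_WHITE_THRESHOLD
) -> float:
    """Fraction of tile pixels that are (near-)white, padding included.

    A pixel is white when all three channels are >= white_threshold; padded
    pixels count as white because they stand for unmapped ground.
    """
    px = tile.pixels
    n_total = px.shape[0] * px.shape[1]
    white = np.all(px >= white_threshold, axis=2)
    # padded pixels are zeros, never >= threshold; add them explicitly
    return (int(white.sum()) + tile.n_padded) / n_total


def inside_fraction(
    tile_footprint: Polygon, boundary: Polygon | MultiPolygon
) -> float:
    """Share of the tile footprint's area lying inside the boundary."""
    area = tile_footprint.area
    if area == 0:
        raise ValueError("zero-area tile footprint")
    return tile_footprint.intersection(boundary).area / area


def split_raster(
    raster: GeoRaster,
    tile_size: int = DEFAULT_TILE_SIZE,
    white_threshold: int = DEFAULT_WHITE_THRESHOLD,
) -> list[Tile]:
    """Cut the raster into row-major tiles starting from the top-left corner.

    Returns n_tile_rows × n_tile_cols tiles.  Edge tiles are zero-padded to
    tile_size; their footprint covers only real pixels and the padding is
    counted as white.
    """
    n_rows, n_cols = grid_dimensions(raster.rows, raster.cols, tile_size)
    tiles: list[Tile] = []
    for ti in range(n_rows):
        for tj in range(n_cols):
            r0, c0 = ti * tile_size, tj * tile_size
            r1 = min(r0 + tile_size, raster.rows)
            c1 = min(c0 + tile_size, raster.cols)
            block = np.zeros((tile_size, tile_size, 3), dtype=raster.pixels.dtype)
            block[: r1 - r0, : c1 - c0] = raster.pixels[r0:r1, c0:c1]
            n_padded = tile_size * tile_size - (r1 - r0) * (c1 - c0)
            tile = Tile(
                tile_id=f"tile_{ti:04d}_{tj:04d}",
                row_index=ti,
                col_index=tj,
                pixels=block,
                transform=tile_world_transform(raster.transform, ti, tj, tile_size),
                footprint=raster.transform.pixel_extent(r0, r1, c0, c1),
                n_padded=n_padded,
            )
            tile.white_fraction = white_fraction(tile, white_threshold)
            tiles.append(tile)
    return tiles


def compute_inside_fractions(
    tiles: list[Tile], boundary: Polygon | MultiPolygon
) -> None:
    """Fill each tile's inside_fraction against the city boundary, in place."""
    for tile in tiles:
        tile.inside_fraction = inside_fraction(tile.footprint, boundary)


def filter_tiles(
    tiles: list[Tile],
    boundary: Polygon | MultiPolygon | None = None,
    min_inside: float = DEFAULT_MIN_INSIDE,
    max_white: float = DEFAULT_MAX_WHITE,
) -> list[Tile]:
    """Keep tiles with inside_fraction >= min_inside and white_fraction <= max_white.

    The two rules are applied as one conjunctive filter; order is preserved.
    If ``boundary`` is given, inside fractions are (re)computed first.
    """
    if not 0 <= min_inside <= 1 or not 0 <= max_white <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    if boundary is not None:
        compute_inside_fractions(tiles, boundary)
    return [
        t for t in tiles
        if t.inside_fraction >= min_inside and t.white_fraction <= max_white
    ]


def tile_manifest(tiles: list[Tile], kept: list[Tile]) -> pd.DataFrame:
    """Per-tile table: grid position, filter fractions, and kept flag."""
    kept_ids = {t.tile_id for t in kept}
    return pd.DataFrame(
        {
            "tile_id": [t.tile_id for t in tiles],
            "row": [t.row_index for t in tiles],
            "col": [t.col_index for t in tiles],
            "inside_fraction": [t.inside_fraction for t in tiles],
            "white_fraction": [t.white_fraction for t in tiles],
            "kept": [t.tile_id in kept_ids for t in tiles],
        }
    )


def write_tiles(tiles: list[Tile], out_dir: str | Path) -> list[Path]:
    """Write each tile as PNG plus world file; returns the image paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tile in tiles:
        path = out_dir / f"{tile.tile_id}.png"
        write_raster(path, GeoRaster(pixels=tile.pixels, transform=tile.transform))
        paths.append(path)
    return paths
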