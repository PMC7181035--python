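"""Georeferencing primitives: world transforms, rasters, and vector I/O.

The georeferencing model is the classic ESRI world-file convention: an
axis-aligned affine transform whose origin is the map coordinate of the
*center* of the top-left pixel, with pixel height stored negative for
north-up rasters.  All geometry lives in projected metric coordinates;
geographic (lat/lon) rasters are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape

__all__ = [
    "WorldTransform",
    "GeoRaster",
    "read_world_file",
    "write_world_file",
    "read_raster",
    "write_raster",
    "read_geojson_geometry",
    "write_geojson_features",
    "read_geojson_features",
]

# world-file extension by image extension (e.g. .pgw for .png)
_WORLD_EXT = {".png": ".pgw", ".tif": ".tfw", ".tiff": ".tfw", ".jpg": ".jgw"}


@dataclass(frozen=True)
class WorldTransform:
    """Axis-aligned affine georeferencing of a raster.

    ``origin_x``/``origin_y`` are the map coordinates of the center of the
    top-left pixel; ``pixel_size_y`` is negative for north-up rasters.
    """

    pixel_size_x: float
    pixel_size_y: float
    rotation_x: float = 0.0
    rotation_y: float = 0.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_x <= 0:
            raise ValueError(f"pixel_size_x must be > 0, got {self.pixel_size_x}")
        if self.pixel_size_y >= 0:
            raise ValueError(f"pixel_size_y must be < 0, got {self.pixel_size_y}")
        if self.rotation_x != 0 or self.rotation_y != 0:
            raise ValueError("rotated rasters are unsupported")

    def pixel_center(self, row: float, col: float) -> tuple[float, float]:
        """Map coordinates of the center of pixel (row, col)."""
        return (
            self.origin_x + col * self.pixel_size_x,
            self.origin_y + row * self.pixel_size_y,
        )

    def pixel_extent(self, row0: int, row1: int, col0: int, col1: int) -> Polygon:
        """Footprint polygon of the half-open pixel block [row0:row1, col0:col1].

        The block's edges pass half a pixel outside the border pixel centers,
        so the polygon covers the full ground area of every pixel in it.
        """
        x_min = self.origin_x + (col0 - 0.5) * self.pixel_size_x
        x_max = self.origin_x + (col1 - 0.5) * self.pixel_size_x
        y_top = self.origin_y + (row0 - 0.5) * self.pixel_size_y
        y_bot = self.origin_y + (row1 - 0.5) * self.pixel_size_y
        return box(x_min, min(y_top, y_bot), x_max, max(y_top, y_bot))

    def as_lines(self) -> list[float]:
        """The six world-file values in file order."""
        return [
            self.pixel_size_x,
            self.rotation_x,
            self.rotation_y,
            self.pixel_size_y,
            self.origin_x,
            self.origin_y,
        ]


@dataclass
class GeoRaster:
    """An 8-bit 3-channel raster together with its world transform."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    transform: WorldTransform

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (rows, cols, 3) array, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("raster must have at least one pixel")

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    def footprint(self) -> Polygon:
        """Ground extent of the whole raster."""
        return self.transform.pixel_extent(0, self.rows, 0, self.cols)


def read_world_file(path: str | Path) -> WorldTransform:
    values = [float(line) for line in Path(path).read_text().split()]
    if len(values) != 6:
        raise ValueError(f"world file {path} must have 6 values, got {len(values)}")
    a, rx, ry, d, ox, oy = values
    return WorldTransform(
        pixel_size_x=a, rotation_x=rx, rotation_y=ry,
        pixel_size_y=d, origin_x=ox, origin_y=oy,
    )


def write_world_file(path: str | Path, transform: WorldTransform) -> None:
    Path(path).write_text(
        "".join(f"{v!r}\n" for v in transform.as_lines())
    )


def _world_path_for(image_path: Path) -> Path:
    ext = _WORLD_EXT.get(image_path.suffix.lower(), image_path.suffix + "w")
    return image_path.with_suffix(ext)


def _geotiff_transform(path: Path) -> WorldTransform | None:
    """Read a transform from GeoTIFF ModelPixelScale/ModelTiepoint tags."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        tags = tf.pages[0].tags
        scale = tags.get(33550)  # ModelPixelScaleTag
        tiepoint = tags.get(33922)  # ModelTiepointTag
    if scale is None or tiepoint is None:
        return None
    sx, sy = float(scale.value[0]), float(scale.value[1])
    # tiepoint maps raster (i, j) -> model (x, y); origin convention is the
    # top-left *corner*, so shift by half a pixel to the center.
    i, j = float(tiepoint.value[0]), float(tiepoint.value[1])
    x, y = float(tiepoint.value[3]), float(tiepoint.value[4])
    origin_x = x - (i - 0.5) * sx
    origin_y = y + (j - 0.5) * sy
    return WorldTransform(
        pixel_size_x=sx, pixel_size_y=-sy, origin_x=origin_x, origin_y=origin_y
    )


def read_raster(path: str | Path) -> GeoRaster:
    """Read a GeoTIFF, or a PNG/TIFF image with an ESRI world-file sidecar."""
    path = Path(path)
    pixels = np.asarray(Image.open(path).convert("RGB"))
    transform: WorldTransform | None = None
    if path.suffix.lower() in (".tif", ".tiff"):
        transform = _geotiff_transform(path)
    if transform is None:
        world = _world_path_for(path)
        if not world.exists():
            raise FileNotFoundError(
                f"{path} has no embedded georeferencing and no world file {world}"
            )
        transform = read_world_file(world)
    return GeoRaster(pixels=pixels, transform=transform)


def write_raster(path: str | Path, raster: GeoRaster) -> None:
    """Write the image plus its 6-line ESRI world file."""
    path = Path(path)
    Image.fromarray(raster.pixels.astype(np.uint8)).save(path)
    write_world_file(_world_path_for(path), raster.transform)


def read_geojson_geometry(path: str | Path) -> Polygon | MultiPolygon:
    """Read the first (Multi)Polygon geometry from a GeoJSON file."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        geom = geoms[0] if len(geoms) == 1 else MultiPolygon(
            [g for gg in geoms for g in (gg.geoms if hasattr(gg, "geoms") else [gg])]
        )
    elif doc.get("type") == "Feature":
        geom = shape(doc["geometry"])
    else:
        geom = shape(doc)
    if not isinstance(geom, (Polygon, MultiPolygon)):
        raise ValueError(f"expected Polygon/MultiPolygon in {path}, got {geom.geom_type}")
    return geom


def read_geojson_features(path: str | Path) -> list[tuple[dict, Polygon | MultiPolygon]]:
    """Read (properties, geometry) pairs from a GeoJSON FeatureCollection."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a FeatureCollection")
    return [(f.get("properties") or {}, shape(f["geometry"])) for f in doc["features"]]


def write_geojson_features(
    path: str | Path, features: list[tuple[dict, Polygon | MultiPolygon]]
) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
            for props, geom in features
        ],
    }
    Path(path).write_text(json.dumps(doc))
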