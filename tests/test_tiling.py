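import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from urbanhealth.geo import GeoRaster, WorldTransform
from urbanhealth.tiling import (
    Tile,
    filter_tiles,
    grid_dimensions,
    inside_fraction,
    split_raster,
    tile_world_transform,
    white_fraction,
)


@pytest.mark.parametrize(
    "rows, cols, tile, expected",
    [
        (23972, 23892, 256, (94, 94)),  # the NYC aerial mosaic
        (256, 256, 256, (1, 1)),
        (257, 256, 256, (2, 1)),
        (300, 300, 256, (2, 2)),
    ],
)
def test_grid_dimensions(rows, cols, tile, expected):
    assert grid_dimensions(rows, cols, tile) == expected


def test_grid_dimensions_rejects_nonpositive():
    with pytest.raises(ValueError):
        grid_dimensions(0, 10, 256)


@given(
    rows=st.integers(1, 5000), cols=st.integers(1, 5000), tile=st.integers(1, 512)
)
def test_grid_count_covers_raster(rows, cols, tile):
    nr, nc = grid_dimensions(rows, cols, tile)
    assert nr * tile >= rows > (nr - 1) * tile
    assert nc * tile >= cols > (nc - 1) * tile


class TestTileWorldTransform:
    def test_offset_arithmetic(self):
        parent = WorldTransform(pixel_size_x=2.0, pixel_size_y=-2.0)
        t = tile_world_transform(parent, row_index=1, col_index=2, tile_size=256)
        assert (t.origin_x, t.origin_y) == (1024.0, -512.0)

    def test_identity_at_origin(self, unit_transform):
        assert tile_world_transform(unit_transform, 0, 0, 256) == unit_transform

    def test_georeferencing_consistency(self, unit_transform):
        # a pixel's map coordinate is the same through parent or tile transform
        t = tile_world_transform(unit_transform, 3, 5, 16)
        assert t.pixel_center(2, 7) == unit_transform.pixel_center(3 * 16 + 2, 5 * 16 + 7)


class TestSplitRaster:
    def test_count_matches_grid(self, gradient_raster):
        tiles = split_raster(gradient_raster, 16)
        assert len(tiles) == 4 * 4
        assert [t.tile_id for t in tiles[:2]] == ["tile_0000_0000", "tile_0000_0001"]

    def test_row_major_from_top_left(self, gradient_raster):
        tiles = split_raster(gradient_raster, 16)
        assert (tiles[1].row_index, tiles[1].col_index) == (0, 1)
        # column index grows along x
        assert tiles[1].transform.origin_x > tiles[0].transform.origin_x

    def test_exact_fit_has_no_padding(self, gradient_raster):
        assert all(t.n_padded == 0 for t in split_raster(gradient_raster, 32))

    def test_edge_padding_counts_as_white(self, unit_transform):
        # 300x300 raster, 256-px tiles: tile (0,1) keeps 44 real columns
        px = np.zeros((300, 300, 3), dtype=np.uint8)
        tiles = split_raster(GeoRaster(pixels=px, transform=unit_transform), 256)
        assert len(tiles) == 4
        t01 = tiles[1]
        assert t01.n_padded == 256 * 256 - 256 * 44
        assert t01.white_fraction >= 1 - 44 / 256

    def test_footprints_tile_the_raster(self, gradient_raster):
        tiles = split_raster(gradient_raster, 24)  # uneven split
        from shapely.ops import unary_union

        union = unary_union([t.footprint for t in tiles])
        footprint = gradient_raster.footprint()
        assert union.symmetric_difference(footprint).area < 1e-9 * footprint.area


class TestWhiteFraction:
    def _tile(self, px):
        return Tile(
            tile_id="t", row_index=0, col_index=0, pixels=px,
            transform=WorldTransform(1.0, -1.0), footprint=box(0, 0, 1, 1),
        )

    def test_all_white(self):
        assert white_fraction(self._tile(np.full((8, 8, 3), 255, np.uint8))) == 1.0

    def test_none_white(self):
        assert white_fraction(self._tile(np.full((8, 8, 3), 100, np.uint8))) == 0.0

    def test_half_white(self):
        px = np.full((8, 8, 3), 100, np.uint8)
        px[:4] = 255
        assert white_fraction(self._tile(px)) == 0.5

    def test_threshold_needs_all_channels(self):
        px = np.full((8, 8, 3), 255, np.uint8)
        px[..., 2] = 0  # bright yellow is not white
        assert white_fraction(self._tile(px)) == 0.0


class TestInsideFraction:
    def test_fully_inside(self):
        assert inside_fraction(box(1, 1, 2, 2), box(0, 0, 10, 10)) == 1.0

    def test_bisected(self):
        assert inside_fraction(box(0, 0, 2, 2), box(1, -5, 10, 10)) == pytest.approx(0.5)

    def test_disjoint(self):
        assert inside_fraction(box(0, 0, 1, 1), box(5, 5, 6, 6)) == 0.0

    def test_zero_area_footprint_fails(self):
        with pytest.raises(ValueError):
            inside_fraction(box(0, 0, 0, 0), box(0, 0, 1, 1))


class TestFilterTiles:
    def _tile(self, inside, white):
        t = Tile(
            tile_id=f"{inside}-{white}", row_index=0, col_index=0,
            pixels=np.zeros((4, 4, 3), np.uint8),
            transform=WorldTransform(1.0, -1.0), footprint=box(0, 0, 4, 4),
        )
        t.inside_fraction, t.white_fraction = inside, white
        return t

    @pytest.mark.parametrize(
        "inside, white, kept",
        [(1.0, 0.0, True), (0.9, 0.1, True), (0.89, 0.0, False), (1.0, 0.11, False)],
    )
    def test_default_thresholds(self, inside, white, kept):
        tiles = [self._tile(inside, white)]
        assert (len(filter_tiles(tiles)) == 1) is kept

    @settings(max_examples=30)
    @given(
        min_inside=st.floats(0, 1), max_white=st.floats(0, 1),
        stricter=st.floats(0, 0.3),
    )
    def test_monotone_in_thresholds(self, min_inside, max_white, stricter):
        rng = np.random.default_rng(0)
        tiles = [self._tile(rng.random(), rng.random()) for _ in range(30)]
        base = {t.tile_id for t in filter_tiles(tiles, min_inside=min_inside, max_white=max_white)}
        tighter = {
            t.tile_id
            for t in filter_tiles(
                tiles,
                min_inside=min(min_inside + stricter, 1.0),
                max_white=max(max_white - stricter, 0.0),
            )
        }
        assert tighter <= base
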