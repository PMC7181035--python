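"""Areal interpolation of census-tract health indexes onto image blocks.

Small-area health estimates are published per census tract; an image block
generally straddles several tracts.  The block-level estimate is the
area-weighted mean

    hci(block) = sum_j w_j * hci(j) / sum_j w_j

where w_j is the fraction of the block's footprint covered by tract j.
Tracts with missing values are dropped and the weights renormalized over
the remaining contributors, which keeps the estimator a convex combination
of observed tract values.  Weights are purely areal; no population
weighting is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from shapely.strtree import STRtree

__all__ = ["TractTable", "overlap_weights", "estimate_block_index", "link_blocks"]


@dataclass
class TractTable:
    """Census-tract polygons joined to their indicator values.

    ``values`` has one row per tract (indexed by tract_id) and one column
    per indicator; entries may be NaN.
    """

    tract_ids: list[str]
    polygons: list[Polygon | MultiPolygon]
    values: pd.DataFrame
    _tree: STRtree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.tract_ids) != len(self.polygons):
            raise ValueError("tract_ids and polygons must align")
        if len(set(self.tract_ids)) != len(self.tract_ids):
            raise ValueError("tract_id values must be unique")
        for tid, poly in zip(self.tract_ids, self.polygons):
            if not poly.is_valid:
                raise ValueError(f"tract {tid} has an invalid polygon")
        self.values = self.values.reindex(self.tract_ids)

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)

    def tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree(self.polygons)
        return self._tree


def overlap_weights(
    block_footprint: Polygon, tracts: TractTable
) -> list[tuple[str, float]]:
    """Per-tract coverage fractions of the block footprint.

    Only strictly positive weights are returned; their sum is <= 1 and can
    fall short of 1 where the block extends past all tracts.
    """
    area = block_footprint.area
    if area == 0:
        raise ValueError("zero-area block footprint")
    weights = []
    for idx in sorted(tracts.tree().query(block_footprint)):
        w = block_footprint.intersection(tracts.polygons[idx]).area / area
        if w > 0:
            weights.append((tracts.tract_ids[idx], w))
    return weights


def estimate_block_index(
    weights: list[tuple[str, float]], tract_values: dict[str, float]
) -> float:
    """Weighted mean of tract values over non-missing contributors.

    Weights are renormalized over tracts with observed values; NaN when no
    contributor has a value or all weights are zero.
    """
    num = den = 0.0
    for tract_id, w in weights:
        if w < 0:
            raise ValueError(f"negative weight for tract {tract_id}")
        v = tract_values.get(tract_id, float("nan"))
        if v is not None and not math.isnan(v):
            num += w * v
            den += w
    return num / den if den > 0 else float("nan")


def link_blocks(tiles, tracts: TractTable) -> pd.DataFrame:
    """Estimate every indicator for every tile; one row per tile.

    Columns: ``tile_id``, one column per indicator, and per-indicator
    effective weight sums ``<indicator>__wsum`` (the denominator actually
    used, after dropping missing contributors).
    """
    records = []
    for tile in tiles:
        weights = overlap_weights(tile.footprint, tracts)
        rec: dict[str, object] = {"tile_id": tile.tile_id}
        for ind in tracts.indicators:
            col = tracts.values[ind]
            vals = {tid: col.loc[tid] for tid, _ in weights}
            rec[ind] = estimate_block_index(weights, vals)
            rec[f"{ind}__wsum"] = sum(
                w for tid, w in weights if not pd.isna(col.loc[tid])
            )
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df if not df.empty else pd.DataFrame(columns=["tile_id"])
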