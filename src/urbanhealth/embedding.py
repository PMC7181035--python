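"""Tile feature extraction and extractor selection.

Tiles are mapped to feature vectors through a pluggable extractor
interface.  The bundled baseline extractor is deterministic and needs no
model download: per-channel 16-bin intensity histograms plus greenness and
gradient-magnitude summaries, all invariant to 90-degree rotations.
Adapters wrapping pre-trained convolutional networks can implement the
same interface.

Candidate extractors are compared with a green-centroid criterion: embed
all tiles, project the features to 2-D with t-SNE, take the greenest tiles,
and score each candidate by the sum of squared distances of those tiles to
their centroid in the 2-D map; the lowest SSE wins.  This rewards
extractors that keep visually green tiles together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

__all__ = [
    "ExtractorSpec",
    "FeatureMatrix",
    "greenness",
    "baseline_extractor",
    "extract_features",
    "green_centroid_sse",
    "select_extractor",
]

HIST_BINS = 16
_N_SUMMARY = 3  # greenness, gradient-magnitude mean and std
BASELINE_DIM = 3 * HIST_BINS + _N_SUMMARY

DEFAULT_GREEN_QUANTILE = 0.10
DEFAULT_TSNE_PERPLEXITY = 30.0
DEFAULT_TSNE_ITER = 1000


@dataclass(frozen=True)
class ExtractorSpec:
    """A named feature extractor mapping an RGB tile to a fixed-size vector."""

    name: str
    dimension: int
    deterministic: bool
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return self.fn(pixels)


@dataclass
class FeatureMatrix:
    """n_tiles × d embedding aligned to an ordered list of tile ids."""

    matrix: np.ndarray
    tile_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.tile_ids):
            raise ValueError("matrix rows must align with tile_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix, columns=[f"f{i}" for i in range(self.matrix.shape[1])]
        )
        df.insert(0, "tile_id", self.tile_ids)
        return df


def _pixels_of(tile) -> np.ndarray:
    return tile.pixels if hasattr(tile, "pixels") else np.asarray(tile)


def greenness(tile) -> float:
    """Fraction of pixels that read as vegetation green.

    A pixel counts when green strictly dominates both red and blue and is
    at least 64, so dark noise and gray pavement do not register.
    """
    px = _pixels_of(tile).astype(np.int16)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    green = (g > r) & (g > b) & (g >= 64)
    return float(green.mean())


def _baseline_features(pixels: np.ndarray) -> np.ndarray:
    px = np.asarray(pixels)
    feats = []
    for c in range(3):
        hist, _ = np.histogram(px[..., c], bins=HIST_BINS, range=(0, 256))
        feats.append(hist / px[..., c].size)
    gray = px.mean(axis=2) / 255.0  # unit scale keeps gradient summaries
    gy, gx = np.gradient(gray)      # commensurate with histogram fractions
    # summing in sorted order makes the summaries exact functions of the
    # multiset of gradient magnitudes, hence bit-identical under rotation
    mag = np.sort(np.hypot(gx, gy), axis=None)
    m1 = float(mag.mean())
    m2 = float((mag**2).mean())
    feats.append([greenness(px), m1, np.sqrt(max(m2 - m1**2, 0.0))])
    return np.concatenate(feats)


def baseline_extractor() -> ExtractorSpec:
    """Deterministic histogram/greenness/gradient extractor.

    Every component is a function of the multiset of pixel values or of the
    gradient-magnitude field, so the features are exactly invariant to
    90/180/270-degree rotations.
    """
    return ExtractorSpec(
        name="baseline-histogram",
        dimension=BASELINE_DIM,
        deterministic=True,
        fn=_baseline_features,
    )


def extract_features(tiles: Sequence, extractor: ExtractorSpec) -> FeatureMatrix:
    """One feature row per tile, in input order."""
    if len(tiles) == 0:
        raise ValueError("no tiles to extract features from")
    rows, ids = [], []
    for i, tile in enumerate(tiles):
        tile_id = getattr(tile, "tile_id", f"tile_{i}")
        try:
            vec = np.asarray(extractor(_pixels_of(tile)), dtype=float)
        except Exception as exc:  # noqa: BLE001 - surface the offending tile
            raise RuntimeError(f"extractor {extractor.name} failed on {tile_id}") from exc
        if vec.shape != (extractor.dimension,):
            raise ValueError(
                f"extractor {extractor.name} returned shape {vec.shape} for "
                f"{tile_id}, expected ({extractor.dimension},)"
            )
        rows.append(vec)
        ids.append(tile_id)
    return FeatureMatrix(matrix=np.vstack(rows), tile_ids=ids)


def tsne_project(
    matrix: np.ndarray,
    seed: int,
    perplexity: float = DEFAULT_TSNE_PERPLEXITY,
    n_iter: int = DEFAULT_TSNE_ITER,
) -> np.ndarray:
    """2-D t-SNE map of a feature matrix, deterministic given the seed."""
    n = matrix.shape[0]
    perp = min(perplexity, (n - 1) / 3)  # t-SNE requires perplexity < n
    tsne = TSNE(
        n_components=2,
        perplexity=perp,
        max_iter=n_iter,
        random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(np.asarray(matrix, dtype=float))


def green_centroid_sse(
    coords_2d: np.ndarray, green_scores: np.ndarray, green_quantile: float
) -> float:
    """SSE of the greenest tiles' 2-D coordinates to their centroid."""
    n = len(green_scores)
    k = max(2, int(round(n * green_quantile)))
    green_idx = np.argsort(-green_scores, kind="stable")[:k]
    if len(green_idx) < 2:
        raise ValueError("need at least 2 tiles in the green subset")
    pts = coords_2d[green_idx]
    centroid = pts.mean(axis=0)
    return float(((pts - centroid) ** 2).sum())


def select_extractor(
    candidates: Sequence[ExtractorSpec],
    tiles: Sequence,
    green_quantile: float = DEFAULT_GREEN_QUANTILE,
    tsne_seed: int = 0,
) -> tuple[ExtractorSpec, dict[str, float]]:
    """Pick the candidate whose t-SNE map best concentrates green tiles.

    For each candidate: extract features, map to 2-D with a fixed-seed
    t-SNE, select the top ``green_quantile`` tiles by greenness, and score
    the SSE of their 2-D coordinates to their centroid.  The candidate with
    the lowest SSE wins; ties go to the earlier candidate in the list.
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate extractor")
    if len(tiles) < 10:
        raise ValueError("extractor selection needs at least 10 tiles")
    green_scores = np.array([greenness(t) for t in tiles])
    sse_by_name: dict[str, float] = {}
    best: ExtractorSpec | None = None
    best_sse = np.inf
    for cand in candidates:
        fm = extract_features(tiles, cand)
        coords = tsne_project(fm.matrix, seed=tsne_seed)
        sse = green_centroid_sse(coords, green_scores, green_quantile)
        sse_by_name[cand.name] = sse
        if sse < best_sse:
            best, best_sse = cand, sse
    assert best is not None
    return best, sse_by_name
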