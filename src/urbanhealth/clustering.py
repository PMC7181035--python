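"""K-means clustering of tile embeddings with silhouette model selection.

K is chosen by a grid search (default 2..6): for each K the best of
``n_reruns`` k-means fits (lowest within-cluster sum of squares, Euclidean
distance) is scored by the mean silhouette coefficient, and the K with the
highest silhouette wins, smaller K on ties.  Features enter k-means
unscaled.  Cluster ids are relabeled 1..K by descending mean greenness of
their member tiles, so cluster 1 is the greenest — matching the convention
that C1 denotes green areas.

The module also provides the t-SNE diagnostic map and a rotation-invariance
validation: selected tiles and their randomly 90/180/270-degree-rotated
copies are embedded and hierarchically clustered; with a rotation-invariant
extractor every original's first merge in the dendrogram is with its own
rotated copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .embedding import ExtractorSpec, FeatureMatrix, extract_features, tsne_project

__all__ = [
    "ClusterResult",
    "TsneMap",
    "kmeans_grid_search",
    "tsne_diagnostic",
    "rotation_invariance_check",
]

DEFAULT_K_MIN = 2
DEFAULT_K_MAX = 6
DEFAULT_N_RERUNS = 10


@dataclass
class ClusterResult:
    """Outcome of the silhouette-driven k-means grid search."""

    labels: np.ndarray  # 1..K per tile
    chosen_k: int
    silhouette_by_k: pd.DataFrame  # columns: k, silhouette, inertia
    n_reruns: int
    seed: int

    @property
    def k(self) -> int:
        return self.chosen_k


@dataclass
class TsneMap:
    coordinates: np.ndarray  # n × 2
    seed: int
    perplexity: float
    labels: np.ndarray | None = field(default=None)


def _best_of_reruns(
    x: np.ndarray, k: int, n_reruns: int, rng: np.random.Generator
) -> KMeans:
    """Best (lowest-inertia) of n_reruns independently seeded k-means fits."""
    best = None
    for _ in range(n_reruns):
        km = KMeans(
            n_clusters=k, n_init=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(x)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    return best


def _relabel_by_score(labels0: np.ndarray, k: int, score: np.ndarray | None) -> np.ndarray:
    """Map raw cluster ids to 1..K, ordered by descending mean score.

    Without a score, clusters are numbered by first appearance in the data.
    """
    if score is not None:
        means = [(c, float(np.mean(score[labels0 == c]))) for c in range(k)]
        order = [c for c, _ in sorted(means, key=lambda cm: -cm[1])]
    else:
        seen: list[int] = []
        for c in labels0:
            if c not in seen:
                seen.append(int(c))
        order = seen
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[int(c)] for c in labels0])


def kmeans_grid_search(
    features: FeatureMatrix | np.ndarray,
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
    n_reruns: int = DEFAULT_N_RERUNS,
    seed: int = 0,
    greenness_scores: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster tiles for each K in [k_min, k_max] and keep the silhouette-best K.

    ``greenness_scores``, when given, orders the final cluster ids so that
    cluster 1 has the greenest members.
    """
    x = features.matrix if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n = x.shape[0]
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if n <= k_max:
        raise ValueError(f"need more than k_max={k_max} samples, got {n}")
    if np.all(x == x[0]):
        raise ValueError("all feature rows identical; silhouette undefined")
    rng = np.random.default_rng(seed)
    rows, fits = [], {}
    for k in range(k_min, k_max + 1):
        km = _best_of_reruns(x, k, n_reruns, rng)
        sil = float(silhouette_score(x, km.labels_, metric="euclidean"))
        rows.append({"k": k, "silhouette": sil, "inertia": float(km.inertia_)})
        fits[k] = km
    table = pd.DataFrame(rows)
    # ties -> smallest K (idxmax returns the first maximum; table is ordered by k)
    chosen_k = int(table.loc[table["silhouette"].idxmax(), "k"])
    labels = _relabel_by_score(fits[chosen_k].labels_, chosen_k, greenness_scores)
    return ClusterResult(
        labels=labels, chosen_k=chosen_k, silhouette_by_k=table,
        n_reruns=n_reruns, seed=seed,
    )


def tsne_diagnostic(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
) -> TsneMap:
    """2-D t-SNE map of the embedding for visual cluster validation."""
    x = features.matrix if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if x.shape[0] < 5:
        raise ValueError("t-SNE diagnostic needs at least 5 samples")
    coords = tsne_project(x, seed=seed, perplexity=perplexity)
    return TsneMap(
        coordinates=coords, seed=seed,
        perplexity=min(perplexity, (x.shape[0] - 1) / 3),
        labels=None if labels is None else np.asarray(labels),
    )


def _rotate(pixels: np.ndarray, angle: int) -> np.ndarray:
    return np.rot90(pixels, k=angle // 90)


def _merge_tree(z: np.ndarray, n_leaves: int) -> dict:
    """Nested dict representation of a scipy linkage matrix."""
    nodes: dict[int, dict] = {i: {"leaf": i} for i in range(n_leaves)}
    for step, (a, b, dist, _) in enumerate(z):
        nodes[n_leaves + step] = {
            "children": [nodes[int(a)], nodes[int(b)]],
            "distance": float(dist),
        }
    return nodes[n_leaves + len(z) - 1]


def rotation_invariance_check(
    selected_tiles: Sequence,
    extractor: ExtractorSpec,
    angles: tuple[int, ...] = (90, 180, 270),
    linkage_method: str = "average",
    seed: int = 0,
) -> tuple[float, dict]:
    """Dendrogram test of embedding robustness to 90-degree rotations.

    Each tile gets one copy rotated by a randomly chosen angle; originals
    and copies are embedded together and hierarchically clustered (average
    linkage, Euclidean distance).  Returns the fraction of originals whose
    first dendrogram merge is with their own rotated copy, plus the merge
    tree as a nested dict.
    """
    if len(selected_tiles) < 2:
        raise ValueError("need at least 2 tiles")
    for a in angles:
        if a % 90 != 0:
            raise ValueError(f"angle {a} is not a multiple of 90 degrees")
    rng = np.random.default_rng(seed)
    n = len(selected_tiles)
    pixel_sets = [np.asarray(t.pixels if hasattr(t, "pixels") else t) for t in selected_tiles]
    rotated = [_rotate(px, int(rng.choice(angles))) for px in pixel_sets]
    feats = extract_features(pixel_sets + rotated, extractor)
    z = linkage(feats.matrix, method=linkage_method, metric="euclidean")

    # replay merges; an original i (leaf i) is "paired" when its first merge
    # is with the singleton leaf n+i (its own rotated copy)
    members: dict[int, set[int]] = {i: {i} for i in range(2 * n)}
    first_merge_partner: dict[int, set[int]] = {}
    for step, (a, b, _, _) in enumerate(z):
        a, b = int(a), int(b)
        for leaf in members[a]:
            if leaf < n and leaf not in first_merge_partner:
                first_merge_partner[leaf] = members[b]
        for leaf in members[b]:
            if leaf < n and leaf not in first_merge_partner:
                first_merge_partner[leaf] = members[a]
        members[2 * n + step] = members[a] | members[b]
    paired = sum(
        1 for i in range(n) if first_merge_partner.get(i) == {n + i}
    )
    return paired / n, _merge_tree(z, 2 * n)
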