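"""Human–machine agreement: confusion matrix, Cohen's kappa, maximum kappa.

Human raters assign each tile to one of the landscape categories; the
algorithm assigns a cluster.  Agreement is summarized by a K × K confusion
matrix (rows = human, columns = machine) with per-row true-positive and
false-negative rates and per-column positive predictive value and false
discovery rate, and by Cohen's kappa

    kappa = (po - pe) / (1 - pe)

where po is the observed agreement and pe the agreement expected by chance
from the margins.  The maximum attainable kappa under the observed margins
replaces po with po_max = sum_i min(row_i, col_i) / n.  A one-sided z-test
against kappa <= 0 uses the large-sample null standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ConfusionMatrix",
    "KappaResult",
    "build_confusion",
    "cohen_kappa",
    "kappa_interpretation",
    "pool_rater_labels",
]

_BANDS = [
    (0.0, 0.2, "slight"),
    (0.2, 0.4, "fair"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "substantial"),
    (0.8, 1.0, "almost perfect"),
]


@dataclass
class ConfusionMatrix:
    """K × K counts, rows = human rater category, columns = machine cluster."""

    counts: np.ndarray
    tpr: np.ndarray  # per row; NaN on a zero row margin
    fnr: np.ndarray
    ppv: np.ndarray  # per column; NaN on a zero column margin
    fdr: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float
    kappa_max: float
    se: float
    p_value: float


def build_confusion(human_labels, machine_labels, n_categories: int | None = None) -> ConfusionMatrix:
    """Cross-tabulate human and machine labels (both coded 1..K)."""
    h = np.asarray(human_labels, dtype=int)
    m = np.asarray(machine_labels, dtype=int)
    if h.shape != m.shape:
        raise ValueError("label vectors must have equal length")
    k = n_categories or int(max(h.max(), m.max()))
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (h - 1, m - 1), 1)
    row = counts.sum(axis=1).astype(float)
    col = counts.sum(axis=0).astype(float)
    diag = np.diag(counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row > 0, diag / row, np.nan)
        ppv = np.where(col > 0, diag / col, np.nan)
    return ConfusionMatrix(counts=counts, tpr=tpr, fnr=1 - tpr, ppv=ppv, fdr=1 - ppv)


def cohen_kappa(matrix: ConfusionMatrix | np.ndarray) -> KappaResult:
    """Chance-corrected agreement with maximum-kappa and a test vs chance.

    po_max (for kappa_max) takes the best diagonal attainable under the
    observed margins.  The z-test of kappa = 0 is one-sided and uses the
    large-sample standard error under the null of independent raters.
    """
    counts = matrix.counts if isinstance(matrix, ConfusionMatrix) else np.asarray(matrix)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 rated items")
    p = counts / n
    row, col = p.sum(axis=1), p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(np.dot(row, col))
    if pe >= 1:
        raise ValueError("kappa undefined: chance agreement is 1")
    kappa = (po - pe) / (1 - pe)
    po_max = float(np.minimum(row, col).sum())
    kappa_max = (po_max - pe) / (1 - pe)
    # large-sample SE under H0 of independence (Fleiss, Cohen & Everitt)
    se0 = np.sqrt(
        (pe + pe**2 - float(np.sum(row * col * (row + col)))) / (n * (1 - pe) ** 2)
    )
    z = kappa / se0
    p_value = float(norm.sf(z))
    return KappaResult(
        po=po, pe=pe, kappa=float(kappa), kappa_max=float(kappa_max),
        se=float(se0), p_value=max(p_value, np.finfo(float).tiny),
    )


def kappa_interpretation(kappa: float) -> str:
    """Conventional verbal band for a kappa value; bands are [lower, upper)."""
    if not -1 <= kappa <= 1:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "poor"
    if kappa == 1.0:
        return "almost perfect"
    for lo, hi, label in _BANDS:
        if lo <= kappa < hi:
            return label
    return "almost perfect"


def pool_rater_labels(
    ratings: pd.DataFrame, exclude_categories: tuple[int, ...] = (5,)
) -> pd.Series:
    """One label per tile from a (tile_id, rater_id, category) table.

    The modal category wins; ties break toward the lowest category id.
    Categories in ``exclude_categories`` (the unknown/other option) are
    dropped before pooling; tiles with no remaining ratings are omitted.
    """
    df = ratings[~ratings["category"].isin(exclude_categories)]
    pooled = {}
    for tile_id, grp in df.groupby("tile_id"):
        vc = grp["category"].value_counts()
        best = vc[vc == vc.max()].index.min()
        pooled[tile_id] = int(best)
    return pd.Series(pooled, name="category")
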