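"""Per-species CAZyme family profiles and Bray-Curtis clustering.

Counts of carbohydrate-active-enzyme (CAZyme) family assignments per
species are normalised to percentages of each species' total, compared
with the Bray-Curtis dissimilarity, and ordered by average-linkage
agglomeration for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import braycurtis, pdist


@dataclass
class ProfileMatrix:
    """Species x family percentages; every row sums to 100."""

    percent: pd.DataFrame
    row_totals: pd.Series  # raw counts per species


def assign_cazyme_family(hits: list[tuple[str, float]]) -> str | None:
    """Family of the lowest-i-evalue hit; lexicographic tie-break.

    ``hits`` are (family, i_evalue) pairs already filtered at the CAZyme
    cutoff; returns None when nothing survives.
    """
    if not hits:
        return None
    return min(hits, key=lambda h: (h[1], h[0]))[0]


def profile_percentages(counts: pd.DataFrame) -> ProfileMatrix:
    """Normalise a species x family count table to row percentages."""
    counts = counts.fillna(0.0)
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"species with zero CAZyme counts: {list(zero.index)}")
    percent = counts.div(totals, axis=0) * 100.0
    return ProfileMatrix(percent=percent, row_totals=totals)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on non-negative rows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    return float(braycurtis(x, y))


def cluster_rows(matrix: pd.DataFrame, method: str = "average"):
    """Agglomerate profile rows; returns (leaf order labels, linkage)."""
    if len(matrix) < 2:
        return list(matrix.index), None
    d = pdist(matrix.to_numpy(dtype=float), metric="braycurtis")
    Z = linkage(d, method=method)
    order = [matrix.index[i] for i in leaves_list(Z)]
    return order, Z
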