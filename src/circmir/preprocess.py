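"""Count filtering, quantile normalisation and exploratory structure.

The analysis set is built by two filters applied to the raw miRNA x sample
count matrix: a detectability filter (seen with at least one read in >= 2
samples) and an abundance filter (count strictly greater than 50 in at least
10% of the samples). Retained counts are quantile normalised — every sample is
mapped onto the across-sample mean of order statistics, ties receiving the
mean of their tied reference quantiles — and log2 transformed with an offset
of one. Samples are explored by abundance ranking and by unsupervised
agglomerative clustering on correlation distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "detectability_filter",
    "abundance_filter",
    "quantile_normalize",
    "rank_by_abundance",
    "cluster_samples",
    "Dendrogram",
]


def detectability_filter(m: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Keep genes detected (count >= 1) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    keep = (m >= 1).sum(axis=1) >= min_samples
    return m.loc[keep]


def abundance_filter(
    m: pd.DataFrame, min_count: int = 50, min_fraction: float = 0.10
) -> pd.DataFrame:
    """Keep genes with count > ``min_count`` in >= ceil(min_fraction * n) samples.

    The count inequality is strict: a gene at exactly ``min_count`` everywhere
    is removed.
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    needed = math.ceil(min_fraction * m.shape[1])
    keep = (m > min_count).sum(axis=1) >= needed
    return m.loc[keep]


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Rank-based quantile normalisation with tie groups averaged."""
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(values, order, axis=0), axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(n_samples):
        col = values[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        mapped = reference.copy()
        # ties within a column get the mean of the reference quantiles they span
        start = 0
        for k in range(1, n_genes + 1):
            if k == n_genes or sorted_col[k] != sorted_col[start]:
                if k - start > 1:
                    mapped[start:k] = reference[start:k].mean()
                start = k
        out[idx, j] = mapped
    return out


def quantile_normalize(m: pd.DataFrame, log2_offset: float = 1.0) -> pd.DataFrame:
    """Quantile-normalise columns then apply log2(x + offset).

    Every column's pre-log value multiset becomes the across-column mean of
    order statistics (up to tie-averaging). With a single sample the mapping
    degenerates to the identity and a warning is emitted; only the log
    transform is applied.
    """
    values = m.to_numpy(dtype=float)
    if values.shape[1] < 2:
        warnings.warn("quantile normalisation skipped: single sample", stacklevel=2)
        normed = values
    else:
        normed = _quantile_normalize_values(values)
    return pd.DataFrame(np.log2(normed + log2_offset), index=m.index, columns=m.columns)


def rank_by_abundance(m: pd.DataFrame, top_n: int = 100) -> pd.DataFrame:
    """Genes ordered by decreasing across-sample mean, with mean/min/max.

    Mirrors the 'top 100 most abundant circulating miRNAs' display: for each
    gene the across-sample mean and the observed range.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    stats_df = pd.DataFrame(
        {"mean": m.mean(axis=1), "min": m.min(axis=1), "max": m.max(axis=1)}
    )
    stats_df = stats_df.sort_values(["mean"], ascending=False, kind="stable")
    return stats_df.head(top_n)


@dataclass
class Dendrogram:
    """Sample dendrogram: scipy linkage matrix plus the leaf labels."""

    labels: list[str]
    linkage: np.ndarray

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return walk(tree) + ";"

    def cut(self, k: int) -> dict[str, int]:
        """Flat partition into k clusters (cluster label per sample)."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def cluster_samples(m: pd.DataFrame) -> Dendrogram:
    """Average-linkage clustering of samples on 1 - Pearson correlation.

    Zero-variance sample columns have undefined correlation; their distance to
    every other sample is set to the maximum (2.0) with a warning. Samples are
    processed in lexicographic id order so equal-distance merges resolve
    deterministically toward the smallest id pair.
    """
    if m.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    cols = sorted(m.columns)
    values = m[cols].to_numpy(dtype=float)
    sd = values.std(axis=0)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"zero-variance samples treated as maximally distant: "
            f"{[c for c, bad in zip(cols, degenerate) if bad]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    np.clip(dist, 0.0, None, out=dist)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(labels=list(cols), linkage=linkage)
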