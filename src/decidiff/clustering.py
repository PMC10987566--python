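"""Hierarchical clustering of sample transcriptomes.

Samples are clustered on log2(TPM + 1) profiles with Euclidean distance
and average linkage by default; distance metric and linkage are
configurable (correlation distance = 1 - Pearson r; complete and single
linkage).  The agglomeration is a plain O(n^3) sweep — sample counts here
are single digits — with a documented deterministic tie-break: among
equally close cluster pairs, the lexicographically smallest pair (by the
sorted member tuples) merges first.  Dendrograms export to Newick with
branch lengths equal to the difference between a node's merge height and
its child's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DomainError
from .formats import ExpressionMatrix

LINKAGES = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """Agglomeration record: leaves plus (cluster A, cluster B, height) merges."""

    leaves: tuple[str, ...]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise DomainError(
                f"{len(self.leaves)} leaves require {len(self.leaves) - 1} "
                f"merges, got {len(self.merges)}"
            )

    def to_newick(self) -> str:
        """Newick string; a child's branch length is its parent's merge
        height minus its own (leaves sit at height 0)."""
        reps: dict[tuple[str, ...], tuple[str, float]] = {
            (leaf,): (leaf, 0.0) for leaf in self.leaves
        }
        node = ""
        for a, b, height in self.merges:
            sub_a, h_a = reps.pop(tuple(a))
            sub_b, h_b = reps.pop(tuple(b))
            node = f"({sub_a}:{height - h_a:.6g},{sub_b}:{height - h_b:.6g})"
            reps[tuple(sorted(set(a) | set(b)))] = (node, height)
        return node + ";"

    def cut_clusters(self, k: int) -> list[frozenset[str]]:
        """Leaf partition obtained by undoing the last k-1 merges."""
        if not 1 <= k <= len(self.leaves):
            raise DomainError(f"k must be in [1, {len(self.leaves)}]")
        clusters = {frozenset([leaf]) for leaf in self.leaves}
        for a, b, _ in self.merges[: len(self.leaves) - k]:
            fa, fb = frozenset(a), frozenset(b)
            clusters.remove(fa)
            clusters.remove(fb)
            clusters.add(fa | fb)
        return sorted(clusters, key=lambda c: sorted(c))


def transform_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    return ExpressionMatrix(np.log2(matrix.data + 1.0))


def sample_distances(
    matrix: ExpressionMatrix, metric: str = "euclidean"
) -> pd.DataFrame:
    """Symmetric sample-by-sample distance table.

    ``euclidean`` over gene profiles, or ``correlation`` defined as
    1 - Pearson correlation.
    """
    if len(matrix.sample_ids) < 2:
        raise DomainError("at least 2 samples required")
    x = matrix.data.to_numpy().T  # samples x genes
    if metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    elif metric == "correlation":
        d = 1.0 - np.corrcoef(x)
        np.fill_diagonal(d, 0.0)
    else:
        raise DomainError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


def _cluster_distance(
    a: tuple[str, ...], b: tuple[str, ...], dist: pd.DataFrame, linkage: str
) -> float:
    block = dist.loc[list(a), list(b)].to_numpy()
    if linkage == "average":
        return float(block.mean())
    if linkage == "complete":
        return float(block.max())
    return float(block.min())  # single


def hierarchical_cluster(
    distances: pd.DataFrame, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a validated distance table.

    Cluster distances are recomputed from the original pairwise table at
    every step (unweighted average / maximum / minimum over cross pairs),
    so merge heights are exact for the three supported linkages.  Ties are
    broken by merging the lexicographically smallest eligible pair.
    """
    if linkage not in LINKAGES:
        raise DomainError(f"unknown linkage {linkage!r}; use one of {LINKAGES}")
    d = distances
    if list(d.index) != list(d.columns):
        raise DomainError("distance table index and columns must match")
    arr = d.to_numpy()
    if arr.shape[0] < 2:
        raise DomainError("at least 2 samples required")
    if not np.allclose(arr, arr.T):
        raise DomainError("distance table must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise DomainError("distance table must have a zero diagonal")

    clusters: list[tuple[str, ...]] = sorted((s,) for s in d.index)
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted((clusters[i], clusters[j]))
                dist_ab = _cluster_distance(a, b, d, linkage)
                cand = (dist_ab, a, b)
                if best is None or cand < best:
                    best = cand
        height, a, b = best
        merges.append((a, b, height))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(tuple(sorted(a + b)))
        clusters.sort()
    return Dendrogram(tuple(d.index), merges)


def cluster_samples(
    matrix: ExpressionMatrix,
    *,
    log_transform: bool = True,
    metric: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Convenience wrapper: transform, distance, agglomerate."""
    m = transform_matrix(matrix) if log_transform else matrix
    return hierarchical_cluster(sample_distances(m, metric), linkage)
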