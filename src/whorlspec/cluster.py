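"""Agglomerative clustering with deterministic tie-breaking.

Complete linkage ("furthest neighbor") is the default throughout the package:
it is used both for the organ-resemblance dendrogram of mean expression
profiles and for the GO-enrichment resemblance clustering of comparisons.
The implementation is a direct agglomeration so that ties between equal
merge candidates resolve reproducibly: among candidate pairs at the minimum
distance, the lexicographically smallest pair of cluster labels (a cluster's
label being its sorted leaf tuple) is merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Dendrogram:
    """Merge sequence of an agglomerative clustering.

    ``merges`` lists (left leaves, right leaves, height) in merge order,
    where each side is the sorted tuple of leaf labels of the cluster.
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    method: str = "complete"
    highlight_below: float | None = None

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def cophenetic(self, a: str, b: str) -> float:
        """Height at which leaves a and b first share a cluster."""
        if a == b:
            return 0.0
        for left, right, h in self.merges:
            if (a in left and b in right) or (a in right and b in left):
                return h
        raise KeyError(f"{a!r} and {b!r} never merge")

    def highlighted_merges(self) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
        """Merges below the highlight distance (e.g. the red lines of a plot)."""
        if self.highlight_below is None:
            return []
        return [m for m in self.merges if m[2] < self.highlight_below]

    def to_newick(self) -> str:
        """Newick string; each child branch length = merge height minus the
        child's own merge height (leaves sit at height 0)."""
        node_height: dict[tuple[str, ...], float] = {}
        node_repr: dict[tuple[str, ...], str] = {}
        for lab in self.labels:
            node_height[(lab,)] = 0.0
            node_repr[(lab,)] = lab
        key = None
        for left, right, h in self.merges:
            bl_l = h - node_height[left]
            bl_r = h - node_height[right]
            key = tuple(sorted(left + right))
            node_repr[key] = (
                f"({node_repr[left]}:{bl_l:.10g},{node_repr[right]}:{bl_r:.10g})"
            )
            node_height[key] = h
        if key is None:  # single leaf
            return f"{self.labels[0]};"
        return node_repr[key] + ";"


def _linkage_distance(dist: pd.DataFrame, ca: tuple[str, ...], cb: tuple[str, ...],
                      method: str) -> float:
    block = dist.loc[list(ca), list(cb)].to_numpy(dtype=float)
    if method == "complete":
        return float(block.max())
    if method == "average":
        return float(block.mean())
    if method == "single":
        return float(block.min())
    raise ValueError(f"unknown linkage method {method!r}")


def agglomerate(dist: pd.DataFrame, method: str = "complete",
                highlight_below: float | None = None) -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    Deterministic: among equally-close candidate pairs the lexicographically
    smallest (by sorted leaf-label tuples) is merged first.
    """
    labels = [str(x) for x in dist.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix index and columns must match")
    arr = dist.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")

    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted((clusters[i], clusters[j]))
                d = _linkage_distance(dist, a, b, method)
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        merges.append((a, b, d))
        clusters = [c for c in clusters if c != a and c != b]
        clusters.append(tuple(sorted(a + b)))
    return Dendrogram(labels=labels, merges=merges, method=method,
                      highlight_below=highlight_below)


def euclidean_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between the COLUMNS of ``profiles``."""
    x = profiles.to_numpy(dtype=float).T
    sq = (x * x).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.clip(d2, 0.0, None))
    return pd.DataFrame(d, index=profiles.columns, columns=profiles.columns)
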