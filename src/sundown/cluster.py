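"""UPGMA clustering of regional co-activity on the 1 − |r| dissimilarity.

Regions whose activity is strongly correlated — positively *or* negatively —
are considered co-regulated, so the dissimilarity between two regions is
d = 1 − |r|: it is 0 at r = ±1 and reaches its maximum of 1 at r = 0.
Agglomeration uses average linkage (UPGMA): at each step the pair of
clusters with the smallest mean inter-cluster dissimilarity is merged, ties
broken deterministically by the lexicographically smallest label pair.

The number of clusters k is chosen by the elbow heuristic on the total
within-cluster pairwise dissimilarity as a function of k; the curve is
returned with an advisory elbow (largest second difference), but the final
k is a user decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sundown.network import GroupCorrMatrix

__all__ = [
    "DissimilarityMatrix",
    "Dendrogram",
    "to_dissimilarity",
    "upgma",
    "cut_clusters",
    "elbow_curve",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric region × region dissimilarity, d = 1 − |r| ∈ [0, 1]."""

    d: pd.DataFrame
    dropped_regions: list[str]

    @property
    def regions(self) -> list[str]:
        return list(self.d.index)


@dataclass
class Dendrogram:
    """UPGMA merge tree in scipy linkage form over named leaves."""

    linkage: np.ndarray           # (n-1, 4) scipy-style linkage matrix
    labels: list[str]
    method: str = "UPGMA"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = len(self.labels)
        node_h = {i: 0.0 for i in range(n)}
        node_s = {i: self.labels[i] for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - node_h[a]
            lb = h - node_h[b]
            nid = n + step
            node_s[nid] = f"({node_s[a]}:{la:g},{node_s[b]}:{lb:g})"
            node_h[nid] = h
        return node_s[n + len(self.linkage) - 1] + ";"


def to_dissimilarity(corr: GroupCorrMatrix | pd.DataFrame) -> DissimilarityMatrix:
    """Convert a region correlation matrix to the 1 − |r| dissimilarity.

    Regions with any undefined off-diagonal correlation are dropped first
    (and reported), since UPGMA needs a complete matrix.
    """
    r = corr.r if isinstance(corr, GroupCorrMatrix) else corr
    R = r.to_numpy(dtype=float).copy()
    np.fill_diagonal(R, 1.0)
    ok = ~np.isnan(R).any(axis=1)
    dropped = list(r.index[~ok])
    if not ok.any():
        raise ValueError("no regions with fully defined correlations")
    keep = r.index[ok]
    D = 1.0 - np.abs(R[np.ix_(ok, ok)])
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(
        d=pd.DataFrame(D, index=keep, columns=keep), dropped_regions=dropped
    )


def upgma(dmat: DissimilarityMatrix | pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix.

    Direct O(n³) implementation so the tie-break is explicit: among pairs at
    the minimal average dissimilarity, the pair whose sorted member-label
    tuples compare lexicographically smallest merges first.  Cluster-pair
    distances are unweighted means over all member pairs, and merge heights
    are non-decreasing (UPGMA is monotone).
    """
    d = dmat.d if isinstance(dmat, DissimilarityMatrix) else dmat
    D = np.asarray(d, dtype=float)
    labels = list(d.index)
    n = len(labels)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix is not symmetric")
    if n < 2:
        raise ValueError("need at least two regions")

    # active clusters: id -> (leaf index set, size); ids 0..n-1 are leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    key: dict[int, tuple] = {i: (labels[i],) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], min(key[kv[0][0]], key[kv[0][1]]),
                            max(key[kv[0][0]], key[kv[0][1]])),
        )
        (a, b), h = best
        na, nb = len(members[a]), len(members[b])
        Z[step] = [min(a, b), max(a, b), h, na + nb]
        new = next_id
        next_id += 1
        members[new] = members.pop(a) + members.pop(b)
        key[new] = tuple(sorted(key.pop(a) + key.pop(b)))
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c in members:
            if c == new:
                continue
            # unweighted mean over all member pairs
            dist[(min(c, new), max(c, new))] = float(
                D[np.ix_(members[new], members[c])].mean()
            )
    return Dendrogram(linkage=Z, labels=labels)


def cut_clusters(dend: Dendrogram, k: int) -> pd.Series:
    """Assign each region to one of exactly k clusters.

    Undoes the last k − 1 merges of the UPGMA tree, i.e. applies the first
    n − k merges in merge order.  With tied merge heights this is the
    merge-order tie-break; cluster ids are 1..k in order of each cluster's
    first leaf.
    """
    n = len(dend.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(dend.linkage[step, 0]), int(dend.linkage[step, 1])
        root = n + step
        parent[find(a)] = root
        parent[find(b)] = root
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    assign = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        assign[i] = relabel[r]
    return pd.Series(assign, index=dend.labels, name="cluster")


def elbow_curve(
    dend: Dendrogram,
    dmat: DissimilarityMatrix | pd.DataFrame,
    k_max: int | None = None,
) -> pd.DataFrame:
    """Total within-cluster pairwise dissimilarity for k = 1..k_max.

    The curve is non-increasing, equals the total pairwise dissimilarity at
    k = 1 and 0 at k = n.  The row with the advisory elbow (largest second
    difference of the curve) is flagged; the heuristic is advisory only.
    """
    d = dmat.d if isinstance(dmat, DissimilarityMatrix) else dmat
    D = np.asarray(d, dtype=float)
    n = len(dend.labels)
    if k_max is None:
        k_max = n
    if k_max > n:
        raise ValueError("k_max exceeds region count")
    totals = []
    for k in range(1, k_max + 1):
        assign = cut_clusters(dend, k).to_numpy()
        tot = 0.0
        for c in np.unique(assign):
            idx = np.flatnonzero(assign == c)
            if len(idx) > 1:
                sub = D[np.ix_(idx, idx)]
                tot += sub[np.triu_indices(len(idx), k=1)].sum()
        totals.append(tot)
    out = pd.DataFrame({"k": np.arange(1, k_max + 1), "total_within": totals})
    out["elbow"] = False
    if k_max >= 3:
        curve = out["total_within"].to_numpy()
        second_diff = curve[:-2] - 2 * curve[1:-1] + curve[2:]
        out.loc[1 + int(np.argmax(second_diff)), "elbow"] = True
    return out
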