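"""Region co-activation correlation matrices and network topology.

Brain-wide mapping yields, per group, a subjects × regions table of activity
densities.  Pairwise Pearson correlations between regions define a
co-activation matrix; the asymptotic significance of each correlation uses
the t transform t = r√(n−2)/√(1−r²) with n−2 degrees of freedom.  Networks
are built either by an alpha threshold on p (for topology sweeps) or by
proportional thresholding — ranking edges by p and keeping the most
significant fraction (e.g. the 1.5% edge density used for group-network
visualization) over a node set shared across groups.

Graph metrics (mean degree, global efficiency, mean clustering, mean
betweenness) are unweighted and undirected, computed with networkx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupCorrMatrix",
    "CorrelationNetwork",
    "region_correlations",
    "significance_mask",
    "joined_network",
    "topology_metrics",
    "threshold_sweep",
    "abs_r_distribution",
]


@dataclass
class GroupCorrMatrix:
    """Square Pearson r over regions with two-sided asymptotic p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame          # per-pair complete-case count
    group: str
    n_subjects: int

    @property
    def regions(self) -> list[str]:
        return list(self.r.index)


@dataclass
class CorrelationNetwork:
    """Region graph whose edges carry the correlation and its p-value."""

    graph: nx.Graph
    group: str
    provenance: dict = field(default_factory=dict)

    @property
    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"region_a": a, "region_b": b, "r": d["r"], "p": d["p"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["region_a", "region_b", "r", "p"])


def region_correlations(
    table: pd.DataFrame,
    group: str,
    group_col: str = "group",
    min_n: int = 4,
) -> GroupCorrMatrix:
    """Pairwise-complete Pearson correlations among regions for one group.

    p-values come from the one-sample t transform on r with df = n − 2,
    two-sided.  Pairs with fewer than ``min_n`` complete observations are
    marked undefined (NaN).
    """
    if group_col not in table.columns:
        raise ValueError(f"table has no {group_col!r} column")
    sub = table[table[group_col] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} not present")
    feats = sub[[c for c in sub.columns if c not in ("subject_id", group_col)]]
    X = feats.to_numpy(dtype=float)
    names = list(feats.columns)
    m = len(names)
    present = ~np.isnan(X)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    nmat = np.zeros((m, m), dtype=int)
    for i in range(m):
        r[i, i] = 1.0
        nmat[i, i] = int(present[:, i].sum())
        for j in range(i + 1, m):
            mask = present[:, i] & present[:, j]
            n = int(mask.sum())
            nmat[i, j] = nmat[j, i] = n
            if n < min_n:
                continue
            xi, xj = X[mask, i], X[mask, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = min(1.0, max(-1.0, rij))
            r[i, j] = r[j, i] = rij
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt(n - 2) / np.sqrt(1 - rij**2)
                pij = 2 * stats.t.sf(abs(t), df=n - 2)
            p[i, j] = p[j, i] = pij
    idx = pd.Index(names)
    return GroupCorrMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
        group=group,
        n_subjects=len(sub),
    )


def significance_mask(corr: GroupCorrMatrix, alpha: float) -> pd.DataFrame:
    """Boolean mask of correlations with p strictly below ``alpha``.

    Conservative alphas (e.g. 0.005 for eYFP+, 0.001 for c-Fos+) pick out
    the correlations shown opaque in heatmaps.  The diagonal is False.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    vals = (corr.p.to_numpy() < alpha).copy()
    np.fill_diagonal(vals, False)
    return pd.DataFrame(vals, index=corr.p.index, columns=corr.p.columns)


def _ranked_edges(corr: GroupCorrMatrix, regions: list[str]) -> list[tuple]:
    """Edges over ``regions`` ranked by p asc, then |r| desc, then labels."""
    rows = []
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            pv = corr.p.loc[a, b]
            rv = corr.r.loc[a, b]
            if np.isnan(pv) or np.isnan(rv):
                continue
            rows.append((float(pv), -abs(float(rv)), a, b, float(rv)))
    rows.sort()
    return rows


def joined_network(
    corrs: dict[str, GroupCorrMatrix],
    edge_density: float = 0.015,
) -> dict[str, CorrelationNetwork]:
    """Proportionally thresholded networks over a shared node set.

    The node set is the regions whose correlations are fully defined in
    every group; each group then independently keeps its
    ``round(edge_density × n(n−1)/2)`` most significant edges (ranked by
    p ascending, ties by |r| descending then label pair).
    """
    if len(corrs) < 2:
        raise ValueError("need at least two groups to join")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")

    shared = None
    for c in corrs.values():
        P = c.p.to_numpy().copy()
        np.fill_diagonal(P, 0.0)
        ok = set(c.p.index[~np.isnan(P).any(axis=1)])
        shared = ok if shared is None else shared & ok
    regions = sorted(shared)
    n = len(regions)
    n_possible = n * (n - 1) // 2
    n_keep = round(edge_density * n_possible)
    if n_keep == 0:
        raise ValueError("edge density yields zero edges at this node count")

    out = {}
    for g, c in corrs.items():
        ranked = _ranked_edges(c, regions)[:n_keep]
        G = nx.Graph()
        G.add_nodes_from(regions)
        for pv, _, a, b, rv in ranked:
            G.add_edge(a, b, r=rv, p=pv)
        out[g] = CorrelationNetwork(
            graph=G,
            group=g,
            provenance={
                "rule": "proportional-by-p",
                "requested_density": edge_density,
                "achieved_density": G.number_of_edges() / n_possible,
                "n_edges": G.number_of_edges(),
                "n_nodes": n,
            },
        )
    return out


def topology_metrics(net: CorrelationNetwork | nx.Graph) -> dict[str, float]:
    """Mean degree, global efficiency, mean clustering, mean betweenness.

    All metrics treat the graph as unweighted and undirected.  Global
    efficiency averages 1/d(u,v) over node pairs with 1/∞ = 0 for
    disconnected pairs; betweenness is normalized by (N−1)(N−2)/2.
    """
    G = net.graph if isinstance(net, CorrelationNetwork) else net
    N = G.number_of_nodes()
    if N == 0:
        raise ValueError("empty network")
    mean_degree = 2 * G.number_of_edges() / N
    efficiency = nx.global_efficiency(G) if N > 1 else 0.0
    clustering = nx.average_clustering(G) if N > 0 else 0.0
    if N > 2:
        betweenness = float(np.mean(list(nx.betweenness_centrality(G, normalized=True).values())))
    else:
        betweenness = 0.0
    return {
        "mean_degree": mean_degree,
        "mean_efficiency": efficiency,
        "mean_clustering": clustering,
        "mean_betweenness": betweenness,
    }


def default_alpha_grid(n_points: int = 40) -> np.ndarray:
    """Log-spaced alpha grid over [0.001, 1] for topology sweeps."""
    return np.logspace(np.log10(0.001), 0.0, n_points)


def threshold_sweep(corr: GroupCorrMatrix, alphas=None) -> pd.DataFrame:
    """Topology metrics of the p < alpha network at each alpha.

    Edge sets are nested across the (ascending) grid, so mean degree and
    efficiency are non-decreasing in alpha.
    """
    if alphas is None:
        alphas = default_alpha_grid()
    alphas = np.asarray(alphas, dtype=float)
    if np.any(np.diff(alphas) < 0):
        raise ValueError("alpha grid must be sorted ascending")
    regions = corr.regions
    rows = []
    for a in alphas:
        G = nx.Graph()
        G.add_nodes_from(regions)
        P = corr.p.to_numpy()
        R = corr.r.to_numpy()
        ii, jj = np.where(np.triu(P < a, k=1))
        for i, j in zip(ii, jj):
            G.add_edge(regions[i], regions[j], r=R[i, j], p=P[i, j])
        rows.append({"alpha": a, **topology_metrics(G)})
    return pd.DataFrame(rows)


def abs_r_distribution(corr: GroupCorrMatrix, region_subset=None) -> np.ndarray:
    """Upper-triangle |r| values, optionally over a region subset.

    Used to compare the correlation-strength distribution of a planted or
    clustered block (e.g. sensorimotor regions) against the whole matrix.
    """
    if region_subset is None:
        sub = corr.r
    else:
        missing = [r for r in region_subset if r not in corr.r.index]
        if missing:
            raise KeyError(f"unknown region(s): {missing}")
        sub = corr.r.loc[region_subset, region_subset]
    vals = sub.to_numpy()
    iu = np.triu_indices(len(sub), k=1)
    tri = vals[iu]
    return np.abs(tri[~np.isnan(tri)])
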