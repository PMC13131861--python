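"""Tests for region correlation matrices, networks and topology metrics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sundown.network import (
    abs_r_distribution,
    joined_network,
    region_correlations,
    significance_mask,
    threshold_sweep,
    topology_metrics,
)
from sundown.synth import SynthConfig, gen_brain_behavior


def brute_force_metrics(adj: np.ndarray):
    """Adjacency-matrix oracle: Floyd–Warshall + triangle counting."""
    n = len(adj)
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                dist[i, j] = min(dist[i, j], dist[i, k] + dist[k, j])
    # mean degree
    deg = adj.sum(axis=1)
    mean_degree = deg.mean()
    # global efficiency: mean of 1/d over ordered pairs, 1/inf = 0
    eff = 0.0
    if n > 1:
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
        eff = inv[~np.eye(n, dtype=bool)].mean()
    # local clustering
    cl = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = len(nb)
        if k >= 2:
            links = adj[np.ix_(nb, nb)].sum() / 2
            cl[i] = links / (k * (k - 1) / 2)
    # betweenness by path enumeration over all simple shortest paths
    bet = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t or not np.isfinite(dist[s, t]) or dist[s, t] == 0:
                continue
            paths = _all_shortest_paths(adj, dist, s, t)
            for v in range(n):
                if v in (s, t):
                    continue
                on = sum(1 for p in paths if v in p)
                bet[v] += on / len(paths)
    if n > 2:
        bet /= (n - 1) * (n - 2) / 2
    return {
        "mean_degree": mean_degree,
        "mean_efficiency": eff,
        "mean_clustering": cl.mean(),
        "mean_betweenness": bet.mean() if n > 2 else 0.0,
    }


def _all_shortest_paths(adj, dist, s, t):
    out = []

    def extend(path):
        v = path[-1]
        if v == t:
            out.append(path)
            return
        for w in np.flatnonzero(adj[v]):
            if dist[s, w] == dist[s, v] + 1 and dist[w, t] == dist[s, t] - dist[s, w]:
                extend(path + [w])

    extend([s])
    return out


def graph_from_adj(adj):
    G = nx.Graph()
    G.add_nodes_from(range(len(adj)))
    for i, j in zip(*np.where(np.triu(adj, 1))):
        G.add_edge(int(i), int(j))
    return G


class TestRegionCorrelations:
    def test_p_value_matches_t_oracle(self):
        # plant a pair with known r, check p against direct t CDF evaluation
        rng = np.random.default_rng(3)
        n = 7
        x = rng.standard_normal(n)
        y = 0.8 * x + 0.4 * rng.standard_normal(n)
        df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                           "group": "A", "r1": x, "r2": y})
        corr = region_correlations(df, "A")
        r = corr.r.loc["r1", "r2"]
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        expect = 2 * stats.t.sf(abs(t), df=n - 2)
        assert corr.p.loc["r1", "r2"] == pytest.approx(expect, rel=1e-12)

    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((8, 4)), columns=list("abcd"))
        df.insert(0, "group", "G")
        corr = region_correlations(df, "G")
        R = corr.r.to_numpy()
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)
        assert np.allclose(corr.p.to_numpy(), corr.p.to_numpy().T, equal_nan=True)

    def test_pairwise_complete_marks_insufficient_pairs_undefined(self):
        df = pd.DataFrame({
            "group": "G",
            "a": [1.0, 2, 3, 4, 5, 6],
            "b": [np.nan, np.nan, np.nan, 4.0, 2, 7],
        })
        corr = region_correlations(df, "G", min_n=4)
        assert np.isnan(corr.r.loc["a", "b"])
        assert corr.n.loc["a", "b"] == 3

    def test_absent_group_raises(self):
        df = pd.DataFrame({"group": ["G"], "a": [1.0]})
        with pytest.raises(ValueError, match="not present"):
            region_correlations(df, "H")


class TestSignificanceMask:
    def test_alpha_one_selects_all_defined_offdiagonal(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((10, 5)),
                          columns=[f"r{i}" for i in range(5)])
        df.insert(0, "group", "G")
        corr = region_correlations(df, "G")
        mask = significance_mask(corr, 1.0)
        expect = ~np.eye(5, dtype=bool)
        assert np.array_equal(mask.to_numpy(), expect)

    def test_alpha_below_floor_gives_all_false(self):
        # with n = 5 the minimum attainable p is bounded away from 0
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((5, 4)),
                          columns=[f"r{i}" for i in range(4)])
        df.insert(0, "group", "G")
        corr = region_correlations(df, "G")
        floor = np.nanmin(corr.p.to_numpy()[~np.eye(4, dtype=bool)])
        mask = significance_mask(corr, floor / 2)
        assert not mask.to_numpy().any()

    def test_mask_density_grows_with_planted_strength(self):
        densities = []
        for strength in (0.0, 0.6, 0.9):
            cfg = SynthConfig(seed=9, n_per_group=20, n_regions=12, n_behaviors=4,
                              latent_strength=0.0, missing_rate=0.0,
                              cluster_spec=[(list(range(8)), strength)] if strength else [])
            brain, _, _ = gen_brain_behavior(cfg)
            corr = region_correlations(brain, "AD")
            m = significance_mask(corr, 0.005).to_numpy()
            densities.append(m.mean())
        assert densities[0] <= densities[1] <= densities[2]
        assert densities[2] > densities[0]


class TestJoinedNetwork:
    def test_density_one_gives_complete_graph(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.standard_normal((12, 6)),
                          columns=[f"r{i}" for i in range(6)])
        df.insert(0, "group", np.repeat(["A", "B"], 6))
        corrs = {g: region_correlations(df, g) for g in ("A", "B")}
        nets = joined_network(corrs, edge_density=1.0)
        for net in nets.values():
            assert net.graph.number_of_edges() == 6 * 5 // 2

    def test_137_nodes_at_density_0015_keeps_140_edges(self):
        # arithmetic oracle: round(0.015 * 137*136/2) = round(139.74) = 140
        n = 137
        rng = np.random.default_rng(8)
        names = [f"reg_{i:03d}" for i in range(n)]
        frames = []
        for g in ("Ctrl", "AD"):
            f = pd.DataFrame(rng.standard_normal((8, n)), columns=names)
            f.insert(0, "group", g)
            frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        corrs = {g: region_correlations(df, g) for g in ("Ctrl", "AD")}
        nets = joined_network(corrs, edge_density=0.015)
        for net in nets.values():
            assert net.graph.number_of_edges() == 140
            assert abs(net.provenance["achieved_density"] - 0.015) < 1 / (n * (n - 1) / 2)

    def test_planted_cluster_appears_only_in_its_group(self):
        rng = np.random.default_rng(10)
        n_sub, n_reg = 12, 15
        names = [f"reg_{i:03d}" for i in range(n_reg)]
        block = list(range(5))
        frames = []
        for g, plant in (("Ctrl", False), ("AD", True)):
            X = rng.standard_normal((n_sub, n_reg))
            if plant:
                shared = rng.standard_normal(n_sub)
                X[:, block] += 3.0 * shared[:, None]
            f = pd.DataFrame(X, columns=names)
            f.insert(0, "group", g)
            frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        corrs = {g: region_correlations(df, g) for g in ("Ctrl", "AD")}
        nets = joined_network(corrs, edge_density=0.1)
        block_names = {names[i] for i in block}

        def block_edges(net):
            return sum(1 for a, b in net.graph.edges
                       if a in block_names and b in block_names)

        assert block_edges(nets["AD"]) > block_edges(nets["Ctrl"])
        # most retained AD edges concentrate in the planted block
        assert block_edges(nets["AD"]) >= 0.7 * nets["AD"].graph.number_of_edges()


class TestTopologyMetrics:
    def test_complete_graph_k4(self):
        m = topology_metrics(graph_from_adj(1 - np.eye(4)))
        assert m["mean_degree"] == pytest.approx(3.0)
        assert m["mean_efficiency"] == pytest.approx(1.0)
        assert m["mean_clustering"] == pytest.approx(1.0)
        assert m["mean_betweenness"] == pytest.approx(0.0)

    def test_path_graph_3_nodes(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        m = topology_metrics(graph_from_adj(adj))
        assert m["mean_efficiency"] == pytest.approx(5 / 6)
        assert m["mean_betweenness"] == pytest.approx(1 / 3)

    def test_edgeless_graph(self):
        m = topology_metrics(graph_from_adj(np.zeros((5, 5))))
        assert all(v == 0 for v in m.values())

    def test_exhaustive_small_graphs_match_oracle(self):
        # every graph on up to 5 nodes
        for n in range(2, 6):
            pairs = list(itertools.combinations(range(n), 2))
            for bits in range(2 ** len(pairs)):
                adj = np.zeros((n, n))
                for b, (i, j) in enumerate(pairs):
                    if bits >> b & 1:
                        adj[i, j] = adj[j, i] = 1
                got = topology_metrics(graph_from_adj(adj))
                want = brute_force_metrics(adj)
                for k in want:
                    assert got[k] == pytest.approx(want[k], abs=1e-12), (n, bits, k)

    def test_random_graphs_n8_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            adj = np.triu((rng.random((n, n)) < 0.4).astype(float), 1)
            adj = adj + adj.T
            got = topology_metrics(graph_from_adj(adj))
            want = brute_force_metrics(adj)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-10)


@pytest.fixture(scope="module")
def corr():
    rng = np.random.default_rng(12)
    df = pd.DataFrame(rng.standard_normal((10, 12)),
                      columns=[f"r{i}" for i in range(12)])
    df.insert(0, "group", "G")
    return region_correlations(df, "G")


class TestThresholdSweep:

    def test_monotone_degree_and_efficiency(self, corr):
        sweep = threshold_sweep(corr)
        assert (np.diff(sweep["mean_degree"]) >= -1e-12).all()
        assert (np.diff(sweep["mean_efficiency"]) >= -1e-12).all()

    def test_alpha_one_matches_complete_graph(self, corr):
        sweep = threshold_sweep(corr, [1.0])
        n = len(corr.regions)
        assert sweep["mean_degree"].iloc[0] == pytest.approx(n - 1)
        assert sweep["mean_efficiency"].iloc[0] == pytest.approx(1.0)

    def test_bit_exact_reproducibility(self, corr):
        s1 = threshold_sweep(corr)
        s2 = threshold_sweep(corr)
        pd.testing.assert_frame_equal(s1, s2)


class TestAbsRDistribution:
    def test_subset_count(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.standard_normal((9, 6)),
                          columns=[f"r{i}" for i in range(6)])
        df.insert(0, "group", "G")
        corr = region_correlations(df, "G")
        assert len(abs_r_distribution(corr)) == 15
        assert len(abs_r_distribution(corr, ["r0", "r1", "r2"])) == 3

    def test_unknown_region_raises(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.standard_normal((6, 3)), columns=list("abc"))
        df.insert(0, "group", "G")
        corr = region_correlations(df, "G")
        with pytest.raises(KeyError):
            abs_r_distribution(corr, ["zz"])

    def test_planted_block_has_elevated_mean(self):
        cfg = SynthConfig(seed=15, n_per_group=20, n_regions=15, n_behaviors=4,
                          latent_strength=0.0, missing_rate=0.0,
                          cluster_spec=[(list(range(5)), 0.8)])
        brain, _, truth = gen_brain_behavior(cfg)
        corr = region_correlations(brain, "AD")
        subset = truth.cluster_members[0]
        assert abs_r_distribution(corr, subset).mean() > abs_r_distribution(corr).mean()
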