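"""Summary graphs, hyperedge bundling, system matrices, hub correlations."""

import numpy as np
import pandas as pd
import pytest

from crossfreq.networks import (
    SummaryGraph,
    bh_adjust,
    cluster_hyperedges,
    cross_frequency_degree_similarity,
    degree_correlation,
    edge_adjacency,
    pool_ratios,
    select_central_edges,
    single_ratio_attribution,
    system_density,
)
from crossfreq.parcels import ParcelMeta


def make_meta(n, crosstalk=None, n_systems=7):
    meta = ParcelMeta.identity(n, n_systems=n_systems)
    if crosstalk is not None:
        meta.crosstalk_matrix = crosstalk
    return meta


class TestPoolRatios:
    def test_shared_edge_weight_counts_ratios(self):
        sets = {m: [(0, 1)] for m in range(2, 10)}
        g = pool_ratios(sets, n_parcels=4)
        assert len(g.edges) == 1
        assert g.edges.weight.iloc[0] == 8

    def test_disjoint_sets_weight_one(self):
        sets = {2: [(0, 1)], 3: [(1, 2)], 4: [(2, 3)]}
        g = pool_ratios(sets, n_parcels=4)
        assert np.all(g.edges.weight == 1)
        assert len(g.edges) == 3

    def test_empty_inputs(self):
        g = pool_ratios({}, n_parcels=4)
        assert len(g.edges) == 0
        assert g.lf_degree().sum() == 0


class TestSingleRatioAttribution:
    def test_dominant_ratio_gets_small_p(self):
        members = [2] * 12
        pooled = [2] * 20 + [3] * 20 + [4] * 20
        p = single_ratio_attribution(members, pooled, n_permutations=500, rng=0)
        assert p < 0.05

    def test_uniform_mixture_retained(self):
        members = [2, 3, 4, 5, 2, 3, 4, 5]
        pooled = [2, 3, 4, 5] * 10
        p = single_ratio_attribution(members, pooled, n_permutations=500, rng=0)
        assert p > 0.2

    def test_single_member_p_is_one(self):
        assert single_ratio_attribution([3], [2, 3, 4]) == 1.0


class TestEdgeAdjacency:
    def test_identical_edges_unit_affinity(self):
        edges = pd.DataFrame({"parcel_low": [0, 0], "parcel_high": [1, 1]})
        aff = edge_adjacency(edges, make_meta(3))
        assert aff[0, 1] == pytest.approx(1.0)

    def test_crosstalk_product(self):
        ct = np.eye(4)
        ct[0, 1] = ct[1, 0] = 0.5
        ct[2, 3] = ct[3, 2] = 0.4
        edges = pd.DataFrame({"parcel_low": [0, 1], "parcel_high": [2, 3]})
        aff = edge_adjacency(edges, make_meta(4, ct))
        assert aff[0, 1] == pytest.approx(0.5 * 0.4)

    def test_zero_crosstalk_zero_affinity(self):
        edges = pd.DataFrame({"parcel_low": [0, 1], "parcel_high": [2, 3]})
        aff = edge_adjacency(edges, make_meta(4, np.eye(4)))
        assert aff[0, 1] == 0.0


class TestClusterHyperedges:
    @staticmethod
    def _edges(pairs, ratios=None):
        df = pd.DataFrame(pairs, columns=["parcel_low", "parcel_high"])
        if ratios is not None:
            df["ratio"] = ratios
        return df

    def test_tight_bundle_survives_isolates_dropped(self):
        pairs = [(0, 5), (1, 5), (0, 6), (1, 6), (2, 5), (3, 8), (4, 9)]
        n = len(pairs)
        aff = np.zeros((n, n))
        aff[:5, :5] = 0.9
        np.fill_diagonal(aff, 1.0)
        bundles = cluster_hyperedges(self._edges(pairs), aff, min_size=4)
        assert len(bundles) == 1
        assert bundles[0].size >= 3  # low-centrality members may be trimmed

    def test_zero_affinity_gives_no_bundles(self):
        pairs = [(0, 2), (1, 3), (0, 3), (1, 2), (2, 3)]
        bundles = cluster_hyperedges(self._edges(pairs), np.eye(5))
        assert bundles == []

    def test_min_size_rule_drops_small_bundles(self):
        pairs = [(0, 3), (1, 3), (2, 3)]
        aff = np.full((3, 3), 0.9)
        np.fill_diagonal(aff, 1.0)
        assert cluster_hyperedges(self._edges(pairs), aff, min_size=4) == []
        assert len(cluster_hyperedges(self._edges(pairs), aff, min_size=3)) == 1

    def test_invariant_to_edge_order(self):
        rng = np.random.default_rng(0)
        pairs = [(0, 5), (1, 5), (0, 6), (1, 6), (2, 6), (3, 8), (4, 9), (3, 9)]
        n = len(pairs)
        aff = rng.uniform(0, 1, (n, n))
        aff = (aff + aff.T) / 2
        np.fill_diagonal(aff, 1.0)
        perm = rng.permutation(n)
        edges_a = self._edges(pairs)
        edges_b = edges_a.iloc[perm].reset_index(drop=True)
        a = cluster_hyperedges(edges_a, aff)
        b = cluster_hyperedges(edges_b, aff[np.ix_(perm, perm)])
        assert [h.member_edges for h in a] == [h.member_edges for h in b]


class TestSelectCentralEdges:
    @staticmethod
    def _graph(pairs, n_parcels=12):
        df = pd.DataFrame(pairs, columns=["parcel_low", "parcel_high"])
        df["weight"] = 1
        df["ratios"] = [(2,)] * len(df)
        return SummaryGraph(edges=df, n_parcels=n_parcels)

    def test_star_graph_all_ranked_top(self):
        star = [(0, q) for q in range(1, 6)] + [(7, 8)]
        out = select_central_edges(self._graph(star), 5, end="LF")
        assert set(out.edges.parcel_low) == {0}

    def test_zero_selection_empty(self):
        out = select_central_edges(self._graph([(0, 1), (1, 2)]), 0)
        assert len(out.edges) == 0

    def test_two_hub_ranking(self):
        big = [(0, q) for q in range(1, 11)]
        small = [(11, q) for q in range(1, 6)]
        out = select_central_edges(self._graph(big + small), 10, end="LF")
        assert set(out.edges.parcel_low) == {0}

    def test_oversized_request_returns_all(self):
        g = self._graph([(0, 1), (1, 2)])
        assert len(select_central_edges(g, 99).edges) == 2


class TestSystemDensity:
    def test_single_system_pair_concentration(self):
        meta = make_meta(8, n_systems=4)  # systems round-robin 0..3
        # edges all from system-0 parcels (0,4) to system-1 parcels (1,5)
        df = pd.DataFrame({"parcel_low": [0, 0, 4, 4], "parcel_high": [1, 5, 1, 5]})
        g = SummaryGraph(edges=df, n_parcels=8)
        sm = system_density(g, meta, n_rand=200, rng=0)
        assert sm.K[0, 1] == pytest.approx(1.0)
        mask = np.ones_like(sm.K, dtype=bool)
        mask[0, 1] = False
        assert np.all(sm.K[mask] == 0)

    def test_randomizations_preserve_edge_count(self):
        meta = make_meta(6, n_systems=3)
        rng = np.random.default_rng(1)
        pairs = [(int(p), int(q)) for p in range(6) for q in range(6)
                 if p != q and rng.uniform() < 0.3]
        df = pd.DataFrame(pairs, columns=["parcel_low", "parcel_high"])
        g = SummaryGraph(edges=df, n_parcels=6)
        sm = system_density(g, meta, n_rand=300, rng=2)
        assert sm.edge_counts.sum() == len(pairs)
        # randomized graphs keep the count: thresholds bounded by K of a
        # graph with exactly len(pairs) edges
        possible = 6 * 5
        assert np.nanmax(sm.null_threshold) <= len(pairs) / (2 * 2) / 1  # sanity bound

    def test_calibration_near_nominal(self):
        # a uniformly random graph should rarely beat the 95th percentile
        meta = make_meta(10, n_systems=5)
        rng = np.random.default_rng(3)
        flags = []
        for rep in range(30):
            pairs = [(p, q) for p in range(10) for q in range(10)
                     if p != q and rng.uniform() < 0.25]
            df = pd.DataFrame(pairs, columns=["parcel_low", "parcel_high"])
            sm = system_density(SummaryGraph(edges=df, n_parcels=10), meta,
                                n_rand=100, rng=rep)
            flags.append(sm.significant.mean())
        assert np.mean(flags) < 0.12


class TestDegreeCorrelations:
    def test_identical_graphs_unit_r(self):
        df = pd.DataFrame({"parcel_low": [0, 1, 2], "parcel_high": [3, 4, 5],
                           "weight": 1, "ratios": [(2,)] * 3})
        g = SummaryGraph(edges=df, n_parcels=6)
        res = degree_correlation(g, g.lf_degree(), g.hf_degree())
        assert res["LF"]["r"] == pytest.approx(1.0)
        assert res["HF"]["r"] == pytest.approx(1.0)

    def test_matches_pearson_oracle(self, rng):
        deg_ps = rng.integers(0, 10, size=10).astype(float)
        df = pd.DataFrame({"parcel_low": rng.integers(0, 10, 30),
                           "parcel_high": rng.integers(0, 10, 30)})
        df["weight"] = 1
        g = SummaryGraph(edges=df, n_parcels=10)
        res = degree_correlation(g, deg_ps, deg_ps)
        expected = np.corrcoef(g.lf_degree(), deg_ps)[0, 1]
        assert res["LF"]["r"] == pytest.approx(expected, abs=1e-12)

    def test_constant_degrees_reported_nan(self):
        df = pd.DataFrame({"parcel_low": [0], "parcel_high": [1], "weight": 1})
        g = SummaryGraph(edges=df, n_parcels=4)
        res = degree_correlation(g, np.zeros(4), np.zeros(4))
        assert np.isnan(res["LF"]["r"])

    def test_degree_similarity_matrix_properties(self, rng):
        deg = rng.integers(0, 8, size=(5, 20)).astype(float)
        r = cross_frequency_degree_similarity(deg)
        assert r.shape == (5, 5)
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)
        identical = cross_frequency_degree_similarity(np.tile(deg[0], (4, 1)))
        assert np.allclose(identical, 1.0)

    def test_bh_adjust_handles_nan(self):
        adj, rej = bh_adjust([0.001, np.nan, 0.8])
        assert np.isnan(adj[1]) and not rej[1]
        assert rej[0]
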