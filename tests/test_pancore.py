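"""Pan/core algebra, graph statistics against brute-force oracles, power-law
fits, the sub-threshold PCC test and the reference-overlap permutation test."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import pancoexpr as px


def _net(series_id, pairs):
    edges = {px.ordered_pair(a, b): w for a, b, w in pairs}
    return px.CoexpressionNetwork(series_id=series_id, edges=edges,
                                  pcc_cutoff=min((w for *_, w in pairs),
                                                 default=None))


# ---------------------------------------------------------------------------
# universality / pan algebra
# ---------------------------------------------------------------------------

def test_identical_networks_all_u2():
    pairs = [("a", "b", 0.9), ("b", "c", 0.8)]
    pan = px.compute_universality([_net("s1", pairs), _net("s2", pairs)])
    assert pan.n_edges == 2
    assert all(rec.universality == 2 for rec in pan.edges.values())
    assert px.universality_histogram(pan) == {2: 2}


def test_disjoint_networks_all_u1():
    pan = px.compute_universality([
        _net("s1", [("a", "b", 0.9)]),
        _net("s2", [("c", "d", 0.8), ("d", "e", 0.7)])])
    assert pan.n_edges == 3
    assert all(rec.universality == 1 for rec in pan.edges.values())
    assert px.universality_histogram(pan) == {1: 3}


def test_duplicate_series_id_rejected():
    with pytest.raises(px.ConfigurationError, match="duplicate"):
        px.compute_universality([_net("s1", [("a", "b", 0.9)]),
                                 _net("s1", [("a", "b", 0.8)])])


def test_histogram_sums_to_pan_edges(tiny_bundle):
    hist = px.universality_histogram(tiny_bundle.pan)
    assert sum(hist.values()) == tiny_bundle.pan.n_edges
    assert all(1 <= u <= tiny_bundle.pan.n_networks for u in hist)


def test_union_algebra_over_subcollections(tiny_bundle):
    """pan(A ∪ B) edge set = pan(A) ∪ pan(B); universality adds across
    disjoint sub-collections."""
    nets = tiny_bundle.networks
    a, b = nets[:2], nets[2:]
    pan_a = px.compute_universality(a)
    pan_b = px.compute_universality(b)
    pan_ab = px.compute_universality(nets)
    assert set(pan_ab.edges) == set(pan_a.edges) | set(pan_b.edges)
    for pair, rec in pan_ab.edges.items():
        ua = pan_a.edges[pair].universality if pair in pan_a.edges else 0
        ub = pan_b.edges[pair].universality if pair in pan_b.edges else 0
        assert rec.universality == ua + ub


def test_planted_core_modal_universality(tiny_bundle):
    """Within-module edges of a core module planted in 4 of 5 series have
    modal U near 4; specific-module edges never exceed their presence."""
    truth = tiny_bundle.truth
    pan = tiny_bundle.pan
    for mid, genes in truth.modules.items():
        presence = len(truth.active_series[mid])
        gs = sorted(genes)
        us = [pan.edges[(a, b)].universality
              for i, a in enumerate(gs) for b in gs[i + 1:]
              if (a, b) in pan.edges]
        assert us, mid
        if truth.module_kind[mid] == "core":
            modal = max(set(us), key=us.count)
            assert abs(modal - presence) <= 1
        else:
            # specific modules have no background loading: U is bounded by
            # the planted presence
            assert max(us) <= presence


# ---------------------------------------------------------------------------
# core extraction
# ---------------------------------------------------------------------------

def test_core_u1_equals_pan(tiny_bundle):
    core1 = px.core_at_cutoff(tiny_bundle.pan, 1)
    assert core1.number_of_edges() == tiny_bundle.pan.n_edges
    assert set(map(frozenset, core1.edges)) == set(
        map(frozenset, tiny_bundle.pan.edges))


def test_core_above_n_networks_empty(tiny_bundle):
    with pytest.warns(UserWarning, match="empty"):
        g = px.core_at_cutoff(tiny_bundle.pan,
                              tiny_bundle.pan.n_networks + 1)
    assert g.number_of_edges() == 0


def test_core_nestedness(tiny_bundle):
    prev = None
    for u in range(1, tiny_bundle.pan.n_networks + 1):
        edges = set(map(frozenset, px.core_at_cutoff(tiny_bundle.pan, u).edges))
        if prev is not None:
            assert edges <= prev
        prev = edges


def test_core_nodes_are_incident_only():
    pan = px.compute_universality([
        _net("s1", [("a", "b", 0.9), ("c", "d", 0.9)]),
        _net("s2", [("a", "b", 0.8)])])
    core = px.core_at_cutoff(pan, 2)
    assert set(core.nodes) == {"a", "b"}


# ---------------------------------------------------------------------------
# clustering coefficient / modularity (brute-force oracles)
# ---------------------------------------------------------------------------

def _brute_avg_clustering(g: nx.Graph) -> float:
    total = 0.0
    for n in g.nodes:
        nbrs = list(g.neighbors(n))
        d = len(nbrs)
        if d < 2:
            continue
        links = sum(1 for u, v in itertools.combinations(nbrs, 2)
                    if g.has_edge(u, v))
        total += 2.0 * links / (d * (d - 1))
    return total / g.number_of_nodes()


def _brute_modularity(g: nx.Graph, member: dict) -> float:
    m = g.number_of_edges()
    q = 0.0
    for c in set(member.values()):
        nodes = [n for n in g.nodes if member[n] == c]
        e_c = sum(1 for u, v in itertools.combinations(nodes, 2)
                  if g.has_edge(u, v))
        d_c = sum(g.degree(n) for n in nodes)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def test_triangle_clustering_one():
    assert px.clustering_coefficient(nx.complete_graph(3)) == pytest.approx(1.0)


def test_star_clustering_zero():
    assert px.clustering_coefficient(nx.star_graph(4)) == pytest.approx(0.0)


def test_chorded_cycle_clustering_matches_enumeration():
    g = nx.cycle_graph(4)
    g.add_edge(0, 2)
    assert px.clustering_coefficient(g) == pytest.approx(
        _brute_avg_clustering(g))
    assert px.clustering_coefficient(g) == pytest.approx(5 / 6)


def test_clustering_empty_graph_nan():
    assert math.isnan(px.clustering_coefficient(nx.Graph()))


def test_clustering_matches_oracle_random_graphs():
    rng = np.random.default_rng(12)
    for _ in range(40):
        g = nx.gnp_random_graph(8, rng.uniform(0.2, 0.8),
                                seed=int(rng.integers(10_000)))
        if g.number_of_nodes() == 0:
            continue
        assert px.clustering_coefficient(g) == pytest.approx(
            _brute_avg_clustering(g), abs=1e-12)


def test_modularity_single_community_zero():
    g = nx.gnp_random_graph(8, 0.5, seed=1)
    part = {n: 0 for n in g.nodes}
    assert px.modularity_score(g, part) == pytest.approx(0.0)


def test_modularity_two_triangles_half():
    """Two disjoint triangles, each its own community: per community
    e_c/m = 3/6 and (d_c/2m)^2 = (6/12)^2, so Q = 2*(1/2 - 1/4) = 1/2."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
    assert px.modularity_score(g, part) == pytest.approx(0.5)


def test_modularity_bounds_and_oracle_random():
    rng = np.random.default_rng(13)
    for _ in range(40):
        g = nx.gnp_random_graph(7, rng.uniform(0.3, 0.9),
                                seed=int(rng.integers(10_000)))
        if g.number_of_edges() == 0:
            continue
        member = {n: int(rng.integers(3)) for n in g.nodes}
        q = px.modularity_score(g, member)
        assert -0.5 <= q <= 1.0
        assert q == pytest.approx(_brute_modularity(g, member), abs=1e-12)
        comms = [{n for n in g.nodes if member[n] == c}
                 for c in set(member.values())]
        assert q == pytest.approx(
            nx.community.modularity(g, comms), abs=1e-12)


def test_modularity_missing_node_error():
    g = nx.path_graph(3)
    with pytest.raises(ValueError, match="cover"):
        px.modularity_score(g, {0: 0, 1: 0})


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------

def test_louvain_recovers_joined_cliques():
    g = nx.Graph()
    for offset in (0, 5):
        for u, v in itertools.combinations(range(offset, offset + 5), 2):
            g.add_edge(u, v)
    g.add_edge(0, 5)
    part = px.detect_communities(g, seed=2)
    assert sorted(map(sorted, part.communities)) == [
        [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]
    singles_q = px.modularity_score(g, {n: n for n in g.nodes})
    assert part.modularity >= singles_q


def test_louvain_deterministic_given_seed(tiny_bundle):
    g = px.core_at_cutoff(tiny_bundle.pan, 2)
    p1 = px.detect_communities(g, seed=5)
    p2 = px.detect_communities(g, seed=5)
    assert p1.communities == p2.communities
    assert p1.modularity == p2.modularity


def test_disconnected_components_not_merged():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (10, 11), (11, 12), (10, 12)])
    part = px.detect_communities(g, seed=0)
    for comm in part.communities:
        assert comm <= {0, 1, 2} or comm <= {10, 11, 12}


# ---------------------------------------------------------------------------
# degree distribution / power law / hubs
# ---------------------------------------------------------------------------

def test_degree_distribution_trivial():
    assert px.degree_distribution(nx.complete_graph(3)) == {2: 3}
    assert px.degree_distribution(nx.star_graph(4)) == {1: 4, 4: 1}


def test_degree_distribution_handshake():
    rng = np.random.default_rng(6)
    for _ in range(20):
        g = nx.gnp_random_graph(15, rng.uniform(0.1, 0.7),
                                seed=int(rng.integers(10_000)))
        hist = px.degree_distribution(g)
        assert sum(hist.values()) == g.number_of_nodes()
        assert sum(k * c for k, c in hist.items()) == 2 * g.number_of_edges()


def test_power_law_recovers_constructed_exponent():
    hist = {k: int(round(1000 * k ** -1.5)) for k in range(1, 51)}
    assert px.fit_power_law(hist, 50) == pytest.approx(-1.5, abs=0.05)


def test_power_law_flat_histogram_zero_slope():
    hist = {k: 7 for k in range(1, 20)}
    assert px.fit_power_law(hist, 19) == pytest.approx(0.0, abs=1e-12)


def test_power_law_scale_invariant():
    hist = {k: int(round(500 * k ** -1.2)) for k in range(1, 40)}
    s1 = px.fit_power_law(hist, 39)
    s2 = px.fit_power_law({k: 10 * c for k, c in hist.items()}, 39)
    assert s1 == pytest.approx(s2, abs=1e-9)


def test_power_law_insufficient_support():
    with pytest.raises(ValueError, match="3 distinct"):
        px.fit_power_law({1: 5, 2: 3}, 50)


def test_hub_table_star_and_truncation():
    g = nx.star_graph(4)  # center 0
    hubs = px.hub_table(g, top_n=3)
    assert hubs[0] == (0, 4)
    assert len(hubs) == 3
    assert len(px.hub_table(g, top_n=99)) == 5


def test_hub_table_stable_under_relabel_order():
    g1 = nx.Graph([(f"g{i}", f"g{j}") for i, j in
                   [(0, 1), (0, 2), (0, 3), (1, 2)]])
    g2 = nx.Graph()
    for u, v in reversed(list(g1.edges)):
        g2.add_edge(u, v)
    assert px.hub_table(g1) == px.hub_table(g2)


# ---------------------------------------------------------------------------
# topology profile
# ---------------------------------------------------------------------------

def test_profile_monotone_counts(tiny_bundle):
    prof = px.topology_profile(tiny_bundle.pan,
                               range(1, tiny_bundle.pan.n_networks + 1),
                               seed=0)
    assert (prof["n_nodes"].diff().dropna() <= 0).all()
    assert (prof["n_edges"].diff().dropna() <= 0).all()


def test_profile_two_triangles_clustering_one():
    nets = [
        _net("s1", [("a", "b", .9), ("b", "c", .9), ("a", "c", .9),
                    ("x", "y", .9), ("y", "z", .9), ("x", "z", .9)]),
        _net("s2", [("a", "b", .8), ("b", "c", .8), ("a", "c", .8),
                    ("x", "y", .8), ("y", "z", .8), ("x", "z", .8),
                    ("a", "x", .8)]),
    ]
    pan = px.compute_universality(nets)
    prof = px.topology_profile(pan, [1, 2], seed=0)
    assert prof.loc[2, "clustering"] == pytest.approx(1.0)
    assert prof.loc[2, "n_edges"] == 6


def test_profile_empty_cutoff_is_nan():
    pan = px.compute_universality([_net("s1", [("a", "b", .9)]),
                                   _net("s2", [("a", "b", .9)])])
    pan.edges[("a", "b")].series_ids.pop()  # force U=1 only
    pan.edges[("a", "b")].pccs.pop()
    prof = px.topology_profile(pan, [1, 2], seed=0)
    assert prof.loc[2, "n_edges"] == 0
    assert math.isnan(prof.loc[2, "modularity"])


# ---------------------------------------------------------------------------
# sub-threshold PCC test
# ---------------------------------------------------------------------------

def test_subthreshold_core_exceeds_pan(tiny_bundle):
    """Core edges stay more correlated than typical pan edges in series
    where they missed the cutoff."""
    core = px.core_at_cutoff(tiny_bundle.pan, 3)
    res = px.subthreshold_pcc_test(tiny_bundle.pan, core,
                                   tiny_bundle.matrices)
    assert res.mean_core > res.mean_pan
    assert res.p < 0.01
    assert res.n_core > 0 and res.n_pan >= res.n_core


def test_subthreshold_welch_matches_formula(tiny_bundle):
    """The Welch statistic equals the textbook formula recomputed from the
    two samples' means and variances."""
    from scipy import stats as sps
    core = px.core_at_cutoff(tiny_bundle.pan, 3)
    res = px.subthreshold_pcc_test(tiny_bundle.pan, core,
                                   tiny_bundle.matrices)
    # reconstruct samples independently
    core_pairs = {px.ordered_pair(a, b) for a, b in core.edges}
    s_core, s_pan = [], []
    for sid, m in tiny_bundle.matrices.items():
        for pair, rec in tiny_bundle.pan.edges.items():
            if sid in rec.series_ids:
                continue
            if pair[0] in m.index and pair[1] in m.index:
                r = np.corrcoef(m.loc[pair[0]], m.loc[pair[1]])[0, 1]
                s_pan.append(r)
                if pair in core_pairs:
                    s_core.append(r)
    v1, v2 = np.var(s_core, ddof=1), np.var(s_pan, ddof=1)
    n1, n2 = len(s_core), len(s_pan)
    t_hand = (np.mean(s_core) - np.mean(s_pan)) / math.sqrt(v1 / n1 + v2 / n2)
    assert res.t == pytest.approx(t_hand, rel=1e-9)
    assert res.n_core == n1 and res.n_pan == n2


def test_subthreshold_empty_sample_undefined():
    nets = [_net("s1", [("a", "b", .9)]), _net("s2", [("a", "b", .9)])]
    pan = px.compute_universality(nets)
    core = px.core_at_cutoff(pan, 2)
    with pytest.warns(UserWarning, match="empty sample"):
        res = px.subthreshold_pcc_test(pan, core, {})
    assert math.isnan(res.p)


# ---------------------------------------------------------------------------
# reference overlap
# ---------------------------------------------------------------------------

def test_reference_self_overlap_minimal_p():
    g = nx.gnp_random_graph(12, 0.4, seed=3)
    ref = {px.ordered_pair(str(a), str(b)) for a, b in g.edges}
    g = nx.relabel_nodes(g, str)
    obs, p = px.reference_overlap_test(g, ref, n_perm=99, seed=0)
    assert obs == g.number_of_edges()
    assert p == pytest.approx(1 / 100)


def test_reference_disjoint_overlap_zero():
    g = nx.relabel_nodes(nx.gnp_random_graph(10, 0.4, seed=4), str)
    ref = {("zz1", "zz2")}
    obs, p = px.reference_overlap_test(g, ref, n_perm=49, seed=0)
    assert obs == 0
    assert p == 1.0


def test_reference_empty_reference():
    g = nx.relabel_nodes(nx.gnp_random_graph(8, 0.5, seed=5), str)
    assert px.reference_overlap_test(g, set(), n_perm=10, seed=0) == (0, 1.0)


def test_rewiring_null_mean_matches_enumeration():
    """Two disjoint edges {ab, cd} admit exactly three degree-preserving
    configurations; each swap moves to one of the other two, so the exact
    chain gives P(back at start after t swaps) = 1/3 + (2/3)(-1/2)^t.
    With reference {ab} and t = 3 swaps the null overlap mean is 1/4."""
    g = nx.Graph([("a", "b"), ("c", "d")])
    expected = 1 / 3 + (2 / 3) * (-0.5) ** 3
    overlaps = []
    for k in range(600):
        h = g.copy()
        nx.double_edge_swap(h, nswap=3, max_tries=300, seed=int(k))
        overlaps.append(1 if h.has_edge("a", "b") else 0)
    se = np.std(overlaps, ddof=1) / np.sqrt(len(overlaps))
    assert np.mean(overlaps) == pytest.approx(expected, abs=3 * se + 0.01)
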