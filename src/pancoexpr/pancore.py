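"""Pan- and core-network analysis.

The *pan-network* is the union of all series networks; every edge carries a
universality number U = how many series networks contained it.  *Core*
networks are extracted by a cutoff U >= u_min (default 10).  This module
also provides the topology profile over universality cutoffs (node count,
average degree, modularity of a detected partition, average clustering),
degree distributions with log-log power-law fits, hub tables, the
sub-threshold PCC t-test (core edges remain more correlated than pan edges
even in series where they missed the cutoff) and the reference-edge-set
overlap test with a degree-preserving rewiring null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .types import (CoexpressionNetwork, ModulePartition, Pair, PanEdge,
                    PanNetwork, ordered_pair)


def compute_universality(networks: list[CoexpressionNetwork]) -> PanNetwork:
    """Merge series networks into the pan-network with per-edge support.

    The pan edge set is exactly the union of the inputs; U counts distinct
    series.  Duplicate series identifiers are rejected to prevent double
    counting.
    """
    if not networks:
        raise ConfigurationError("n_networks: at least one network is required")
    seen: set[str] = set()
    edges: dict[Pair, PanEdge] = {}
    for net in networks:
        if net.series_id in seen:
            raise ConfigurationError(
                f"duplicate series_id {net.series_id!r} in pan-network merge")
        seen.add(net.series_id)
        for pair, w in net.edges.items():
            rec = edges.get(pair)
            if rec is None:
                edges[pair] = PanEdge(series_ids=[net.series_id], pccs=[w])
            else:
                rec.series_ids.append(net.series_id)
                rec.pccs.append(w)
    return PanNetwork(edges=edges, n_networks=len(networks))


def universality_histogram(pan: PanNetwork) -> dict[int, int]:
    """Edge count per universality value; counts sum to the pan edge count."""
    hist: dict[int, int] = {}
    for rec in pan.edges.values():
        hist[rec.universality] = hist.get(rec.universality, 0) + 1
    return dict(sorted(hist.items()))


def core_at_cutoff(pan: PanNetwork, u_min: int = 10) -> nx.Graph:
    """Subgraph of pan edges with U >= u_min; nodes are incident genes only.

    Edge attributes: ``universality`` and ``mean_pcc``.
    """
    if u_min < 1:
        raise ValueError("u_min must be >= 1")
    if u_min > pan.n_networks:
        warnings.warn(
            f"u_min={u_min} exceeds the number of networks ({pan.n_networks}); "
            "core is empty")
    g = nx.Graph()
    for pair in sorted(pan.edges):
        rec = pan.edges[pair]
        if rec.universality >= u_min:
            g.add_edge(pair[0], pair[1], universality=rec.universality,
                       mean_pcc=rec.mean_pcc)
    return g


def clustering_coefficient(graph: nx.Graph, transitivity: bool = False) -> float:
    """Average local clustering coefficient (nodes with degree < 2 count 0).

    ``transitivity=True`` returns the global transitivity instead.
    """
    if graph.number_of_nodes() == 0:
        return float("nan")
    if transitivity:
        return float(nx.transitivity(graph))
    return float(nx.average_clustering(graph, count_zeros=True))


def modularity_score(graph: nx.Graph,
                     partition: list[set[str]] | dict[str, int] | ModulePartition
                     ) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2], unweighted.

    ``partition`` may be a node->community mapping, a list of node sets, or
    a :class:`ModulePartition`.  Every node of the graph must be covered.
    """
    if isinstance(partition, ModulePartition):
        member = partition.membership
    elif isinstance(partition, dict):
        member = partition
    else:
        member = {n: i for i, c in enumerate(partition) for n in c}
    missing = [n for n in graph.nodes if n not in member]
    if missing:
        raise ValueError(f"partition does not cover node {missing[0]!r}")
    m = graph.number_of_edges()
    if m == 0:
        return float("nan")
    within: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for a, b in graph.edges:
        if member[a] == member[b]:
            within[member[a]] = within.get(member[a], 0) + 1
    for n, d in graph.degree:
        degsum[member[n]] = degsum.get(member[n], 0) + d
    q = 0.0
    for c in degsum:
        q += within.get(c, 0) / m - (degsum[c] / (2.0 * m)) ** 2
    return float(q)


def detect_communities(graph: nx.Graph, seed: int = 0) -> ModulePartition:
    """Louvain greedy modularity maximization; deterministic given seed."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect communities of an empty graph")
    comms = nx.community.louvain_communities(graph, seed=seed)
    part = ModulePartition(communities=[frozenset(c) for c in comms],
                           modularity=0.0)
    part.modularity = modularity_score(graph, part)
    return part


def topology_profile(pan: PanNetwork, u_range: range | list[int] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Per-cutoff topology table: nodes, edges, average degree, modularity
    of the Louvain partition detected at that cutoff, average clustering.

    Empty graphs at a cutoff are recorded with NaN metrics, not raised.
    """
    if u_range is None:
        u_range = range(1, pan.n_networks + 1)
    rows = []
    for u in u_range:
        if not (1 <= u <= pan.n_networks):
            raise ValueError(f"u={u} outside [1, {pan.n_networks}]")
        g = core_at_cutoff(pan, u)
        n, e = g.number_of_nodes(), g.number_of_edges()
        if n == 0:
            rows.append({"u": u, "n_nodes": 0, "n_edges": 0,
                         "avg_degree": np.nan, "modularity": np.nan,
                         "clustering": np.nan})
            continue
        part = detect_communities(g, seed=seed)
        rows.append({
            "u": u, "n_nodes": n, "n_edges": e,
            "avg_degree": 2.0 * e / n,
            "modularity": part.modularity,
            "clustering": clustering_coefficient(g),
        })
    return pd.DataFrame(rows).set_index("u")


def degree_distribution(graph: nx.Graph) -> dict[int, int]:
    """degree -> node count; satisfies sum(counts) = N and the handshake
    identity sum(degree * count) = 2E."""
    hist: dict[int, int] = {}
    for _, d in graph.degree:
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def fit_power_law(degree_hist: dict[int, int], tail_cutoff: int) -> float:
    """Log-log least-squares exponent of the degree distribution.

    Fits log10(count) against log10(degree) over degrees 1..tail_cutoff with
    non-zero counts (the regime below the exponential-cutoff transition).
    Requires at least 3 distinct supported degrees.
    """
    ks = np.array([k for k, c in degree_hist.items()
                   if 1 <= k <= tail_cutoff and c > 0], dtype=float)
    if len(ks) < 3:
        raise ValueError(
            "power-law fit needs >= 3 distinct degrees with non-zero counts "
            "below the tail cutoff")
    cs = np.array([degree_hist[int(k)] for k in ks], dtype=float)
    slope, _ = np.polyfit(np.log10(ks), np.log10(cs), 1)
    return float(slope)


def hub_table(graph: nx.Graph, top_n: int = 200) -> list[tuple[str, int]]:
    """Top-``top_n`` nodes by degree (descending), gene-id tie-break."""
    ranked = sorted(graph.degree, key=lambda t: (-t[1], t[0]))
    return [(n, int(d)) for n, d in ranked[:top_n]]


@dataclass
class SubthresholdResult:
    mean_core: float
    mean_pan: float
    t: float
    p: float
    n_core: int
    n_pan: int


def subthreshold_pcc_test(pan: PanNetwork, core: nx.Graph,
                          filtered_matrices: dict[str, pd.DataFrame]
                          ) -> SubthresholdResult:
    """Welch one-sided t-test: core edges keep higher PCC than pan edges in
    series where they were *not* retained.

    Sample 1: PCCs of core edges recomputed in series where the edge missed
    the cutoff (both genes measured there).  Sample 2: the same for all pan
    edges.  ``filtered_matrices`` maps series id to its post-filter
    expression matrix.
    """
    core_pairs = {ordered_pair(a, b) for a, b in core.edges}
    core_vals: list[float] = []
    pan_vals: list[float] = []
    for sid, matrix in sorted(filtered_matrices.items()):
        idx = {g: i for i, g in enumerate(matrix.index)}
        x = matrix.to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.sqrt((xc ** 2).sum(axis=1))
        norms[norms == 0] = np.nan
        z = xc / norms[:, None]
        ai, bi, is_core = [], [], []
        for pair, rec in pan.edges.items():
            if sid in rec.series_ids:
                continue
            ia, ib = idx.get(pair[0]), idx.get(pair[1])
            if ia is None or ib is None:
                continue
            ai.append(ia)
            bi.append(ib)
            is_core.append(pair in core_pairs)
        if not ai:
            continue
        r = np.einsum("ij,ij->i", z[np.array(ai)], z[np.array(bi)])
        mask = np.array(is_core, dtype=bool)
        ok = ~np.isnan(r)
        r, mask = r[ok], mask[ok]
        pan_vals.extend(r.tolist())
        core_vals.extend(r[mask].tolist())
    if not core_vals or not pan_vals:
        warnings.warn("subthreshold test: empty sample; result undefined")
        return SubthresholdResult(float("nan"), float("nan"), float("nan"),
                                  float("nan"), len(core_vals), len(pan_vals))
    t, p = stats.ttest_ind(core_vals, pan_vals, equal_var=False,
                           alternative="greater")
    return SubthresholdResult(
        mean_core=float(np.mean(core_vals)), mean_pan=float(np.mean(pan_vals)),
        t=float(t), p=float(p), n_core=len(core_vals), n_pan=len(pan_vals))


def reference_overlap_test(graph: nx.Graph,
                           reference_edges: set[Pair],
                           n_perm: int = 1000, seed: int = 0
                           ) -> tuple[int, float]:
    """Overlap of the graph's edges with a reference edge set, with an
    empirical p-value from a degree-preserving rewiring null.

    p = (1 + #{null >= observed}) / (n_perm + 1).  An empty reference gives
    overlap 0 and p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ref = {ordered_pair(a, b) for a, b in reference_edges}
    observed = sum(1 for a, b in graph.edges if ordered_pair(a, b) in ref)
    if not ref:
        return 0, 1.0
    e = graph.number_of_edges()
    if e < 2 or graph.number_of_nodes() < 4:
        warnings.warn("graph too small for degree-preserving rewiring; p = 1")
        return observed, 1.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        g = graph.copy()
        try:
            nx.double_edge_swap(g, nswap=e, max_tries=100 * e,
                                seed=int(rng.integers(2**31 - 1)))
        except nx.NetworkXError as err:  # saturated graphs cannot rewire
            warnings.warn(f"rewiring incomplete: {err}")
        null = sum(1 for a, b in g.edges if ordered_pair(a, b) in ref)
        if null >= observed:
            exceed += 1
    return observed, (1 + exceed) / (n_perm + 1)
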