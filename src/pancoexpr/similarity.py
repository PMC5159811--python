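"""Network-to-network similarity and the "network of networks".

Two similarity measures between series networks are provided: the Jaccard
index on edge sets, and a module-preservation Z-summary.  The Z-summary of
a module (detected in a reference network) evaluated in a test series is
the mean of two permutation Z-scores: one for module *density* (mean
pairwise PCC of the module genes in the test series) and one for
*connectivity* (correlation between the genes' intramodular connectivity in
the reference vs the test series), each standardized against random gene
sets of equal size drawn from the genes shared by both series.

The raw pairwise Z-summary matrix feeds the network-of-networks graph
(cutoff S > 10, at most 10 strongest neighbors shown per node); a min-max
normalized copy is used only for visualization-style outputs such as
hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch

from .exceptions import ConfigurationError
from .pancore import detect_communities
from .types import CoexpressionNetwork, NetworkSimilarity


def _labels_frame(networks: list[CoexpressionNetwork]) -> pd.DataFrame:
    return pd.DataFrame(
        {"tissue": [n.tissue for n in networks],
         "condition": [n.condition for n in networks]},
        index=[n.series_id for n in networks])


def jaccard_matrix(networks: list[CoexpressionNetwork]) -> NetworkSimilarity:
    """Pairwise edge-set Jaccard index J = |Ei ∩ Ej| / |Ei ∪ Ej|.

    J(i, i) = 1; a pair of empty edge sets gets J = 0 with a warning.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    ids = [n.series_id for n in networks]
    sets = [n.edge_set for n in networks]
    m = np.eye(len(ids))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            union = len(sets[i] | sets[j])
            if union == 0:
                warnings.warn(
                    f"both {ids[i]!r} and {ids[j]!r} are empty; J set to 0")
                jac = 0.0
            else:
                jac = len(sets[i] & sets[j]) / union
            m[i, j] = m[j, i] = jac
    return NetworkSimilarity(
        matrix=pd.DataFrame(m, index=ids, columns=ids),
        kind="jaccard", labels=_labels_frame(networks))


# ---------------------------------------------------------------------------
# module preservation
# ---------------------------------------------------------------------------

def _corr(matrix: pd.DataFrame) -> tuple[dict[str, int], np.ndarray]:
    """Full gene x gene correlation of a series matrix (rows = genes)."""
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc ** 2).sum(axis=1))
    norms[norms == 0] = np.nan
    z = xc / norms[:, None]
    c = z @ z.T
    np.clip(c, -1.0, 1.0, out=c)
    return {g: i for i, g in enumerate(matrix.index)}, c


def _density(corr: np.ndarray, idx: np.ndarray) -> float:
    sub = corr[np.ix_(idx, idx)]
    s = len(idx)
    return float((sub.sum() - np.trace(sub)) / (s * (s - 1)))


def _connectivity(ref_corr: np.ndarray, ref_idx: np.ndarray,
                  test_corr: np.ndarray, test_idx: np.ndarray) -> float:
    """Correlation of intramodular connectivity (within-module PCC row sums)
    between reference and test series."""
    kref = ref_corr[np.ix_(ref_idx, ref_idx)].sum(axis=1) - 1.0
    ktest = test_corr[np.ix_(test_idx, test_idx)].sum(axis=1) - 1.0
    if np.std(kref) == 0 or np.std(ktest) == 0:
        return float("nan")
    return float(np.corrcoef(kref, ktest)[0, 1])


def _zscore(obs: float, null: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.nanmean(null))
    sd = float(np.nanstd(null, ddof=1))
    if not np.isfinite(sd) or sd == 0:
        return mean, sd, float("nan")
    return mean, sd, (obs - mean) / sd


def _preservation_rows(modules, ref_map: dict[str, int], ref_c: np.ndarray,
                       test_map: dict[str, int], test_c: np.ndarray,
                       n_perm: int, seed: int, min_genes: int) -> pd.DataFrame:
    shared = sorted(set(ref_map) & set(test_map))
    if len(shared) < min_genes:
        raise ValueError("fewer shared genes than min_genes")
    shared_pos = {g: i for i, g in enumerate(shared)}
    ref_shared = np.array([ref_map[g] for g in shared])
    test_shared = np.array([test_map[g] for g in shared])
    rng = np.random.default_rng(seed)
    rows = []
    for mi, module in enumerate(modules):
        genes = sorted(set(module) & set(shared_pos))
        if len(genes) < min_genes:
            rows.append({"module": mi, "n_genes": len(genes), "skipped": True,
                         "obs_density": np.nan, "obs_connectivity": np.nan,
                         "null_density_mean": np.nan, "null_density_sd": np.nan,
                         "null_connectivity_mean": np.nan,
                         "null_connectivity_sd": np.nan,
                         "z_density": np.nan, "z_connectivity": np.nan,
                         "z_summary": np.nan})
            continue
        pos = np.array([shared_pos[g] for g in genes])
        obs_d = _density(test_c, test_shared[pos])
        obs_k = _connectivity(ref_c, ref_shared[pos], test_c, test_shared[pos])
        null_d = np.empty(n_perm)
        null_k = np.empty(n_perm)
        for p in range(n_perm):
            draw = rng.choice(len(shared), size=len(genes), replace=False)
            null_d[p] = _density(test_c, test_shared[draw])
            null_k[p] = _connectivity(ref_c, ref_shared[draw],
                                      test_c, test_shared[draw])
        dm, ds, zd = _zscore(obs_d, null_d)
        km, ks, zk = _zscore(obs_k, null_k)
        zs = np.nanmean([zd, zk]) if not (np.isnan(zd) and np.isnan(zk)) \
            else float("nan")
        rows.append({"module": mi, "n_genes": len(genes), "skipped": False,
                     "obs_density": obs_d, "obs_connectivity": obs_k,
                     "null_density_mean": dm, "null_density_sd": ds,
                     "null_connectivity_mean": km, "null_connectivity_sd": ks,
                     "z_density": zd, "z_connectivity": zk,
                     "z_summary": float(zs)})
    return pd.DataFrame(rows).set_index("module")


def module_preservation(modules: list[set[str]] | list[frozenset[str]],
                        ref_matrix: pd.DataFrame, test_matrix: pd.DataFrame,
                        n_perm: int = 200, seed: int = 0,
                        min_genes: int = 5) -> pd.DataFrame:
    """Permutation Z-summary of each reference module in a test series.

    Module genes absent from either series are dropped; a module is
    evaluated only if >= ``min_genes`` survive (otherwise it is recorded as
    skipped).  The null draws ``n_perm`` random gene sets of equal size
    from the genes shared by both series.  Zero null-sd leaves the Z
    undefined (NaN).
    """
    ref_map, ref_c = _corr(ref_matrix)
    test_map, test_c = _corr(test_matrix)
    return _preservation_rows(modules, ref_map, ref_c, test_map, test_c,
                              n_perm=n_perm, seed=seed, min_genes=min_genes)


def zsummary_matrix(networks: list[CoexpressionNetwork],
                    matrices: dict[str, pd.DataFrame],
                    n_perm: int = 100, seed: int = 0,
                    min_genes: int = 5,
                    max_genes: int | None = None,
                    symmetrize: bool = True) -> NetworkSimilarity:
    """Raw series x series Z-summary similarity.

    Modules are detected per network (Louvain); S(i, j) is the mean
    Z-summary of network i's modules evaluated in series j, symmetrized as
    (S(i, j) + S(j, i)) / 2.  Entries with no evaluable module are NaN.
    ``max_genes`` optionally skips very large (noise-agglomerate) modules
    to bound the permutation cost.  ``symmetrize=False`` returns the
    directed matrix (modules of the row network evaluated in the column
    series); its diagonal is the self-preservation of each network's own
    modules.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    ids = [n.series_id for n in networks]
    missing = [i for i in ids if i not in matrices]
    if missing:
        raise ValueError(f"no expression matrix for series {missing[0]!r}")
    module_sets: list[list[frozenset[str]]] = []
    for k, net in enumerate(networks):
        if net.n_edges == 0:
            module_sets.append([])
            continue
        part = detect_communities(net.to_graph(), seed=seed + k)
        module_sets.append([
            c for c in part.communities
            if len(c) >= min_genes and (max_genes is None or len(c) <= max_genes)
        ])

    corr_cache = {sid: _corr(matrices[sid]) for sid in ids}
    s = np.full((len(ids), len(ids)), np.nan)
    for i, net in enumerate(networks):
        if not module_sets[i]:
            continue
        ref_map, ref_c = corr_cache[ids[i]]
        for j in range(len(ids)):
            test_map, test_c = corr_cache[ids[j]]
            res = _preservation_rows(
                module_sets[i], ref_map, ref_c, test_map, test_c,
                n_perm=n_perm, seed=seed + 1000 * i + j, min_genes=min_genes)
            vals = res.loc[~res["skipped"], "z_summary"].to_numpy()
            vals = vals[np.isfinite(vals)]
            if vals.size:
                s[i, j] = float(vals.mean())
    if symmetrize:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            s = np.nanmean(np.stack([s, s.T]), axis=0)
    return NetworkSimilarity(
        matrix=pd.DataFrame(s, index=ids, columns=ids),
        kind="zsummary" if symmetrize else "zsummary_directed",
        labels=_labels_frame(networks))


# ---------------------------------------------------------------------------
# normalization, network of networks, clustering, label test
# ---------------------------------------------------------------------------

def normalize_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale to [0, 1] using the off-diagonal range, for
    visualization-style outputs; raw scores are kept alongside, never
    replaced."""
    m = matrix.to_numpy(dtype=float)
    off = m[~np.eye(len(m), dtype=bool)]
    off = off[np.isfinite(off)]
    if off.size == 0 or off.max() == off.min():
        raise ConfigurationError(
            "normalize_similarity: constant (or empty) off-diagonal entries")
    out = (m - off.min()) / (off.max() - off.min())
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def network_of_networks(raw: pd.DataFrame,
                        labels: pd.DataFrame | None = None,
                        threshold: float = 10.0,
                        max_neighbors: int = 10) -> nx.Graph:
    """Graph over series: edge (i, j) iff raw similarity S(i, j) > threshold.

    Per node only the ``max_neighbors`` highest-similarity neighbors are
    kept (an edge survives if either endpoint keeps it; ties broken by
    series id); isolated nodes are dropped.  Applies to RAW scores.
    """
    ids = list(raw.index)
    kept: set[tuple[str, str]] = set()
    for i in ids:
        nbrs = [(j, raw.loc[i, j]) for j in ids
                if j != i and np.isfinite(raw.loc[i, j])
                and raw.loc[i, j] > threshold]
        nbrs.sort(key=lambda t: (-t[1], t[0]))
        for j, _ in nbrs[:max_neighbors]:
            kept.add((i, j) if i < j else (j, i))
    g = nx.Graph()
    for a, b in sorted(kept):
        g.add_edge(a, b, similarity=float(raw.loc[a, b]))
    if labels is not None:
        for n in g.nodes:
            if n in labels.index:
                g.nodes[n]["tissue"] = str(labels.loc[n, "tissue"])
                g.nodes[n]["condition"] = str(labels.loc[n, "condition"])
    return g


@dataclass
class ClusteringResult:
    leaf_order: list[str]
    linkage: np.ndarray
    newick: str


def _to_newick(node: sch.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    parts = []
    for child in (node.get_left(), node.get_right()):
        length = max(node.dist - child.dist, 0.0)
        parts.append(f"{_to_newick(child, labels)}:{length:.6g}")
    return "(" + ",".join(parts) + ")"


def cluster_networks(similarity: pd.DataFrame,
                     normalize: bool = True) -> ClusteringResult:
    """Average-linkage hierarchical clustering of series networks.

    Distance = 1 - (min-max normalized) similarity.  Undefined entries are
    imputed as the minimum observed similarity (with a warning).  The leaf
    order is deterministic.
    """
    sim = similarity.copy()
    vals = sim.to_numpy(dtype=float)
    if np.isnan(vals).any():
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise ConfigurationError("similarity matrix is entirely undefined")
        warnings.warn("undefined similarity entries imputed as the minimum")
        vals = np.where(np.isnan(vals), finite.min(), vals)
        sim = pd.DataFrame(vals, index=sim.index, columns=sim.columns)
    norm = normalize_similarity(sim) if normalize else sim
    d = 1.0 - norm.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    condensed = d[np.triu_indices(len(d), k=1)]
    z = sch.linkage(condensed, method="average")
    order = sch.leaves_list(z)
    labels = list(sim.index)
    tree = sch.to_tree(z)
    newick = _to_newick(tree, labels) + ";"
    return ClusteringResult(leaf_order=[labels[i] for i in order],
                            linkage=z, newick=newick)


def label_association_test(similarity: pd.DataFrame,
                           labels: pd.Series | dict[str, str],
                           n_perm: int = 999, seed: int = 0
                           ) -> tuple[float, float]:
    """Permutation test for label (e.g. tissue) structure in a similarity
    matrix.

    Statistic: mean within-label similarity minus mean between-label
    similarity over off-diagonal entries.  Null: label permutations.
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    lab = labels.loc[similarity.index].to_numpy()
    if len(set(lab)) < 2:
        raise ValueError("label association test needs >= 2 label classes")
    m = similarity.to_numpy(dtype=float)
    off = ~np.eye(len(m), dtype=bool)

    def stat(lv: np.ndarray) -> float:
        same = (lv[:, None] == lv[None, :]) & off
        diff = (~(lv[:, None] == lv[None, :])) & off
        return float(np.nanmean(m[same]) - np.nanmean(m[diff]))

    observed = stat(lab)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if stat(rng.permutation(lab)) >= observed:
            exceed += 1
    return observed, (1 + exceed) / (n_perm + 1)
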