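"""Core domain containers.

The unit of analysis is one expression *series* (one published experiment,
a genes x samples abundance matrix with replicate-group structure).  Each
series yields one :class:`CoexpressionNetwork`; a collection of networks is
merged into a :class:`PanNetwork` whose edges carry a universality count U
(the number of series networks an edge was observed in).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

Pair = tuple[str, str]


def ordered_pair(a: str, b: str) -> Pair:
    """Canonical (lexicographically sorted) unordered gene pair."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionSeries:
    """One experiment: abundance matrix, detection flags and sample metadata.

    Parameters
    ----------
    matrix
        Non-negative abundances, rows indexed by gene/TE identifiers,
        columns by sample identifiers.
    present
        Boolean detection ("present") calls, same shape as ``matrix``.
    replicate_group
        Series mapping each sample identifier to its replicate-group label.
    te_rows
        Row identifiers that are transposable-element measurements; these
        never enter network construction but set the abundance floor.
    """

    series_id: str
    matrix: pd.DataFrame
    present: pd.DataFrame
    replicate_group: pd.Series
    tissue: str = ""
    condition: str = ""
    te_rows: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.te_rows = frozenset(self.te_rows)
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ConfigurationError(
                f"series {self.series_id!r}: duplicate row identifier {dup!r}"
            )
        if self.present.shape != self.matrix.shape:
            raise ConfigurationError(
                f"series {self.series_id!r}: present flags shape "
                f"{self.present.shape} != matrix shape {self.matrix.shape}"
            )
        if not self.present.index.equals(self.matrix.index) or not (
            self.present.columns.equals(self.matrix.columns)
        ):
            raise ConfigurationError(
                f"series {self.series_id!r}: present flags not aligned with matrix"
            )
        missing = [s for s in self.matrix.columns if s not in self.replicate_group.index]
        if missing:
            raise ConfigurationError(
                f"series {self.series_id!r}: sample {missing[0]!r} has no replicate group"
            )
        if (self.matrix.to_numpy() < 0).any():
            raise ConfigurationError(
                f"series {self.series_id!r}: negative abundance value"
            )
        unknown = self.te_rows - set(self.matrix.index)
        if unknown:
            raise ConfigurationError(
                f"series {self.series_id!r}: te_rows not in matrix: {sorted(unknown)[:3]}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def gene_ids(self) -> list[str]:
        """Row identifiers eligible for network construction (TE rows excluded)."""
        return [g for g in self.matrix.index if g not in self.te_rows]

    def gene_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[self.gene_ids]


@dataclass
class FilterReport:
    """Outcome of the biologically-relevant-gene filter for one series."""

    series_id: str
    anova_p: pd.Series
    selected_by_anova: frozenset[str]
    passed_abundance: frozenset[str]
    final_genes: list[str]
    fallback_used: bool
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "series_id": self.series_id,
            "n_selected_by_anova": len(self.selected_by_anova),
            "n_passed_abundance": len(self.passed_abundance),
            "final_genes": list(self.final_genes),
            "fallback_used": self.fallback_used,
            "warnings": list(self.warnings),
        }


@dataclass
class CoexpressionNetwork:
    """Thresholded coexpression network for one series.

    ``edges`` maps canonical gene pairs to their Pearson correlation;
    ``pcc_cutoff`` is the smallest retained correlation (None if empty).
    """

    series_id: str
    edges: dict[Pair, float]
    pcc_cutoff: float | None = None
    tissue: str = ""
    condition: str = ""

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def edge_set(self) -> frozenset[Pair]:
        return frozenset(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(series_id=self.series_id, tissue=self.tissue,
                     condition=self.condition)
        for (a, b) in sorted(self.edges):
            g.add_edge(a, b, weight=float(self.edges[(a, b)]))
        return g


@dataclass
class PanEdge:
    """Support record for one pan-network edge across series."""

    series_ids: list[str]
    pccs: list[float]

    @property
    def universality(self) -> int:
        return len(self.series_ids)

    @property
    def mean_pcc(self) -> float:
        return float(np.mean(self.pccs))


@dataclass
class PanNetwork:
    """Union of series networks; each edge carries its universality support."""

    edges: dict[Pair, PanEdge]
    n_networks: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def universality(self, pair: Pair) -> int:
        return self.edges[pair].universality


@dataclass
class ModulePartition:
    """Node communities of one network plus the modularity of the partition."""

    communities: list[frozenset[str]]
    modularity: float

    def __post_init__(self) -> None:
        # canonical ordering for reproducible downstream iteration
        self.communities = sorted(
            (frozenset(c) for c in self.communities), key=lambda c: min(c)
        )

    @property
    def membership(self) -> dict[str, int]:
        return {n: i for i, c in enumerate(self.communities) for n in c}

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities]


@dataclass
class NetworkSimilarity:
    """Symmetric series x series similarity with per-series labels."""

    matrix: pd.DataFrame
    kind: str  # "jaccard" | "zsummary" | "zsummary_directed"
    labels: pd.DataFrame  # index: series ids; columns: tissue, condition

    def __post_init__(self) -> None:
        m = self.matrix
        if not m.index.equals(m.columns):
            raise ConfigurationError("similarity matrix index/columns mismatch")
        if not self.kind.endswith("_directed") and not np.allclose(
                m.to_numpy(), m.to_numpy().T, equal_nan=True):
            raise ConfigurationError("similarity matrix is not symmetric")


@dataclass
class GroundTruth:
    """Planted-module truth for a synthetic collection.

    ``modules`` maps module id to its gene set, ``active_series`` to the set
    of series the module's latent factor is switched on in.  The expected
    universality of a within-module edge equals the active-series count.
    """

    modules: dict[str, frozenset[str]]
    active_series: dict[str, frozenset[str]]
    module_kind: dict[str, str]  # "core" | "specific"

    def __post_init__(self) -> None:
        self.modules = {k: frozenset(v) for k, v in self.modules.items()}
        self.active_series = {k: frozenset(v) for k, v in self.active_series.items()}
        if set(self.modules) != set(self.active_series):
            raise ConfigurationError("modules/active_series key mismatch")

    @property
    def expected_universality(self) -> dict[str, int]:
        return {m: len(s) for m, s in self.active_series.items()}

    def module_pairs(self, kind: str | None = None) -> set[Pair]:
        """All within-module gene pairs, optionally restricted to one kind."""
        out: set[Pair] = set()
        for mid, genes in self.modules.items():
            if kind is not None and self.module_kind[mid] != kind:
                continue
            gs = sorted(genes)
            for i, a in enumerate(gs):
                for b in gs[i + 1:]:
                    out.add((a, b))
        return out

    def to_dict(self) -> dict:
        return {
            "modules": [
                {
                    "module_id": m,
                    "kind": self.module_kind[m],
                    "genes": sorted(self.modules[m]),
                    "active_series": sorted(self.active_series[m]),
                    "expected_universality": len(self.active_series[m]),
                }
                for m in sorted(self.modules)
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        modules = {r["module_id"]: frozenset(r["genes"]) for r in d["modules"]}
        active = {r["module_id"]: frozenset(r["active_series"]) for r in d["modules"]}
        kind = {r["module_id"]: r["kind"] for r in d["modules"]}
        return cls(modules=modules, active_series=active, module_kind=kind)
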