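"""Term-enrichment testing for network modules.

Annotations are gene -> term records with evidence codes plus an is_a term
hierarchy.  IEP-coded records (inferred from expression pattern) are removed
to avoid circularity, annotations are propagated to all ancestors, overly
broad terms are screened out, and each (module, term) pair is tested with a
one-sided Fisher exact test followed by Benjamini-Hochberg correction.

The broad-term screen retains a term only if its minimum achievable Fisher
p-value (a module of the largest tested size lying entirely inside the
term) could still pass a Bonferroni-corrected alpha; a simpler
maximum-fraction-of-background rule is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .types import ModulePartition

Record = tuple[str, str, str]  # (gene, term, evidence code)


def strip_iep(records: Iterable[Record],
              codes: tuple[str, ...] = ("IEP",)) -> list[Record]:
    """Drop annotation records whose evidence code is IEP (or any listed
    code); all other records pass unchanged."""
    return [r for r in records if r[2] not in codes]


def _ancestors(term: str, hierarchy: Mapping[str, set[str]],
               cache: dict[str, frozenset[str]],
               stack: tuple[str, ...] = ()) -> frozenset[str]:
    if term in cache:
        return cache[term]
    if term in stack:
        raise ConfigurationError(
            f"is_a hierarchy contains a cycle through term {term!r}")
    out: set[str] = set()
    for parent in hierarchy.get(term, ()):
        out.add(parent)
        out |= _ancestors(parent, hierarchy, cache, stack + (term,))
    result = frozenset(out)
    cache[term] = result
    return result


def propagate_annotations(direct: Mapping[str, set[str]],
                          hierarchy: Mapping[str, set[str]]
                          ) -> dict[str, frozenset[str]]:
    """Close each gene's term set under is_a ancestors.

    ``hierarchy`` maps a term to its parent terms and must be acyclic.
    The operation is idempotent: propagating an already-closed annotation
    returns it unchanged.
    """
    cache: dict[str, frozenset[str]] = {}
    out: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set(terms)
        for t in terms:
            closed |= _ancestors(t, hierarchy, cache)
        out[gene] = frozenset(closed)
    return out


@dataclass
class AnnotationSet:
    """Propagated gene annotations over a background gene universe."""

    direct: dict[str, frozenset[str]]
    hierarchy: dict[str, frozenset[str]]
    background: frozenset[str]
    propagated: dict[str, frozenset[str]] = field(init=False)
    term_size: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.propagated = propagate_annotations(
            {g: set(t) for g, t in self.direct.items()},
            {t: set(p) for t, p in self.hierarchy.items()})
        sizes: dict[str, int] = {}
        for gene in self.background:
            for t in self.propagated.get(gene, ()):
                sizes[t] = sizes.get(t, 0) + 1
        self.term_size = sizes

    @classmethod
    def from_records(cls, records: Iterable[Record],
                     hierarchy: Mapping[str, set[str]],
                     background: Iterable[str],
                     strip_evidence: tuple[str, ...] = ("IEP",)
                     ) -> "AnnotationSet":
        direct: dict[str, set[str]] = {}
        for gene, term, _ in strip_iep(records, strip_evidence):
            direct.setdefault(gene, set()).add(term)
        return cls(direct={g: frozenset(t) for g, t in direct.items()},
                   hierarchy={t: frozenset(p) for t, p in hierarchy.items()},
                   background=frozenset(background))

    def genes_of(self, term: str) -> frozenset[str]:
        return frozenset(g for g in self.background
                         if term in self.propagated.get(g, ()))


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact p for the 2x2 table
    (a, b; c, d): the hypergeometric upper tail P(X >= a) with population
    a+b+c+d, successes a+c and draws a+b."""
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    return float(min(stats.hypergeom.sf(a - 1, n, a + c, a + b), 1.0))


def min_achievable_p(term_size: int, background_size: int,
                     module_size: int) -> float:
    """Smallest Fisher p a term could reach: the module lies entirely
    inside the term (a = min(module_size, term_size))."""
    a = min(module_size, term_size)
    if a == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, background_size, term_size,
                                    module_size))


def filter_broad_terms(annotations: AnnotationSet, alpha: float = 0.05,
                       max_module_size: int | None = None,
                       method: str = "min_p",
                       max_fraction: float = 0.2) -> frozenset[str]:
    """Terms retained for testing, broad terms excluded.

    ``min_p`` keeps term t iff its minimum achievable Fisher p-value at
    module size ``max_module_size`` passes alpha / (number of candidate
    terms) — terms too broadly annotated can never reach it.  The
    ``max_fraction`` fallback simply excludes terms annotated to more than
    that fraction of the background.  Retention is monotone in alpha.
    """
    candidates = sorted(t for t, s in annotations.term_size.items() if s > 0)
    n_bg = len(annotations.background)
    if not candidates or n_bg == 0:
        return frozenset()
    if method == "max_fraction":
        return frozenset(t for t in candidates
                         if annotations.term_size[t] <= max_fraction * n_bg)
    if method != "min_p":
        raise ConfigurationError(f"broad_term_method: unknown method {method!r}")
    m = max_module_size if max_module_size is not None else n_bg // 2
    m = max(1, min(m, n_bg))
    bound = alpha / len(candidates)
    return frozenset(
        t for t in candidates
        if min_achievable_p(annotations.term_size[t], n_bg, m) <= bound)


def fisher_enrichment(module_genes: Iterable[str],
                      annotations: AnnotationSet,
                      terms: Iterable[str] | None = None) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact test per term.

    The 2x2 table for term t is (a, b; c, d) = (in-module & in-term,
    in-module & not-in-term; out-module & in-term, out-module &
    not-in-term) over the background universe; p is the hypergeometric
    upper tail P(X >= a).
    """
    module = frozenset(module_genes)
    if not module:
        raise ValueError("module is empty")
    extra = module - annotations.background
    if extra:
        raise ValueError(
            f"module gene {sorted(extra)[0]!r} not in the background universe")
    if terms is None:
        terms = sorted(t for t, s in annotations.term_size.items() if s > 0)
    else:
        terms = sorted(terms)
    n_bg = len(annotations.background)
    n_mod = len(module)
    rows = []
    for t in terms:
        in_term = annotations.genes_of(t)
        a = len(module & in_term)
        b = n_mod - a
        c = len(in_term) - a
        d = n_bg - a - b - c
        rows.append({"term": t, "a": a, "b": b, "c": c, "d": d,
                     "odds_direction": "over" if a * d > b * c else "under_or_none",
                     "p": fisher_pvalue(a, b, c, d)})
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, in [0, 1])."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(partition: ModulePartition | list[set[str]],
                   annotations: AnnotationSet, alpha: float = 0.05,
                   broad_method: str = "min_p", max_fraction: float = 0.2,
                   min_module_genes: int = 1) -> pd.DataFrame:
    """Per-(module, term) enrichment over broad-screened terms.

    Returns a table with contingency counts, p and pooled-BH q per row plus
    a ``top`` flag marking each module's best term.  Modules with no
    annotated genes are recorded with ``unannotated=True`` and no tests.
    """
    comms = (partition.communities if isinstance(partition, ModulePartition)
             else [frozenset(c) for c in partition])
    if not comms:
        raise ValueError("partition is empty")
    comms = [c for c in comms if len(c) >= min_module_genes]
    columns = ["module", "term", "a", "b", "c", "d", "odds_direction", "p",
               "unannotated", "q", "top"]
    if not comms:
        return pd.DataFrame(columns=columns)
    largest = max((len(c & annotations.background) for c in comms), default=0)
    retained = filter_broad_terms(annotations, alpha=alpha,
                                  max_module_size=max(1, largest),
                                  method=broad_method,
                                  max_fraction=max_fraction)
    frames = []
    for i, comm in enumerate(comms):
        genes = comm & annotations.background
        annotated = {g for g in genes if annotations.propagated.get(g)}
        if not genes or not annotated or not retained:
            frames.append(pd.DataFrame([{
                "module": i, "term": None, "a": 0, "b": 0, "c": 0, "d": 0,
                "odds_direction": None, "p": np.nan, "unannotated": True}]))
            continue
        tab = fisher_enrichment(genes, annotations, terms=retained)
        tab.insert(0, "module", i)
        tab["unannotated"] = False
        frames.append(tab)
    table = pd.concat(frames, ignore_index=True)
    tested = table["p"].notna()
    table["q"] = np.nan
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["top"] = False
    for i in table.loc[tested, "module"].unique():
        sub = table[(table["module"] == i) & tested]
        best = sub.sort_values(["q", "p", "term"]).index[0]
        table.loc[best, "top"] = True
    return table
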