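"""Synthetic expression-series collections with planted coexpression structure.

The generator emulates the statistical shape of a compendium of public
expression experiments: each series is a genes x samples abundance matrix
with replicate groups, present/absent detection flags and a block of
transposable-element (TE) rows.  Coexpressed modules are planted with a
latent-factor model,

    value(g, s) = baseline(g) + amp * (signal * f(s) + noise_sd * eps(g, s)),

where all genes of a module share the factor ``f`` within a series in which
the module is active.  Because the Pearson correlation is invariant under
per-gene affine maps, the expected within-module correlation is the
factor-model value signal^2 / (signal^2 + noise_sd^2) regardless of
baseline and amplitude.  The factor itself carries a between-replicate-group
variance component so that the ANOVA filter retains module genes; noise
genes are i.i.d. and carry no group effect.

Core modules are active in most series (large expected edge universality);
specific modules are active in only a few series of one tissue, giving the
similarity stage tissue structure to find.  Core modules additionally keep a
weak residual loading (``core_background_signal``) in series where they are
not active, emulating housekeeping machinery that remains mildly
co-regulated everywhere: its pairs stay well below the edge cutoff but
their correlations are clearly positive, which is the signal probed by the
sub-threshold PCC test.  Low-abundance genes sit strictly below the TE
rows' abundance range and are flagged absent everywhere, so the abundance
filter's ground truth is unambiguous.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import SyntheticConfig
from .types import ExpressionSeries, GroundTruth, ordered_pair

# abundance scale constants (linear, MAS5-like): regular genes sit well above
# the TE range; low-abundance genes strictly below it
_BASELINE_RANGE = (300.0, 1000.0)
_AMPLITUDE = 25.0
_TE_RANGE = (20.0, 80.0)
_LOW_RANGE = (1.0, 10.0)

_CONDITIONS = ("abiotic-stress", "development", "mutant", "hormone")


def _gene_ids(config: SyntheticConfig) -> dict[str, list[str]]:
    ids = {
        "core": [f"CORE{m:02d}_{i:03d}"
                 for m in range(config.n_core_modules)
                 for i in range(config.core_module_size)],
        "specific": [f"SPEC{m:02d}_{i:03d}"
                     for m in range(config.n_specific_modules)
                     for i in range(config.specific_module_size)],
        "noise": [f"NOISE{i:05d}" for i in range(config.n_noise_genes)],
        "low": [f"LOWAB{i:04d}" for i in range(config.n_low_abundance_genes)],
        "te": [f"TE{i:04d}" for i in range(config.n_te_rows)],
    }
    return ids


def _tissue_of(series_index: int, config: SyntheticConfig) -> str:
    t = series_index * config.n_tissues // config.n_series
    return f"tissue_{t}"


def _plan_modules(config: SyntheticConfig) -> GroundTruth:
    """Deterministic module -> genes and module -> active-series assignment."""
    ids = _gene_ids(config)
    series_ids = [f"SYN{k:03d}" for k in range(config.n_series)]
    modules: dict[str, frozenset[str]] = {}
    active: dict[str, frozenset[str]] = {}
    kind: dict[str, str] = {}

    for m in range(config.n_core_modules):
        mid = f"core_{m:02d}"
        genes = ids["core"][m * config.core_module_size:(m + 1) * config.core_module_size]
        modules[mid] = frozenset(genes)
        active[mid] = frozenset(series_ids[: config.core_presence])
        kind[mid] = "core"

    # specific modules are tissue-aligned: module k lives in tissue k % n_tissues
    # and is active in `presence` consecutive series of that tissue block,
    # with presence cycling over the configured (lo, hi) range
    blocks: dict[str, list[str]] = {}
    for s, sid in enumerate(series_ids):
        blocks.setdefault(_tissue_of(s, config), []).append(sid)
    tissues = sorted(blocks)
    lo, hi = config.specific_presence
    for k in range(config.n_specific_modules):
        mid = f"specific_{k:02d}"
        genes = ids["specific"][k * config.specific_module_size:(k + 1) * config.specific_module_size]
        modules[mid] = frozenset(genes)
        block = blocks[tissues[k % len(tissues)]]
        presence = min(lo + k % (hi - lo + 1), len(block))
        start = (k // len(tissues)) % len(block)
        chosen = [block[(start + i) % len(block)] for i in range(presence)]
        active[mid] = frozenset(chosen)
        kind[mid] = "specific"

    return GroundTruth(modules=modules, active_series=active, module_kind=kind)


def _generate_series(series_id: str, tissue: str, condition: str,
                     n_samples: int, n_groups: int,
                     active_modules: list[frozenset[str]],
                     background_modules: list[frozenset[str]],
                     config: SyntheticConfig,
                     rng: np.random.Generator) -> ExpressionSeries:
    ids = _gene_ids(config)
    regular = ids["core"] + ids["specific"] + ids["noise"]
    all_rows = regular + ids["low"] + ids["te"]
    samples = [f"{series_id}_s{j:02d}" for j in range(n_samples)]
    # contiguous replicate groups, each of (near-)equal size >= 2
    group_of = np.array([min(j * n_groups // n_samples, n_groups - 1)
                         for j in range(n_samples)])

    n_reg = len(regular)
    baseline = rng.uniform(*_BASELINE_RANGE, size=n_reg)
    # every regular gene starts as i.i.d. unit noise around its baseline
    signal_part = rng.standard_normal((n_reg, n_samples))
    row_of = {g: i for i, g in enumerate(regular)}

    a = np.sqrt(config.group_effect)
    b = np.sqrt(1.0 - config.group_effect)
    # strongly active modules get the full loading plus a between-group
    # factor component (so ANOVA retains them); background modules (core
    # machinery in series where it is not the focus) share a weak factor
    # with no group structure, keeping their pairs sub-threshold
    for genes, loading, grouped in (
            [(g, config.module_signal, True) for g in active_modules]
            + [(g, config.core_background_signal, False)
               for g in background_modules]):
        if loading == 0.0:
            continue
        if grouped:
            z = rng.standard_normal(n_groups)       # between-group component
            w = rng.standard_normal(n_samples)      # within-group component
            f = a * z[group_of] + b * w             # latent factor, unit variance
        else:
            f = rng.standard_normal(n_samples)
        idx = np.array(sorted(row_of[g] for g in genes))
        eps = rng.standard_normal((len(idx), n_samples))
        signal_part[idx] = loading * f + config.noise_sd * eps

    reg_values = baseline[:, None] + _AMPLITUDE * signal_part
    low_values = rng.uniform(*_LOW_RANGE,
                             size=(config.n_low_abundance_genes, n_samples))
    te_values = rng.uniform(*_TE_RANGE, size=(config.n_te_rows, n_samples))

    matrix = pd.DataFrame(
        np.vstack([reg_values, low_values, te_values]),
        index=all_rows, columns=samples,
    )
    present = pd.DataFrame(True, index=all_rows, columns=samples)
    present.loc[ids["low"], :] = False

    return ExpressionSeries(
        series_id=series_id,
        matrix=matrix,
        present=present,
        replicate_group=pd.Series([f"group_{g}" for g in group_of], index=samples),
        tissue=tissue,
        condition=condition,
        te_rows=frozenset(ids["te"]),
    )


def generate_collection(config: SyntheticConfig
                        ) -> tuple[list[ExpressionSeries], GroundTruth]:
    """Generate a collection of series plus its planted-module ground truth.

    Deterministic for a given config (including its seed).  If
    ``n_undersized_series > 0``, extra series with fewer samples than the
    minimum-sample filter allows are appended; no module is active in them
    and they do not appear in any ground-truth active-series set.
    """
    truth = _plan_modules(config)
    streams = np.random.SeedSequence(config.seed).spawn(
        config.n_series + config.n_undersized_series)

    series_list: list[ExpressionSeries] = []
    def _background(sid: str) -> list[frozenset[str]]:
        return [truth.modules[m] for m in sorted(truth.modules)
                if truth.module_kind[m] == "core"
                and sid not in truth.active_series[m]]

    for s in range(config.n_series):
        sid = f"SYN{s:03d}"
        active = [truth.modules[m] for m in sorted(truth.modules)
                  if sid in truth.active_series[m]]
        series_list.append(_generate_series(
            series_id=sid,
            tissue=_tissue_of(s, config),
            condition=_CONDITIONS[s % len(_CONDITIONS)],
            n_samples=config.samples_per_series,
            n_groups=config.n_replicate_groups,
            active_modules=active,
            background_modules=_background(sid),
            config=config,
            rng=np.random.default_rng(streams[s]),
        ))
    for u in range(config.n_undersized_series):
        n = config.undersized_samples
        groups = config.n_replicate_groups if n >= 2 * config.n_replicate_groups \
            else max(2, n // 2)
        sid = f"SYNU{u:03d}"
        series_list.append(_generate_series(
            series_id=sid,
            tissue=_tissue_of(0, config),
            condition=_CONDITIONS[u % len(_CONDITIONS)],
            n_samples=n,
            n_groups=groups,
            active_modules=[],
            background_modules=_background(sid),
            config=config,
            rng=np.random.default_rng(streams[config.n_series + u]),
        ))
    return series_list, truth


def expected_module_pcc(config: SyntheticConfig, background: bool = False
                        ) -> float:
    """Factor-model within-module correlation, loading^2/(loading^2 + noise_sd^2).

    With ``background=True`` the expectation uses the weak residual loading
    core modules keep in series where they are not active.
    """
    s2 = (config.core_background_signal if background
          else config.module_signal) ** 2
    return s2 / (s2 + config.noise_sd ** 2)


def write_collection(series_list: list[ExpressionSeries],
                     ground_truth: GroundTruth,
                     directory: str | Path) -> Path:
    """Write a collection to ``directory``; returns the manifest path.

    Layout: one matrix/flags/metadata TSV triple per series, ground truth
    as JSON, and a JSON manifest listing every file plus the TE id prefix.
    """
    from . import io as _io  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for series in series_list:
        paths = _io.write_series(series, directory)
        entries.append({
            "series_id": series.series_id,
            **{k: str(Path(v).name) for k, v in paths.items()},
        })
    gt_path = directory / "ground_truth.json"
    _io.write_json(ground_truth.to_dict(), gt_path)
    manifest = {
        "te_prefix": "TE",
        "series": entries,
        "ground_truth": gt_path.name,
    }
    manifest_path = directory / "manifest.json"
    _io.write_json(manifest, manifest_path)
    return manifest_path


# ---------------------------------------------------------------------------
# companion synthetic annotation / reference-edge inputs for the downstream
# stages (enrichment test, reference-overlap test)
# ---------------------------------------------------------------------------

def generate_annotations(ground_truth: GroundTruth, genes: list[str],
                         seed: int = 0, n_random_terms: int = 20,
                         random_term_size: tuple[int, int] = (10, 50),
                         n_iep_records: int = 10,
                         ) -> tuple[list[tuple[str, str, str]], dict[str, set[str]]]:
    """Synthetic gene->term records plus an is_a hierarchy.

    One term coincides with each planted module (evidence IDA), random terms
    cover random gene subsets, one deliberately broad term covers most of the
    gene universe, and a few IEP-coded records exercise the evidence filter.
    Returns ``(records, hierarchy)`` with records as (gene, term, evidence).
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str]] = []
    hierarchy: dict[str, set[str]] = {}

    root = "T:ROOT"
    for parent in ("T:CORE_PROCESS", "T:SPECIFIC_PROCESS", "T:MISC_PROCESS"):
        hierarchy[parent] = {root}

    for mid in sorted(ground_truth.modules):
        term = f"T:MOD_{mid}"
        parent = ("T:CORE_PROCESS" if ground_truth.module_kind[mid] == "core"
                  else "T:SPECIFIC_PROCESS")
        hierarchy[term] = {parent}
        for g in sorted(ground_truth.modules[mid]):
            records.append((g, term, "IDA"))

    genes_sorted = sorted(genes)
    lo, hi = random_term_size
    for i in range(n_random_terms):
        term = f"T:RAND{i:03d}"
        hierarchy[term] = {"T:MISC_PROCESS"}
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(genes_sorted), size=min(size, len(genes_sorted)),
                            replace=False)
        for j in sorted(chosen):
            records.append((genes_sorted[j], term, "IEA"))

    broad = "T:BROAD"
    hierarchy[broad] = {root}
    for g in genes_sorted[: max(1, int(0.9 * len(genes_sorted)))]:
        records.append((g, broad, "IEA"))

    iep_term = "T:IEP_DERIVED"
    hierarchy[iep_term] = {"T:MISC_PROCESS"}
    for j in range(min(n_iep_records, len(genes_sorted))):
        records.append((genes_sorted[j], iep_term, "IEP"))

    return records, hierarchy


def generate_reference_edges(ground_truth: GroundTruth, seed: int = 0,
                             keep_fraction: float = 0.5,
                             n_random_edges: int = 200) -> set[tuple[str, str]]:
    """Reference interaction edge set: a sample of planted within-module
    pairs (physically plausible partners) plus random gene pairs."""
    rng = np.random.default_rng(seed)
    pairs = sorted(ground_truth.module_pairs())
    keep = rng.random(len(pairs)) < keep_fraction
    out = {p for p, k in zip(pairs, keep) if k}
    genes = sorted({g for m in ground_truth.modules.values() for g in m})
    for _ in range(n_random_edges):
        a, b = rng.choice(len(genes), size=2, replace=False)
        out.add(ordered_pair(genes[a], genes[b]))
    return out
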