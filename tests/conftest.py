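"""Shared fixtures: a small, fast synthetic collection for unit tests and
the full default-conditions collection for the end-to-end checks."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import pancoexpr as px


@pytest.fixture(scope="session")
def tiny_config() -> px.SyntheticConfig:
    """Small collection: 5 series, 2 core + 3 specific modules, enough noise
    genes that the top-0.1% edge budget exceeds the planted pair count."""
    return px.SyntheticConfig(
        n_series=5, samples_per_series=20, n_replicate_groups=5,
        n_core_modules=2, core_module_size=10, core_presence=4,
        n_specific_modules=3, specific_module_size=8,
        specific_presence=(1, 2), n_noise_genes=600,
        n_low_abundance_genes=30, n_te_rows=40, n_tissues=2, seed=7)


@pytest.fixture(scope="session")
def tiny_collection(tiny_config):
    series, truth = px.generate_collection(tiny_config)
    return series, truth


@pytest.fixture(scope="session")
def tiny_bundle(tiny_collection):
    """Networks, filtered matrices and the pan-network of the tiny collection."""
    series, truth = tiny_collection
    networks, matrices, reports = [], {}, {}
    for s in series:
        report = px.select_relevant_genes(s)
        networks.append(px.build_series_network(s, report=report))
        matrices[s.series_id] = s.matrix.loc[report.final_genes]
        reports[s.series_id] = report
    pan = px.compute_universality(networks)
    return SimpleNamespace(series=series, truth=truth, networks=networks,
                           matrices=matrices, reports=reports, pan=pan)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 15 series x 24 samples, 3 core modules
    active in 12 series, 10 tissue-aligned specific modules (presence 1-2)."""
    config = px.SyntheticConfig()
    series, truth = px.generate_collection(config)
    networks, matrices = [], {}
    for s in series:
        report = px.select_relevant_genes(s)
        networks.append(px.build_series_network(s, report=report))
        matrices[s.series_id] = s.matrix.loc[report.final_genes]
    pan = px.compute_universality(networks)
    return SimpleNamespace(config=config, series=series, truth=truth,
                           networks=networks, matrices=matrices, pan=pan)


def make_series(matrix: np.ndarray | pd.DataFrame, groups: list[str],
                te_rows: dict[str, list[float]] | None = None,
                present: np.ndarray | None = None,
                series_id: str = "S1", **kw) -> px.ExpressionSeries:
    """Hand-build a small ExpressionSeries from raw pieces."""
    if isinstance(matrix, np.ndarray):
        matrix = pd.DataFrame(
            matrix,
            index=[f"g{i:02d}" for i in range(matrix.shape[0])],
            columns=[f"s{j:02d}" for j in range(matrix.shape[1])])
    matrix = matrix.astype(float)
    if te_rows:
        te = pd.DataFrame(te_rows, index=matrix.columns).T
        te.columns = matrix.columns
        matrix = pd.concat([matrix, te])
    if present is None:
        pres = pd.DataFrame(True, index=matrix.index, columns=matrix.columns)
    else:
        pres = pd.DataFrame(present, index=matrix.index, columns=matrix.columns)
    return px.ExpressionSeries(
        series_id=series_id, matrix=matrix, present=pres,
        replicate_group=pd.Series(groups, index=matrix.columns),
        te_rows=frozenset(te_rows or ()), **kw)
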