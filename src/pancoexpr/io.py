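"""Readers and writers for the package's plain-text dialects.

Expression matrix: TSV, first column the gene/TE identifier, remaining
columns samples.  Sample metadata: TSV with columns sample_id,
replicate_group, tissue, condition.  Present/absent flags: parallel TSV of
P/A.  Networks: edge-list TSV (gene_a < gene_b) and GraphML.  Pan-network:
TSV with universality and supporting series.  Collections: JSON manifest
declaring the TE identifier prefix and per-series files.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ParseError
from .types import (CoexpressionNetwork, ExpressionSeries, GroundTruth,
                    PanEdge, PanNetwork, ordered_pair)


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# expression series
# ---------------------------------------------------------------------------

def write_series(series: ExpressionSeries, directory: str | Path
                 ) -> dict[str, Path]:
    """Write one series as matrix/flags/metadata TSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = series.series_id
    matrix_path = directory / f"{sid}.matrix.tsv"
    flags_path = directory / f"{sid}.flags.tsv"
    meta_path = directory / f"{sid}.samples.tsv"
    # full float repr: lossless round trip; index_label avoids mutating the
    # caller's (shared) Index object
    series.matrix.to_csv(matrix_path, sep="\t", index_label="gene_id")
    flags = series.present.replace({True: "P", False: "A"})
    flags.to_csv(flags_path, sep="\t", index_label="gene_id")
    meta = pd.DataFrame({
        "sample_id": series.samples,
        "replicate_group": [series.replicate_group[s] for s in series.samples],
        "tissue": series.tissue,
        "condition": series.condition,
    })
    meta.to_csv(meta_path, sep="\t", index=False)
    return {"matrix": matrix_path, "metadata": meta_path, "flags": flags_path}


def _read_matrix(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        line = int(np.flatnonzero(raw.index == dup)[1]) + 2  # header is line 1
        raise ParseError(f"{path}: duplicate gene id {dup!r} at line {line}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at line {r + 2}, "
            f"column {raw.columns[c]!r}")
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ParseError(f"{path}: missing value at line {r + 2}, "
                         f"column {values.columns[c]!r}")
    values.index.name = None
    return values


def read_series(matrix_path: str | Path, metadata_path: str | Path,
                flags_path: str | Path, te_prefix: str = "TE"
                ) -> ExpressionSeries:
    """Load and validate one series from its TSV triple.

    TE rows are recognized by ``te_prefix`` on the row identifier.
    Raises :class:`ParseError` on duplicate gene ids, non-numeric cells or
    samples missing from the metadata.
    """
    matrix_path = Path(matrix_path)
    matrix = _read_matrix(matrix_path)
    flags_raw = pd.read_csv(flags_path, sep="\t", index_col=0, dtype=str)
    if not flags_raw.index.equals(matrix.index) or not (
            flags_raw.columns.equals(matrix.columns)):
        raise ParseError(f"{flags_path}: flags not aligned with matrix "
                         f"{matrix_path}")
    invalid = ~flags_raw.isin(["P", "A"]).to_numpy()
    if invalid.any():
        r, c = np.argwhere(invalid)[0]
        raise ParseError(f"{flags_path}: flag {flags_raw.iat[r, c]!r} at line "
                         f"{r + 2} is not P/A")
    present = flags_raw == "P"
    present.index.name = None

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "replicate_group"}
    if not required <= set(meta.columns):
        raise ParseError(f"{metadata_path}: missing column(s) "
                         f"{sorted(required - set(meta.columns))}")
    meta = meta.set_index("sample_id")
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ParseError(
            f"{metadata_path}: sample {missing[0]!r} has no metadata row")
    sid = matrix_path.name.split(".")[0]
    tissue = str(meta["tissue"].iloc[0]) if "tissue" in meta.columns else ""
    condition = (str(meta["condition"].iloc[0])
                 if "condition" in meta.columns else "")
    return ExpressionSeries(
        series_id=sid,
        matrix=matrix,
        present=present,
        replicate_group=meta["replicate_group"].loc[list(matrix.columns)],
        tissue=tissue,
        condition=condition,
        te_rows=frozenset(g for g in matrix.index if g.startswith(te_prefix)),
    )


def read_collection(manifest_path: str | Path
                    ) -> tuple[list[ExpressionSeries], GroundTruth | None]:
    """Load a collection written by ``synthetic.write_collection``."""
    manifest_path = Path(manifest_path)
    manifest = read_json(manifest_path)
    base = manifest_path.parent
    te_prefix = manifest.get("te_prefix", "TE")
    series_list = [
        read_series(base / e["matrix"], base / e["metadata"],
                    base / e["flags"], te_prefix=te_prefix)
        for e in manifest["series"]
    ]
    truth = None
    if manifest.get("ground_truth"):
        truth = GroundTruth.from_dict(read_json(base / manifest["ground_truth"]))
    return series_list, truth


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network_tsv(network: CoexpressionNetwork, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_a\tgene_b\tpcc\n")
        for (a, b) in sorted(network.edges):
            fh.write(f"{a}\t{b}\t{network.edges[(a, b)]:.6g}\n")
    return path


def read_network_tsv(path: str | Path, series_id: str = "",
                     tissue: str = "", condition: str = ""
                     ) -> CoexpressionNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    if list(df.columns[:3]) != ["gene_a", "gene_b", "pcc"]:
        raise ParseError(f"{path}: expected columns gene_a, gene_b, pcc")
    edges: dict[tuple[str, str], float] = {}
    for i, row in df.iterrows():
        pair = ordered_pair(str(row["gene_a"]), str(row["gene_b"]))
        if pair in edges:
            raise ParseError(f"{path}: duplicate edge {pair} at line {i + 2}")
        edges[pair] = float(row["pcc"])
    cutoff = min(edges.values()) if edges else None
    sid = series_id or path.name.split(".")[0]
    return CoexpressionNetwork(series_id=sid, edges=edges, pcc_cutoff=cutoff,
                               tissue=tissue, condition=condition)


def write_network_graphml(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(graph, path)
    return path


def write_pan_tsv(pan: PanNetwork, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_a\tgene_b\tuniversality\tsupporting_series\tmean_pcc\n")
        for (a, b) in sorted(pan.edges):
            rec = pan.edges[(a, b)]
            support = ";".join(rec.series_ids)
            fh.write(f"{a}\t{b}\t{rec.universality}\t{support}\t"
                     f"{rec.mean_pcc:.6g}\n")
    return path


def read_pan_tsv(path: str | Path, n_networks: int) -> PanNetwork:
    path = Path(path)
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene_a": str, "gene_b": str,
                            "supporting_series": str})
    edges = {}
    for _, row in df.iterrows():
        pair = ordered_pair(str(row["gene_a"]), str(row["gene_b"]))
        support = str(row["supporting_series"]).split(";")
        mean_pcc = float(row["mean_pcc"])
        edges[pair] = PanEdge(series_ids=support,
                              pccs=[mean_pcc] * len(support))
    return PanNetwork(edges=edges, n_networks=n_networks)


def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Generic reference edge list: two-column (or more) TSV, one pair per
    line, header optional."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if ln == 1 and parts[0].lower() in ("gene_a", "gene", "source"):
                continue
            if parts[0] == parts[1]:
                continue
            pairs.add(ordered_pair(parts[0], parts[1]))
    return pairs


# ---------------------------------------------------------------------------
# similarity matrices
# ---------------------------------------------------------------------------

def write_similarity_tsv(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t", float_format="%.6g", index_label="series_id")
    return path


def read_similarity_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df
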