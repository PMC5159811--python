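"""End-to-end pipeline: filter -> per-series networks -> pan/core analysis
-> communities -> enrichment -> network similarity.

``run_pipeline`` writes every stage's outputs plus a machine-readable
``run_summary.json`` (counts, cutoffs, seeds, versions).  The summary is
deterministic for a given config; wall-clock timings go to the log only.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import enrichment as enr
from . import io as _io
from . import netbuild, pancore, preprocess, similarity, synthetic
from .config import PipelineConfig
from .exceptions import PancoexprError
from .types import CoexpressionNetwork, ExpressionSeries, GroundTruth

log = logging.getLogger("pancoexpr")


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_pancoexpr_tag", None) for h in log.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler()
        h._pancoexpr_tag = "stderr"  # type: ignore[attr-defined]
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh._pancoexpr_tag = "file"  # type: ignore[attr-defined]
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


class _Stage:
    """Context manager logging a stage's duration and naming it on failure."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
        return False


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and return the results directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "resolved_config.yaml")
    summary: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seeds": {s: config.stage_seed(s)
                  for s in ("synthetic", "netbuild", "pancore", "modules",
                            "enrichment", "similarity", "overlap", "label")},
    }

    # -- input collection ---------------------------------------------------
    truth: GroundTruth | None = None
    with _Stage("collection"):
        if config.input_manifest:
            series_list, truth = _io.read_collection(config.input_manifest)
            log.info("loaded %d series from %s", len(series_list),
                     config.input_manifest)
        else:
            syn = dataclasses.replace(config.synthetic,
                                      seed=config.stage_seed("synthetic"))
            series_list, truth = synthetic.generate_collection(syn)
            log.info("generated %d synthetic series", len(series_list))
    summary["n_series_input"] = len(series_list)

    # -- preprocess + netbuild ----------------------------------------------
    networks: list[CoexpressionNetwork] = []
    filtered: dict[str, pd.DataFrame] = {}
    kept_series: list[ExpressionSeries] = []
    skipped: list[str] = []
    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    with _Stage("filter+netbuild"):
        for series in series_list:
            if not preprocess.check_min_samples(series, config.min_samples):
                skipped.append(series.series_id)
                log.info("series %s skipped: %d < %d samples",
                         series.series_id, series.n_samples, config.min_samples)
                continue
            try:
                report = preprocess.select_relevant_genes(
                    series, alpha=config.anova_alpha,
                    fallback_n=config.fallback_n,
                    te_quantile=config.te_quantile,
                    te_scope=config.te_percentile_scope,
                    min_samples=config.min_samples)
                net = netbuild.build_series_network(
                    series, min_samples=config.min_samples,
                    fraction=config.edge_fraction,
                    positive_only=config.positive_only,
                    drop_nonpositive_first=config.drop_nonpositive_first,
                    report=report)
            except PancoexprError as err:
                raise PancoexprError(
                    f"stage filter+netbuild failed on series "
                    f"{series.series_id!r}: {err}") from err
            filtered[series.series_id] = series.matrix.loc[report.final_genes]
            kept_series.append(series)
            networks.append(net)
            _io.write_network_tsv(net, netdir / f"{net.series_id}.edges.tsv")
    summary["skipped_series"] = sorted(skipped)
    summary["networks"] = {
        n.series_id: {
            "n_nodes": len(n.nodes), "n_edges": n.n_edges,
            "pcc_cutoff": None if n.pcc_cutoff is None
            else round(float(n.pcc_cutoff), 6),
        } for n in networks}

    # -- pan/core -----------------------------------------------------------
    with _Stage("pancore"):
        pan = pancore.compute_universality(networks)
        hist = pancore.universality_histogram(pan)
        core = pancore.core_at_cutoff(pan, config.core_u)
        _io.write_pan_tsv(pan, outdir / "pan_network.tsv")
        _io.write_network_graphml(core, outdir / "core_network.graphml")
        profile = pancore.topology_profile(
            pan, range(1, pan.n_networks + 1),
            seed=config.stage_seed("pancore"))
        profile.to_csv(outdir / "topology_profile.tsv", sep="\t",
                       float_format="%.6g")
        pan_graph = pancore.core_at_cutoff(pan, 1)
        deg_pan = pancore.degree_distribution(pan_graph)
        deg_core = pancore.degree_distribution(core)
        fits = {}
        for name, hist_d, cutoff in (("pan", deg_pan, config.powerlaw_tail_pan),
                                     ("core", deg_core, config.powerlaw_tail_core)):
            try:
                fits[name] = round(pancore.fit_power_law(hist_d, cutoff), 4)
            except ValueError as err:
                fits[name] = None
                log.warning("power-law fit (%s) unavailable: %s", name, err)
        sub = pancore.subthreshold_pcc_test(pan, core, filtered)
    summary["pan"] = {
        "n_edges": pan.n_edges, "n_nodes": len(pan.nodes),
        "universality_histogram": {str(k): v for k, v in hist.items()},
        "fraction_u1": round(hist.get(1, 0) / pan.n_edges, 6) if pan.n_edges else None,
    }
    summary["core"] = {"u_cutoff": config.core_u,
                       "n_edges": core.number_of_edges(),
                       "n_nodes": core.number_of_nodes()}
    summary["powerlaw_exponent"] = {"fit": "log-log least squares",
                                    **fits}
    summary["hubs"] = {
        "pan": pancore.hub_table(pan_graph, 10),
        "core": pancore.hub_table(core, 10)}
    summary["subthreshold_pcc_test"] = {
        "mean_core": None if np.isnan(sub.mean_core) else round(sub.mean_core, 6),
        "mean_pan": None if np.isnan(sub.mean_pan) else round(sub.mean_pan, 6),
        "t": None if np.isnan(sub.t) else round(sub.t, 4),
        "p": None if np.isnan(sub.p) else float(f"{sub.p:.3e}"),
        "n_core": sub.n_core, "n_pan": sub.n_pan}

    # -- modules ------------------------------------------------------------
    with _Stage("modules"):
        seed_m = config.stage_seed("modules")
        parts = {}
        for name, graph in (("pan", pan_graph), ("core", core)):
            if graph.number_of_nodes() == 0:
                parts[name] = None
                continue
            parts[name] = pancore.detect_communities(graph, seed=seed_m)
        _io.write_json(
            {name: (None if p is None else
                    {"modularity": round(p.modularity, 6),
                     "sizes": p.sizes(),
                     "communities": [sorted(c) for c in p.communities]})
             for name, p in parts.items()},
            outdir / "modules.json")
    summary["modules"] = {
        name: (None if p is None else
               {"n_communities": p.n_communities,
                "modularity": round(p.modularity, 6)})
        for name, p in parts.items()}

    # -- ground-truth recovery (synthetic collections only) ------------------
    if truth is not None:
        core_edges = {tuple(sorted(e)) for e in core.edges}
        core_pairs = truth.module_pairs("core")
        spec_pairs = truth.module_pairs("specific")
        recall = (len(core_edges & core_pairs) / len(core_pairs)
                  if core_pairs else None)
        contam = (len(core_edges & spec_pairs) / len(spec_pairs)
                  if spec_pairs else None)
        summary["ground_truth_recovery"] = {
            "core_pair_recall": None if recall is None else round(recall, 4),
            "specific_pair_contamination": None if contam is None
            else round(contam, 4),
        }

    # -- reference overlap ---------------------------------------------------
    with _Stage("overlap"):
        if config.reference_edges_path:
            reference = _io.read_edge_list(config.reference_edges_path)
        elif truth is not None:
            reference = synthetic.generate_reference_edges(
                truth, seed=config.stage_seed("overlap"))
        else:
            reference = set()
        if reference and core.number_of_edges() > 0:
            obs, p = pancore.reference_overlap_test(
                core, reference, n_perm=config.n_perm_overlap,
                seed=config.stage_seed("overlap"))
            summary["reference_overlap"] = {
                "n_reference_edges": len(reference), "overlap": obs,
                "p": round(p, 6), "n_perm": config.n_perm_overlap}
        else:
            summary["reference_overlap"] = None

    # -- enrichment ----------------------------------------------------------
    with _Stage("enrichment"):
        if config.annotations_path and config.hierarchy_path:
            records = [tuple(r) for r in pd.read_csv(
                config.annotations_path, sep="\t", dtype=str
            ).itertuples(index=False)]
            hier_df = pd.read_csv(config.hierarchy_path, sep="\t", dtype=str)
            hierarchy: dict[str, set[str]] = {}
            for _, row in hier_df.iterrows():
                hierarchy.setdefault(row.iloc[0], set()).add(row.iloc[1])
        elif truth is not None:
            all_genes = sorted({g for s in kept_series for g in s.gene_ids})
            records, hierarchy = synthetic.generate_annotations(
                truth, all_genes, seed=config.stage_seed("enrichment"))
        else:
            records, hierarchy = [], {}
        enrich_out = {}
        if records:
            for name, graph in (("pan", pan_graph), ("core", core)):
                part = parts.get(name)
                if part is None or graph.number_of_nodes() == 0:
                    continue
                background = (sorted(graph.nodes)
                              if config.background_scope == "network"
                              else sorted({g for s in kept_series
                                           for g in s.gene_ids}))
                annset = enr.AnnotationSet.from_records(
                    records, hierarchy, background)
                table = enr.enrich_modules(
                    part, annset, alpha=config.enrichment_alpha,
                    broad_method=config.broad_term_method,
                    max_fraction=config.broad_max_fraction,
                    min_module_genes=config.min_module_genes)
                table.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t",
                             index=False, float_format="%.6g")
                tops = table[table["top"]]
                enrich_out[name] = [
                    {"module": int(r["module"]), "term": r["term"],
                     "q": None if pd.isna(r["q"]) else float(f"{r['q']:.3e}")}
                    for _, r in tops.iterrows()]
    summary["enrichment_top_terms"] = enrich_out or None

    # -- similarity ----------------------------------------------------------
    with _Stage("similarity"):
        sim_out: dict = {}
        if len(networks) >= 2:
            seed_s = config.stage_seed("similarity")
            jac = similarity.jaccard_matrix(networks)
            _io.write_similarity_tsv(jac.matrix, outdir / "similarity_jaccard.tsv")
            zsum = similarity.zsummary_matrix(
                networks, filtered, n_perm=config.n_perm_preservation,
                seed=seed_s, min_genes=config.min_module_genes,
                max_genes=config.max_module_genes)
            _io.write_similarity_tsv(zsum.matrix,
                                     outdir / "similarity_zsummary_raw.tsv")
            try:
                znorm = similarity.normalize_similarity(zsum.matrix)
                _io.write_similarity_tsv(
                    znorm, outdir / "similarity_zsummary_normalized.tsv")
            except PancoexprError as err:
                log.warning("similarity normalization unavailable: %s", err)
            non = similarity.network_of_networks(
                zsum.matrix, labels=zsum.labels,
                threshold=config.similarity_threshold,
                max_neighbors=config.max_neighbors)
            _io.write_network_graphml(non, outdir / "network_of_networks.graphml")
            clus = similarity.cluster_networks(jac.matrix)
            (outdir / "jaccard_dendrogram.nwk").write_text(clus.newick + "\n")
            tissues = jac.labels["tissue"]
            label_p = None
            if tissues.nunique() >= 2:
                _, label_p = similarity.label_association_test(
                    jac.matrix, tissues, n_perm=config.n_perm_label,
                    seed=config.stage_seed("label"))
            sim_out = {
                "jaccard_mean_offdiag": round(float(
                    jac.matrix.to_numpy()[~np.eye(len(networks), dtype=bool)]
                    .mean()), 6),
                "network_of_networks": {"n_nodes": non.number_of_nodes(),
                                        "n_edges": non.number_of_edges()},
                "leaf_order": clus.leaf_order,
                "tissue_association_p": label_p,
            }
    summary["similarity"] = sim_out or None

    _io.write_json(summary, outdir / "run_summary.json")
    log.info("pipeline complete; summary at %s", outdir / "run_summary.json")
    return outdir
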