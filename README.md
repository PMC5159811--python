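# pancoexpr

Pan- and core-coexpression network analysis for collections of gene
expression series.

Most coexpression studies pool many experiments into one matrix and build a
single network, which favors relationships that hold in every context and
can be distorted by batch effects.  `pancoexpr` takes the complementary
route: it builds **one network per experiment** and studies the collection.
Every edge of the union ("pan-network") carries a *universality number*

```
U(edge) = number of series networks in which the edge was observed,
```

and the "core-network" is the sub-network of edges with U ≥ 10 — gene
pairs co-regulated across many unrelated experimental contexts, typically
parts of large molecular machines.  Everything below the cutoff is
condition-specific rewiring.  The package is aimed at computational
biologists who want to separate universal from context-dependent
co-regulation in transcriptome compendia, and at method developers who
need a tested, seedable desk-scale harness for pan/core edge statistics.

## What it implements

- **Filtering** per series: ≥ 20 samples; one-way ANOVA across replicate
  groups (p < 0.01, top-3000-by-p fallback); abundance above the
  90th percentile of transposable-element probes plus a present call.
- **Network construction**: all-pairs Pearson correlation, top 0.1% of
  pairs, positive correlations only; the implied significance via
  t = r√(n−2)/√(1−r²).
- **Pan/core**: universality counting, U-histograms, nested core
  extraction, topology profiles (nodes, average degree, Louvain
  modularity, clustering coefficient vs U), degree distributions with
  log-log power-law exponents, hub tables, a Welch test showing core edges
  stay correlated even where they missed the cutoff, and reference-edge
  overlap significance under degree-preserving rewiring.
- **Module enrichment**: is_a propagation, IEP evidence removal,
  broad-term screening, one-sided Fisher exact tests, Benjamini–Hochberg.
- **Network similarity**: edge Jaccard; a permutation module-preservation
  Z-summary (density + connectivity Z-scores); min–max normalization;
  the S > 10 "network of networks" with a 10-neighbor cap; hierarchical
  clustering with Newick export; tissue-label permutation tests.
- **Synthetic collections** with planted core/specific modules and known
  ground truth, so the whole pipeline is validated end to end at desk
  scale (retrieving and normalizing a real public compendium of a hundred
  or more series is out of scope).

## Worked example

```python
import pancoexpr as px

# a synthetic collection with known planted structure
series, truth = px.generate_collection(px.SyntheticConfig())

networks = [px.build_series_network(s) for s in series]
pan = px.compute_universality(networks)
core = px.core_at_cutoff(pan, u_min=10)
hist = px.universality_histogram(pan)

print(len(networks), "networks;",
      f"pan: {pan.n_edges} edges / {len(pan.nodes)} genes;",
      f"core(U>=10): {core.number_of_edges()} edges /"
      f" {core.number_of_nodes()} genes")
print("fraction of edges at U=1:",
      round(hist[1] / pan.n_edges, 3))
print("PCC p-value at r=0.73, n=20:",
      round(px.correlation_pvalue(0.73, 20), 6))
```

prints

```
15 networks; pan: 13412 edges / 1825 genes; core(U>=10): 900 edges / 75 genes
fraction of edges at U=1: 0.818
PCC p-value at r=0.73, n=20: 0.000258
```

Read: of ~13.4 k distinct edges observed across 15 experiments, ~82% appear
in exactly one experiment (condition-specific), while the 900-edge core is
precisely the three planted "housekeeping" modules (3 × C(25,2) = 900) —
the universality cutoff separates the two regimes cleanly.  The last line
is the analytic significance of a correlation of 0.73 with 20 samples,
comfortably below 0.001, which justifies the rank-based 0.1% cutoff.

The same run from a shell:

```
pancoexpr run-all --out results/demo --seed 0
```

writes per-series edge lists, the pan-network TSV, the core GraphML, the
topology profile, enrichment tables, similarity matrices, the
network-of-networks GraphML, a Newick dendrogram and a machine-readable
`run_summary.json`.  Subcommands `simulate`, `filter`, `build`, `pancore`,
`modules`, `enrich` and `similarity` run the stages separately; every
configuration field is available as a flag or through `--config` YAML.

See `docs/methods.md` for the model, parameter meanings, and what the
synthetic benchmark does and does not demonstrate.

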