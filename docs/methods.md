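# Methods

## Problem setting

`pancoexpr` analyzes a *collection* of gene-expression experiments
("series"), each a genes × samples abundance matrix with replicate-group
structure, rather than one pooled matrix.  Each series yields its own
coexpression network; the collection is then described by two objects:

- the **pan-network**, the union of all per-series edge sets, where every
  edge carries a *universality number* U — the count of series networks it
  was observed in; and
- **core-networks**, subgraphs of the pan-network restricted to edges with
  U at or above a cutoff (default 10).

Edges with low U are *condition-specific*: they reflect co-regulation that
appears only under particular experimental contexts.  Edges with high U
connect machinery that is co-regulated almost everywhere (ribosomes,
photosystems).  The package quantifies this decomposition, characterizes
the topology of the two regimes, tests module enrichment, and compares
networks to each other ("network of networks").

## Per-series network construction

1. **Minimum sample count.**  Series with fewer than `min_samples` (default
   20) samples are excluded; correlation estimates below that are too
   unstable for a 0.1% tail cutoff.
2. **ANOVA filter.**  A one-way fixed-effects F-test per gene across
   replicate groups keeps genes with p < `anova_alpha` (default 0.01).  If
   fewer than `fallback_n` (default 3000) genes qualify, the 3000
   smallest-p genes are taken instead (all genes if fewer exist); ties at
   the boundary break by gene identifier.  Genes with zero total variance
   get p = 1 (constant rows occur in real matrices and carry no signal);
   zero within-group variance with non-zero between-group variance gives
   p = 0.
3. **Abundance filter.**  A gene must (a) carry a "present" detection call
   in at least one sample AND (b) exceed the `te_quantile` (default 0.90)
   percentile of the transposable-element rows' abundances in at least one
   sample.  TE probes measure transcripts that should be silent, so their
   90th percentile is a per-array noise floor.  The percentile is computed
   per sample (an "array" on single-channel platforms is one sample) with
   the linear-interpolation convention; a dataset-wide pooled floor is
   available via `te_percentile_scope="dataset"`.
4. **Ordering.**  ANOVA selection and abundance passing are intersected;
   the final count may drop below 3000 and is not topped up.
5. **Edges.**  All G(G−1)/2 Pearson correlations are computed on the
   filtered matrix; the top `edge_fraction` (default 0.001, i.e. 0.1%) of
   pairs are retained with k = floor(fraction · P), ties at the boundary
   resolved by lexicographic gene-pair order, and non-positive correlations
   then discarded (`positive_only`).  The alternative
   drop-negatives-before-ranking order is exposed as
   `drop_nonpositive_first`.  The 0.1% is a rank cutoff; the significance
   it implies (two-sided p from t = r√(n−2)/√(1−r²)) is reported
   separately — at the typical resulting cutoff r ≈ 0.7 and n ≥ 20 it is
   far below 0.001.  Missing values are rejected at load; zero-variance
   rows reaching the correlation step yield NaN pairs with a warning.

## Pan/core analysis

`compute_universality` merges networks (duplicate series identifiers are
an error so no series is counted twice); `core_at_cutoff` extracts U ≥ u
subgraphs, which are nested in u by construction.  The topology profile
reports, per cutoff: node count, edge count, average degree 2E/N,
modularity of a Louvain partition detected at that cutoff (best-found per
cutoff), and the average local clustering coefficient (nodes with degree
< 2 contribute 0; Gephi's convention — global transitivity is a config
switch).  Modularity is the unweighted Newman–Girvan
Q = Σ_c [e_c/m − (d_c/2m)²]; Louvain is seeded and deterministic.

Degree distributions are summarized with a log-log least-squares exponent
fitted over degrees up to a tail cutoff (defaults 50 for core, 500 for
pan), below the exponential-cutoff transition.  Least squares on the
log-log histogram is used deliberately — the quantity of interest is the
printed slope of the scale-free regime, not a maximum-likelihood tail
index — and the fit method is labeled in output.

Two statistical checks accompany the decomposition:

- **Sub-threshold PCC test.**  For every pan edge and every series in
  which it was *not* retained (both genes measured there), the PCC is
  recomputed.  Core edges' values (sample 1) are compared against all pan
  edges' values (sample 2) with a one-sided Welch t-test ("greater").
  Welch is chosen because the two samples have very different sizes and
  variances.
- **Reference-edge overlap.**  Overlap of a graph with an external
  interaction edge list is tested against a degree-preserving
  double-edge-swap null (E swaps per replicate), with empirical
  p = (1 + #{null ≥ obs}) / (n_perm + 1).

## Enrichment

Annotation records (gene, term, evidence) are filtered of IEP evidence
(inferred from expression pattern — circular for coexpression modules),
closed under is_a ancestors (cycle detection included), and screened for
overly broad terms: a term is retained only if its minimum achievable
Fisher p (a module of the largest tested size entirely inside the term)
could pass alpha divided by the number of candidate terms.  A simpler
maximum-fraction-of-background rule (default 0.2) is available.  Each
(module, term) pair gets a one-sided Fisher exact p (hypergeometric upper
tail) over the background universe — by default the genes of the network
under test, with a genome-wide switch — followed by Benjamini–Hochberg
correction pooled across the whole table (the correction family is
otherwise arbitrary; pooling is the conservative common choice).

## Network similarity

- **Jaccard**: J(i, j) = |E_i ∩ E_j| / |E_i ∪ E_j| on edge sets.
- **Z-summary**: modules are detected per network (Louvain; modules with
  fewer than 5 genes skipped, very large noise agglomerates above
  `max_module_genes` excluded to bound permutation cost).  For a module of
  network i evaluated in series j, the *density* statistic is the mean
  pairwise PCC of the module genes in j, and the *connectivity* statistic
  is the correlation between the genes' intramodular connectivity (row
  sums of within-module PCC) in i versus j.  Both are standardized against
  `n_perm` random equal-size gene sets drawn from the genes shared by both
  series; Z_summary is the mean of the two Z-scores (for self-evaluation
  the connectivity null is degenerate and Z_summary reduces to the density
  Z).  This is a deliberately simplified two-statistic analog of WGCNA's
  modulePreservation Zsummary: permutation-based, self-contained, and
  using this pipeline's Louvain modules rather than WGCNA blockwise
  modules.  S(i, j) is the mean Z_summary over modules, symmetrized as
  (S(i,j) + S(j,i))/2; the directed matrix is available and its diagonal
  (self-preservation) dominates each row on synthetic defaults.
- **Network of networks**: edges where raw S > 10 (the threshold applies
  to raw scores; min–max normalization to [0, 1] exists only for
  visualization-style outputs and never replaces raw values), then each
  node keeps only its 10 highest-S neighbors ("first" neighbors read as
  strongest; ties break by series id); an edge survives if either endpoint
  keeps it; isolated nodes are dropped.
- **Clustering**: average-linkage hierarchical clustering on
  1 − normalized similarity, deterministic leaf order, Newick export.
  Undefined entries are imputed as the minimum observed similarity with a
  warning.
- **Label association**: the statistic mean(within-label similarity) −
  mean(between-label similarity) against a label-permutation null.

## Synthetic study conditions

The generator emulates a compendium of public microarray experiments at
desk scale.  Defaults (the study conditions for all end-to-end checks):
15 series × 24 samples × 6 replicate groups; 3 core modules of 25 genes,
each active in the first 12 series; 10 specific modules of 25 genes,
tissue-aligned, with presence cycling 1–2 series; 1500 noise genes; 150
low-abundance genes; 200 TE rows; 3 tissue blocks.

Planted modules follow a latent-factor model: within an active series,
each module gene is baseline + amp·(s·f + σ·ε) with shared factor f per
sample, loading s = 0.95 and noise σ = 0.3.  Pearson correlation is
invariant under per-gene affine maps, so the expected within-module PCC is
s²/(s² + σ²) ≈ 0.91 regardless of baseline (uniform 300–1000) and
amplitude (25).  The factor carries 70% of its variance between replicate
groups, which is what the ANOVA filter detects; noise genes are i.i.d. and
group-free.  Core modules additionally keep a weak residual loading of
0.2 (PCC ≈ 0.31) in series where they are not active — housekeeping
machinery stays mildly co-regulated everywhere — which is the mechanism
behind the sub-threshold PCC test; setting `core_background_signal = 0`
restores fully silent inactive modules.  Specific modules are always
fully silent outside their active series.  TE rows are uniform 20–80,
low-abundance genes uniform 1–10 (strictly below any TE value) and
flagged absent everywhere; regular genes are flagged present.

These sizes were chosen so that the post-filter gene count (≈ 1825) gives
≈ 1.66 M pairs and a top-0.1% budget of ≈ 1664 edges per series — more
than the planted active pairs, so planted edges are recovered while the
boundary of the cutoff is set by the null-correlation tail (around
0.6–0.7 at n = 24, of the same order as published series-level cutoffs).
Node counts per network land in the hundreds-to-thousands range typical
of real series networks.

What the generator does **not** emulate: probe-level artifacts, MAS5-style
detection calling (flags are planted, not derived), batch effects,
heavy-tailed abundance distributions, and correlated noise between
modules.  Passing tests therefore demonstrate that the pipeline's
machinery recovers known structure under a clean factor model — not that
it is robust to every failure mode of real microarray compendia.

## Numerical choices and degenerate inputs

- All randomness flows from a single root seed fanned out per stage
  (`PipelineConfig.stage_seed`); reruns with the same seed produce
  byte-identical run summaries (timings go to the log only).
- Tie-breaks are lexicographic everywhere (edge boundary, ANOVA boundary,
  hub ranking, neighbor cap) for determinism.
- k = floor(fraction · P); k = 0 yields an empty network with a warning.
- Empty graphs at a profile cutoff record NaN metrics rather than raising;
  empty Fisher modules and single-class label tests raise.
- Zero permutation-null standard deviation leaves a Z undefined (NaN) and
  is flagged; NaN similarity entries are imputed as the minimum for
  clustering only.
- `n_perm` defaults: 100 (preservation), 200 (overlap), 999 (labels) —
  small enough for desk-scale runs, large enough for the p resolutions
  asserted in the tests.

## Known limitations

- The Z-summary is a two-statistic surrogate, not WGCNA's full composite;
  absolute values are not comparable to WGCNA output, though the > 10
  "strong preservation" regime behaves analogously on planted modules.
- The broad-term screen approximates an intent (exclude terms that cannot
  yield informative enrichment) rather than a published formula.
- The log-log least-squares exponent is biased relative to
  maximum-likelihood estimators for true power laws; it is reported as a
  descriptive slope.
- The permutation null of the overlap test mixes slowly on very dense or
  very small graphs; such graphs are reported with p = 1 and a warning.
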