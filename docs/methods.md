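# Methods

## The screening model

The pipeline formalises a common integrative-pharmacology workflow: an
herb's candidate constituents are screened by structure similarity to
known drugs, their predicted gene targets are joined with a disease's
known therapeutic targets through a confidence-filtered
protein–protein interaction (PPI) layer, and the resulting undirected
graph is mined for *key targets* — nodes that are simultaneously
well-connected (degree), bridging (betweenness) and central
(closeness). Key targets are then tested for pathway
over-representation, and bench plausibility is checked with microplate
inhibition statistics.

The graph model is deliberately minimal: undirected, unweighted, no
self-loops, no parallel edges. PPI confidence scores are carried as
edge attributes but never enter shortest-path computations; the
centrality definitions used in this literature are path-count based,
and mixing in weights would change the medians the screen depends on.

### Threshold semantics

Every screen in the pipeline is **strict**: compounds need similarity
*T* > 0.8 (not ≥), PPI edges need a combined score strictly above the
table median, and key nodes need all three centralities strictly above
their medians. Strictness has an important degenerate consequence that
the tests pin down: a constant score column survives nothing, and a
vertex-transitive graph (e.g. a cycle) yields an empty key set. The
median of an even-length list is the mean of the two middle order
statistics, so an even-length table of distinct scores keeps exactly
half its edges.

### Merged-network arithmetic

Declared inputs at study scale are 1 herb + 10 compounds + 155
putative targets + 282 disease targets = 448 entities, yet the merged
interaction network of the case study has 307 nodes. Two mechanisms
account for the difference, and both are explicit knobs here:

* genes on both target lists collapse into a single `shared_target`
  node (counted toward both lists in reports);
* after the median screen, target nodes with no incident edge are
  dropped (`drop_isolated=True` by default — an interaction table
  imported into a network viewer contains only connected nodes). The
  herb and compound nodes are connected by construction and never
  drop.

The study-scale synthetic scenario realises one consistent reading of
that arithmetic — 30 shared genes and 111 post-screen-isolated
disease-only genes (30 + 111 = 141 = 448 − 307) — and reproduces
166/165 and 307/1086 nodes/edges exactly, by construction. Any other
split of 141 between the two mechanisms would reproduce the same
totals; with only the published counts to constrain it, the choice is
arbitrary and is fixed once here.

### Centrality conventions

* **Degree** is the raw link count (the printed degrees in this
  literature are integers).
* **Betweenness** is Brandes-accumulated and normalised by
  (n−1)(n−2)/2 with *n* the whole-network node count, giving values in
  [0, 1]; graphs with n < 3 score 0 everywhere. This is the common
  analyzer convention and matches the magnitude of the published
  values (10⁻⁴–10⁻¹ on a ~300-node network).
* **Closeness** is component-scaled: (m−1)/Σd within the node's
  connected component, 0 for isolates. The whole-graph scaling
  (×(m−1)/(n−1)) used by some analyzers is available via
  `whole_graph_scaled_closeness` but off by default; on a network
  dominated by one large component the two agree up to a factor near
  1, and the component convention matches the published 0.32–0.43
  range.
* **Medians** for the key screen are taken over *all* nodes of the
  analysed network, herb and compounds included — the published key
  set contains the herb and three compounds, so non-gene nodes
  demonstrably compete in the screen.

Both centralities are validated against brute-force Floyd–Warshall
path-counting oracles (tolerance 1e-9) on every connected graph with
up to 7 nodes and on 100 random graphs with up to 50 nodes.

### Enrichment

The over-representation test is the exact hypergeometric upper tail
P(X ≥ k) computed through the survival function (log-space internally),
with the EASE variant (tail at k−1, floored at 0) available because
DAVID-style servers apply it; EASE is provably never more significant
than the plain tail. The background defaults to the union of all
annotated genes and is overridable; query genes outside the background
are dropped with a logged count, and terms with zero overlap are
omitted. Benjamini–Hochberg step-up adjustment is applied by default.

Exact published enrichment p-values are **not** reproducible targets:
they depend on a specific annotation snapshot and background that are
not available. The stage is validated instead by oracle equivalence
(exact PMF summation), by planted-term recovery, and by null
calibration. One caveat the test suite makes explicit: for a discrete
exact test the null probability of p < 0.05 is *below* 0.05 (measured
≈ 0.02 over all term tests at the default sizes), so the calibration
check asserts the one-sided bound — the false-positive fraction does
not exceed 0.05 plus three binomial standard errors — rather than a
two-sided band around 0.05, which only a continuous p-value could
satisfy.

### Plate statistics

Inhibition ratio is computed from **group mean** ODs:
IR(%) = (OD_ctrl − OD_trt)/(OD_ctrl − OD_blank) × 100, unclamped
(negative values mean growth stimulation), with `od_blank` defaulting
to 0 — the blank well's value is never published, and a zero blank
reproduces the published 22.8% and 10.4% BEL-7404 ratios to rounding.
The published 5.5% ratio for the 6.25% serum dose (mean-based
recomputation: 5.0%) and all normal-liver-line ratios (5.4/2.5/1.9%
printed vs 5.3/2.4/1.4% recomputed) are *not* consistent with
mean-based arithmetic; per-replicate averaging likely produced them,
but the replicate values are unrecoverable, so those rows are
documented here and excluded from strict checks. Group SDs use the
n−1 denominator; the between-group test is the classical
equal-variance Student t-test (a Welch flag exists), skipped with a
warning for groups with fewer than two replicates.

## The synthetic generators

`netpharm.synthetic` emulates the *statistical shape* of the real
exports, not their content: gene symbols are `G000001…`, compounds
`CPD0001…`. Every generator is driven by one integer seed through
independent `numpy` PRNG streams; identical seeds give byte-identical
files.

What the scenarios emulate, and the default conditions:

* **Compound table** — 25 candidates of which exactly 10 draw
  similarity scores above 0.8 (uniform on either side of the
  threshold, with a small guard band so 4-decimal rounding cannot
  cross it); associations link each of 155 targets to a configurable
  number of passing compounds (default 1, matching the 165-edge
  published network).
* **Disease list** — 282 genes, a configurable fraction shared with
  the putative targets.
* **PPI layer** — preferential attachment by default (the published
  6–61 degree span on ~300 nodes implies heavy-tailed degrees), with
  i.i.d. uniform combined scores so roughly half of a large table
  falls below its median. Optional planted hubs attach to 35% of the
  base nodes and to each other, so they dominate all three centrality
  medians by construction; the key-node screen recovers all five hubs
  in ≥ 95 of 100 seeded 200-node runs (measured: 100/100).
* **Annotations** — background of 1000 genes, 50 terms of nominal
  size 50–100 (5–10% of the background, a typical pathway-annotation
  density), query of 62 genes — the key-target count of the case
  study. "Enriched by factor *f*" means literally *f*-fold: the
  planted term includes each query gene with probability f·K/N, other
  genes with the probability that keeps the expected term size at K.
  At f = 4 the planted term attains the smallest raw p in ≥ 95% of
  runs; at f = 1 its rank is uniform.
* **Plate** — OD = group mean × (1 + Gaussian noise), truncated at 0,
  three replicates; default group means are the published BEL-7404
  values and the relative noise SD (0.015) matches the ~0.01 OD
  replicate SDs of that table.

What the synthetic data does **not** carry: real gene identity and
real interaction structure. Consequently the published per-gene
centrality triples (TP53 61/0.1278/0.4129, CASP3 24/0.0246/0.3711,
BCL2 12/0.0028/0.3333, BAX 8/4.55e-4/0.3271), the published ranges,
and the exact 66-node key set are functions of the actual interaction
export and cannot be recomputed here — the study-scale scenario
reproduces the published node/edge bookkeeping exactly but yields its
own key-node count (~97 at the default seed). Passing tests therefore
demonstrate the correctness of the machinery and the recoverability of
planted structure, not agreement with any particular biological
network.

## Numerical and procedural choices

* Gene symbols are upper-cased and trimmed at ingestion — one
  canonical key across database dialects.
* Conflicting duplicate PPI rows keep the maximum score (deterministic
  and conservative toward retaining evidence); associations and
  disease rows keep the first occurrence.
* Enrichment results sort by raw p with term id as tiebreak, so
  output order is total and reproducible.
* The median screen is applied exactly once, to the full input table,
  before merging; re-filtering a kept set would use a new median and
  is deliberately not done.
* Pipeline runs echo their full configuration into `report.json`;
  re-running an identical configuration reproduces byte-identical
  TSV artifacts.

## Validation problem sizes

The test suite exercises: every connected ≤ 7-node graph plus 100
random ≤ 50-node graphs against the centrality oracles; 150+ random
parameter sets against the exact hypergeometric enumeration; 100
seeded runs each for hub and term recovery; and 2000 null plates for
t-test calibration (rejection rate within three binomial standard
errors of 0.05). The full suite runs in well under a minute on one
CPU.

## Limitations

* Tanimoto similarity is consumed, never computed — no chemistry is
  performed.
* The pipeline does not recalibrate PPI confidence scores or model
  evidence channels; the median screen is a rank cut, nothing more.
* Enrichment is organism-agnostic and snapshot-agnostic; published
  p-values from versioned annotation servers are out of reach by
  design.
* Dose–response modelling (IC50 fitting), image-based assays and
  densitometry are out of scope; the bioassay module stops at group
  summaries and t-tests.
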