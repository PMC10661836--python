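# Methods

## Scope and model

`keynet` implements a degree-centrality screening procedure for scored
protein–protein interaction networks. The underlying model is deliberately
simple: influence in the network is proxied by degree (hub status), and
confidence in an individual interaction is proxied by a STRING-style
combined score (CS) on the 0–999 integer scale. The procedure makes no
attempt to model interaction mechanisms; it is a descriptive screen whose
output is a shortlist of candidate key proteins and a small subnetwork
around them.

All graphs are simple and undirected. Edge scores are data: the package
never recomputes a combined score from its evidence channels (coexpression,
experimental, text mining); channels are carried through to reports
unchanged.

## Topology definitions

Statistics follow the Cytoscape NetworkAnalyzer conventions, fixed here
explicitly because published values depend on them:

| statistic | definition |
|---|---|
| average neighbors | 2E/N (mean degree) |
| density | 2E/(N(N−1)), N ≥ 2 |
| characteristic path length | mean shortest-path distance over connected ordered pairs |
| diameter | maximum finite shortest-path distance |
| clustering coefficient | mean over nodes of Cᵢ = 2eᵢ/(kᵢ(kᵢ−1)); Cᵢ = 0 for kᵢ < 2 |
| heterogeneity | √(population variance of degree) / mean degree |
| centralization | (N/(N−2))·(k_max/(N−1) − density); 0 reported for N < 3 |
| closeness | reciprocal mean distance to reachable nodes; 0 for isolated nodes |
| betweenness | Brandes dependency sum / (N−1)(N−2), ties split fractionally |

Two of these choices are load-bearing. First, heterogeneity uses the
divide-by-N (population) variance: on the 6-node/7-edge reference
subnetwork with degree sequence (3,3,2,2,2,2) this yields 0.20 and on the
10-node/44-edge one 0.045 → 0.05, the published values, whereas the sample
variance would give 0.22. Second, betweenness is normalised by the
ordered-pair count (N−1)(N−2), which puts values in [0, 1] and matches the
normalised NetworkAnalyzer/networkx convention; the test suite pins all
path-based statistics against networkx as an independent oracle on random
graphs of up to 8 nodes at 1e−9.

Disconnected graphs are legal inputs: path statistics are computed over
connected pairs only and the report carries a `connected` flag. Reports
always print both the undirected edge count and the directed-pair count
(2E), because published network legends mix the two conventions.

Display rounding (1 decimal for average neighbors, 2 for unit-interval
statistics) is applied only in the TSV writers; dataclasses retain full
precision.

## Key-protein selection

* **HDPs** — the top-k nodes by degree, k = 2 by default. If the k-th rank
  is tied, all tied nodes are returned and a tie flag is set: degree alone
  cannot order them, and dropping some silently would bias the screen.
* **CS threshold** — the q-quantile (default q = 0.90) of the edge
  combined-score multiset. The default quantile rule is nearest-rank
  (ceil(qm)-th order statistic), so the threshold is an attainable score
  value and the strict `CS > threshold` criterion is well defined; linear
  interpolation is available as an option.
* **HSIPs** — neighbors of an HDP joined by an edge strictly above the
  threshold, sorted by CS descending. Strictness matters only at the exact
  threshold value and is the convention adopted throughout.
* **Subnetwork** — breadth-first closure of the HDP set along
  above-threshold edges, default depth 2 (the direct HSIPs plus one further
  shell, which is what published key-protein subnetworks contain). The
  default edge policy keeps *every* network edge among members (induced
  subgraph): a complete published subnetwork with density 1.0 is only
  reproducible this way, since some member–member edges sit below the
  threshold. The alternative `above_threshold_only` policy is exposed for
  the stricter reading. Raising the threshold can only shrink HSIP sets and
  the closure (anti-monotonicity; property-tested).

## Frequency distributions

Degree histograms bin the max-normalised degree into five half-open classes
on (0, 1], class 1 starting at 0 exclusive, so isolated nodes are never
binned and the maximal-degree node always lands in the top class. Score
histograms bin raw CS values into classes of width 120 starting at 400 (the
usual medium-confidence floor); the top class is closed, spanning 880–999.

The relative-frequency denominator is decoupled from the binned-item count
because published figures normalise degree frequencies to protein counts
and score frequencies to directed-pair interaction counts, neither of which
must equal the number of items binned. Defaults: node count for degree
tables, 2E for score tables; passing the item count as a custom denominator
makes the frequencies sum to exactly 1.

## Enrichment

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k), X ~ Hypergeom(N, K, n), computed by `scipy.stats.hypergeom`; the
EASE variant substitutes k−1 (so singleton overlaps are never significant,
the DAVID convention). Fold enrichment is (k/n)/(K/N); n counts only
annotated query genes. Adjustment is Benjamini–Hochberg by default
(`statsmodels`), Bonferroni optional; chart counting at a significance
cut-off uses the raw p, mirroring DAVID's chart reports, with the adjusted
p reported alongside. The background defaults to all genes appearing in the
annotation and can be overridden with an explicit population size. Exact
reproduction of any published DAVID p-value is out of reach without that
tool's internal background and GO release; the contract here is the
statistical machinery, property-tested against an exact
binomial-coefficient enumeration and a sampling estimate.

## Synthetic data

The generator answers one question: does the screen recover known structure
under realistic conditions? It emulates two features of curated PPI
networks:

* **Hub separation.** An Erdős–Rényi background (defaults: 28 nodes,
  p = 0.12, mean background degree ≈ 3) with 2 planted hubs wired to degree
  22 — the degree gap observed between published hub proteins (degrees
  ~28–64) and their network means (~5–12), scaled to a 28-node graph.
  Recovery of both hubs by top-2 degree ranking succeeds in ≥ 95% of 100
  seeded replicates (tested).
* **Score bimodality.** Edge CS values drawn from a two-component uniform
  mixture: weight 0.55 on [400, 760) and 0.45 on [880, 999], leaving the
  760–880 class empty in expectation — the "valley" profile seen in
  STRING-derived score histograms where high-confidence interactions
  dominate. The class-4 depletion is verified over 100 replicates.

Edge scores are drawn independently of topology, so hub recovery (a degree
property) and HSIP selection (a score property) are exercised as
independent axes. Channel scores are sampled uniformly below the combined
score with one channel pinned to it, preserving the invariant that the
combined score is the maximum channel. A single integer seed drives all
randomness through `numpy.random.default_rng`; no global state is touched.

What the generator does **not** emulate: scale-free degree distributions,
score–degree correlation, protein families/complex structure, and the
identity of real STRING edges. Passing tests therefore demonstrate the
correctness and statistical behaviour of the procedure, not biological
conclusions about any real network.

The packaged fixture lists (PoS 36, AcouStim 33, Tin 60 symbols; 81 unique
over six non-empty Venn regions) have exact membership; their relevance
scores are placeholders drawn uniformly from the observed range
[0.8, 30.9] under a fixed seed, since the original per-gene keyword scores
are not published. One caveat is inherited from the source material: the
prose list sizes (36/34/61) and the tabulated region sums (36/33/60)
disagree by one gene in two lists; the fixture follows the tabulated
regions, and the discrepancy is documented rather than resolved.

## Pipeline and numerical choices

The pipeline writes deterministic TSVs (fixed column orders, `%.6g` float
formatting, LF endings): identical config + seed gives byte-identical
tables. The run manifest (JSON) records the package version, seed, full
config and stage timings. Any stage failure removes partial outputs and
raises an error naming the stage.

Tie-breaks are deterministic everywhere: degree ties alphabetical, HSIP
ties by CS then name, enrichment ties by p, then larger overlap, then term
id. Degenerate inputs have defined behaviour: single-node networks report
centralization 0 with a warning, edgeless networks are rejected by the
quantile and distribution operations, a degenerate all-equal score
distribution yields a threshold with zero strictly-exceeding edges.

Problem sizes throughout the test suite and reference computations are
desk-scale by design — graphs of 5–57 nodes and 100-replicate simulation
batches — matching the curated-network regime the procedure targets; the
whole suite runs in a few seconds.

## Limitations

* Degree ranking is one hub criterion among many (MCC, MNC, bottleneck are
  deliberate non-goals); closeness and betweenness are reported
  descriptively, not used for selection.
* Identifier handling is case normalisation only; no alias/ortholog mapping.
* Annotations are flat: no GO-graph propagation, no DAVID clustering.
* The combined score is trusted as given; no evidence-channel integration
  or recalibration is attempted.
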