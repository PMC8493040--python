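# Methods

## Graph construction

The GO DAG is read from OBO flat files (obsolete terms excluded, `alt_id`
accessions mapped to their canonical ids). All relation types — `is_a`,
`part_of`, `regulates`, … — are flattened identically to undirected,
unweighted edges; direction and type are discarded for embedding purposes
because walk-based methods operate on plain adjacency. A relation-type
filter and per-namespace graphs are available, but the default merges the
three namespaces into one GO graph. The GOA graph adds one node per
annotated protein and one edge per (protein, annotating term) pair on top of
the flattened term–term edges; protein and term id spaces must be disjoint.

Annotations come from GAF 2.x. Evidence codes are not filtered by default;
include/exclude lists are optional. Annotations are **not** propagated to
ancestor terms before building the GOA graph — proteins connect only to
their directly annotated terms. (Propagation would densify the GOA graph
and blur the distinction between specific and general annotation; the IC
machinery already accounts for ancestry where it matters.)

## Embedding methods

All four methods are implemented in seeded numpy and are bitwise
reproducible per seed on one machine.

- **Walk-based (DeepWalk / Node2vec).** One code path: `generate_walks`
  applies the second-order (p, q) transition rule — weight 1/p to return,
  1 to a neighbor of the previous node, 1/q otherwise, normalized over the
  current node's neighbors — and `train_skipgram` fits skip-gram with
  negative sampling over windowed co-occurrences, minibatched SGD with a
  linearly decaying learning rate and a unigram^0.75 noise distribution.
  DeepWalk is the p = q = 1 special case (uniform steps, sampled without
  building the weight vector — the same distribution). Negatives that
  collide with the true context are masked out; this matters on very small
  graphs where the noise distribution has few atoms.
- **LINE.** Both directions of every undirected edge are positive examples.
  First order shares one vector table (symmetric objective); second order
  uses a separate context table. `concatenated` trains both at d/2 and
  concatenates.
- **SDNE.** Full-batch autoencoder on adjacency rows: sigmoid hidden layer
  of size min(256, n) on each side, linear bottleneck of size d, Adam.
  Reconstruction error up-weights nonzero adjacency entries by β (default
  5); the first-order penalty α·2tr(ZᵀLZ) (default α = 1e-5) pulls adjacent
  nodes together in embedding space. A non-finite loss aborts with a
  diagnostic rather than returning garbage.

Default hyperparameters (d = 128, 10 walks of length 80 per node, window
10, 5 epochs, p = q = 1) follow common practice in the embedding
literature. Pipeline runs on desk-scale fixtures use smaller settings
(d = 32, walks of length 30, window 5, 3 epochs) — at a few hundred nodes
the larger setting adds runtime but no measurable signal. Isolated nodes
keep their random initialization and are flagged in
`EmbeddingMap.isolated`.

## DTW protein similarity

DTW needs sequences, but GO annotation sets are unordered; term vectors are
ordered lexicographically by GO id, a deterministic convention that makes
scores independent of input order (any fixed order yields a valid
alignment; DTW's elasticity absorbs much of the arbitrariness). The local
metric d(·,·) defaults to Euclidean distance, with cosine distance as an
option. Boundary conditions: D(1,1) = d(1,1) and cumulative sums along the
first row/column; diagonal steps pay the local distance twice, so the
unwarped diagonal alignment of identical sequences costs 0.

Raw DTW distances grow with sequence length, so scores are mapped to
s = 1/(1 + D(m,n)/(m+n)) ∈ (0,1]: length-normalized, strictly decreasing in
distance, and on the same scale as cosine scores so that τ-threshold and
percentile screening apply to both routes.

## IC similarities

p(g) counts proteins annotated by g *or any descendant* (descendant closure
over all directed relation types, matching the flattening choice), divided
by the total number of annotated proteins N. Terms never used have p = 0
and IC = +∞; pairs involving them are undefined rather than infinitely
similar, and undefined term pairs are skipped inside each BMA max (a pair
is undefined overall only if every term pair is). The MICA maximizes IC
over common ancestors with ties broken by term id. The Rel measure
multiplies Lin's ratio by (1 − p(g_c)), keeping it in [0, 1); an additive
variant is available behind a flag. Jiang–Conrath scores are ≤ 0 and are
not rescaled before BMA. Cross-namespace pairs have no common ancestor and
are undefined.

## Screening and link prediction

τ screening keeps pairs with score strictly above τ. Percentile bands rank
defined pairs by score descending (ties broken by pair id): top 5% = the
first 5% of ranks, last 5% = the final 5%, middle 5% = the 5%-wide band
centered at the median rank. Undefined pairs never enter the ranking
denominator; self-pairs never become edges.

The evaluation removes round(0.2·|E|) edges entirely (E_r — never scored,
neither probe nor non-edge), then splits the remainder into training E_p
and probes E_t (default 20% of E_s as probes). Indexes are computed on E_p
only. Non-edge candidates are exhaustive for networks with ≤ 2,000 nodes,
else a uniform sample of 10·|E_t| under seed. AUC is the exact tie-corrected
rank statistic (Mann–Whitney U / (n₊n₋)); a sampled estimator exists for
cross-checking. Recall uses M = |E_t| so that exhaustive retrieval reaches
recall 1; the variant M = |E| − |E_r| is available behind a flag. AUCPR is
the trapezoidal area under the PR curve anchored at (recall 0, first
precision), so a perfect ranking scores exactly 1.

## Synthetic fixtures

`gen_ontology` builds a single-root layered DAG; each non-root term takes
1–2 parents from a 3-wide window around its relative position in the layer
above. The window is what makes id-contiguous terms descend from shared
ancestors — the synthetic analogue of semantically related GO terms
clustering under common parents — and without it, term embeddings carry no
community information and only exact term sharing would. `gen_annotations`
anchors each protein community to a disjoint block of leaf terms; a protein
draws k ∈ [3, 8] terms, from its block with probability 0.9 and uniformly
from all leaves otherwise. `gen_ppi` is a planted partition over the same
communities (p_in = 0.3, p_out = 0.02). Defaults (200 terms, 5 layers,
100 proteins, 2 communities) keep a full pipeline run around ten seconds.

What the fixture does **not** emulate: GO's term-degree distribution and
namespace sizes, multi-namespace annotation profiles, evidence-code
composition, and the heavy-tailed degree distribution of real PPI networks.
Passing tests therefore demonstrate that the machinery recovers planted
annotation-community signal end to end — not that any particular embedding
method wins on real Human/Yeast data.

## Numerical and design notes

- Every stochastic stage takes a seed; pipeline stages derive their seeds
  from the run seed by fixed offsets.
- The planted 2-community link-prediction ceiling is well below 1: probe
  edges and within-community non-edges are statistically exchangeable, so
  AUC is governed by the cross-community non-edge fraction (≈ 0.73 at the
  default densities for RA).
- Coincidence degree normalizes by the larger edge set, making it symmetric
  and conservative when the two networks differ in size.
- Degenerate inputs fail loudly: empty vector sets, dimension mismatches,
  cycles in the directed DAG, protein/term id collisions, and networks too
  small to split all raise with specific messages.

## Problem sizes used in the checks

Analytic checks run on hand-sized graphs (≤ 4 nodes, ≤ 4-step sequences).
Stochastic checks use the default fixture (200 terms / 100 proteins / 4,950
scored pairs / 248-edge screened networks), 60-node planted graphs for
community recovery (5 seeds per method), and 100-node Erdős–Rényi nulls —
sizes at which each check's outcome is stable across seeds while the whole
suite stays in the tens of seconds.
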