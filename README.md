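# gosimnet

Protein functional similarity networks from Gene Ontology graph embeddings.

Two proteins that perform related functions tend to be annotated with
related GO terms. `gosimnet` turns that intuition into similarity networks
and asks how predictive they are of actual protein–protein interactions.
It is aimed at computational biologists comparing unsupervised
representation-learning approaches to classical information-content (IC)
semantic similarity.

## What it computes

**Embeddings.** The GO DAG is flattened into an undirected, unweighted *GO
graph* (every `is_a` / `part_of` / … relation becomes a plain edge);
combining term–term edges with term–protein annotation edges gives the
heterogeneous *GOA graph*. Four methods learn a vector per node:

- **DeepWalk** — uniform truncated random walks fed to skip-gram with
  negative sampling.
- **Node2vec** — biased walks: from the previous node *t*, the unnormalized
  weight of moving to neighbor *x* is 1/p if *x* = *t*, 1 if *x* is adjacent
  to *t*, and 1/q otherwise; p = q = 1 recovers DeepWalk exactly.
- **LINE** — edge-wise first-/second-order proximity objectives,
  maximizing log σ(ωᵤ·ωᵥ) over edges with negative sampling.
- **SDNE** — an adjacency-row autoencoder (bottleneck = embedding) with loss
  Σ‖(S′ᵢ − Sᵢ) ⊙ bᵢ‖² + α Σᵢⱼ Aᵢⱼ‖zᵢ − zⱼ‖², nonzero entries up-weighted by β.

**Protein similarity.** On the GO route, a protein with terms
G = {g₁,…,gₘ} becomes the vector sequence V = {v₁,…,vₘ} (lexicographic term
order) and pairs are compared by dynamic time warping:

    D(i,j) = min( D(i−1,j) + d(i,j),  D(i,j−1) + d(i,j),  D(i−1,j−1) + 2·d(i,j) )

mapped to a similarity s = 1/(1 + D(m,n)/(m+n)) ∈ (0,1]. On the GOA route,
protein vectors ω are compared by cosine, ωₘ·ωₙ/‖ωₘ‖‖ωₙ‖.

**IC baselines.** With p(g) the fraction of proteins annotated by g or a
descendant and IC(g) = −log p(g), term pairs are scored by Jiang–Conrath,
2·IC(g_c) − IC(g₁) − IC(g₂), or by Rel,
[2·IC(g_c)/(IC(g₁)+IC(g₂))]·(1 − p(g_c)), where g_c is the most informative
common ancestor; protein pairs by the Best Match Average of their term sets.

**Evaluation.** Scored pairs are screened into a network by a threshold
(τ > 0.4) or a rank band (top/middle/last 5%). Networks are evaluated by
(i) the coincidence degree with a reference PPI, |Ea ∩ Eb| / max(|Ea|,|Eb|),
and (ii) link prediction: remove 20% of edges, split the rest into training
and probe sets, score candidate pairs with common neighbors (CN), Jaccard
(JC) or resource allocation (RA = Σ_z 1/K_z over common neighbors), and
report AUC (probability a probe outranks a non-edge, ties ½) and AUCPR.

A synthetic fixture generator (layered DAG ontology, community-structured
annotations, planted-partition PPI) makes the whole pipeline runnable and
testable without downloads; point the CLI at a real `go.obo`, GAF file and
PPI edge list to run at full scale.

## Worked example

```python
from gosimnet.synthetic import FixtureSpec, write_fixture
from gosimnet.pipeline import RunConfig, run_pipeline

write_fixture(FixtureSpec(seed=7), "fixtures")   # 200 terms, 100 proteins
cfg = RunConfig(obo="fixtures/ontology.obo", gaf="fixtures/annotations.gaf",
                ppi="fixtures/ppi.tsv", mode="go_dtw", outdir="run",
                dim=32, band="top", band_frac=0.05, index="ra",
                repeats=5, seed=7)
run_pipeline(cfg)
```

prints to `run/result.json` (times vary):

```
n_terms 200  n_proteins 100
network_edges 248
coincidence_degree 0.1167
auc 0.7154 +- 0.0487
aucpr 0.0882
```

Read: the top-5% DTW similarity network (248 of 4,950 scored pairs) shares
~12% of its edges with the planted PPI (chance would be ~5%), and RA link
prediction on it reaches AUC ≈ 0.72 — the annotation communities planted in
the fixture are recovered end to end. The same run with `band="last"` drops
to chance, mirroring the expectation that AUC falls as node similarity falls.

The same steps are available as subcommands
(`gosimnet fixtures|embed|icsim|protsim|screen|coincide|linkpred|run`), e.g.

```sh
gosimnet fixtures --preset default --seed 7 --outdir fixtures/
gosimnet embed --graph go_edges.tsv --method node2vec --dim 128 --p 1 --q 1 \
    --walk-length 80 --num-walks 10 --seed 42 --out vectors.tsv
```

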