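"""Desk-scale synthetic fixtures: ontologies, annotations, and PPI networks.

The generator emulates the three real inputs of the pipeline without any
download: a layered single-root DAG standing in for a GO namespace, a
protein→term annotation map with planted community structure (proteins in
the same community draw their annotations from the same block of leaf
terms), and a planted-partition PPI network whose communities coincide with
the annotation communities.  The shared community assignment is what makes
annotation-derived similarity informative about PPI edges, which is the
signal every downstream stage is tested against.

All generation is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .ontology import AnnotationSet, OntologyGraph, Term, write_obo


@dataclass
class FixtureSpec:
    """Shape and signal parameters of a synthetic fixture.

    Defaults give a 200-term, 100-protein, 2-community fixture small enough
    for a full pipeline run in seconds yet with enough planted structure for
    embeddings and link prediction to recover it.
    """

    n_terms: int = 200
    n_layers: int = 5
    branching: int = 2
    n_proteins: int = 100
    k_min: int = 3
    k_max: int = 8
    n_communities: int = 2
    within_rate: float = 0.9
    ppi_p_in: float = 0.3
    ppi_p_out: float = 0.02
    seed: int = 0
    namespace: str = "biological_process"

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        for rate in (self.within_rate, self.ppi_p_in, self.ppi_p_out):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid annotation-count range")


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def gen_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Single-root layered DAG: each non-root term gets 1–2 parents from the
    layer above.  Acyclic by construction; one namespace.

    Parents are drawn from a small window around the child's relative
    position in its layer, so that id-contiguous terms descend from shared
    ancestors — mirroring how semantically related GO terms cluster under
    common parents.  This locality is what lets graph embeddings (not just
    exact term overlap) see the annotation communities planted on
    contiguous leaf blocks.
    """
    rng = np.random.default_rng(spec.seed)
    # allocate terms to layers: root alone, remaining terms spread with
    # geometric growth controlled by branching
    weights = np.array([float(spec.branching) ** i for i in range(1, spec.n_layers)])
    remaining = spec.n_terms - 1
    sizes = np.maximum(1, np.round(remaining * weights / weights.sum()).astype(int))
    while sizes.sum() > remaining:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < remaining:
        sizes[np.argmax(weights)] += 1
    layers: list[list[str]] = [[_term_id(0)]]
    next_id = 1
    for size in sizes:
        layers.append([_term_id(next_id + j) for j in range(size)])
        next_id += size

    onto = OntologyGraph()
    for layer in layers:
        for tid in layer:
            onto.terms[tid] = Term(id=tid, namespace=spec.namespace, name=f"synthetic term {tid}")
    for li in range(1, len(layers)):
        above = layers[li - 1]
        layer = layers[li]
        for pos, tid in enumerate(layer):
            n_parents = 1 if len(above) == 1 else int(rng.integers(1, 3))
            n_parents = min(n_parents, len(above))
            # window of candidate parents centered at the child's relative position
            center = int(pos / len(layer) * len(above))
            window = [
                (center + off) % len(above) for off in range(-1, 2)
            ]
            window = sorted(set(window))
            parents = rng.choice(len(window), size=min(n_parents, len(window)), replace=False)
            for p in parents:
                onto.relations.add((tid, above[window[p]], "is_a"))
    return onto


def leaf_terms(ontology: OntologyGraph) -> list[str]:
    """Terms with no children (no incoming child→parent relation)."""
    parents = {parent for _, parent, _ in ontology.relations}
    return sorted(t for t in ontology.terms if t not in parents)


def community_assignment(spec: FixtureSpec) -> dict[str, int]:
    """Protein id → community index, proteins split as evenly as possible."""
    return {
        f"PROT{i + 1:04d}": i % spec.n_communities for i in range(spec.n_proteins)
    }


def gen_annotations(
    spec: FixtureSpec, ontology: OntologyGraph
) -> tuple[AnnotationSet, dict[str, int]]:
    """Community-structured annotations anchored to disjoint leaf-term blocks.

    Each community owns an equal, disjoint block of leaf terms.  A protein
    draws k ∈ [k_min, k_max] distinct terms, each from its own block with
    probability ``within_rate`` and uniformly from all leaves otherwise, so
    annotation-set overlap is higher within communities than between.
    """
    rng = np.random.default_rng(spec.seed + 1)
    leaves = leaf_terms(ontology)
    block_size = len(leaves) // spec.n_communities
    if block_size < spec.k_max:
        raise ValueError(
            f"leaf block size {block_size} smaller than k_max={spec.k_max}; "
            "grow the ontology or shrink the annotation range"
        )
    blocks = [
        leaves[c * block_size : (c + 1) * block_size] for c in range(spec.n_communities)
    ]
    communities = community_assignment(spec)
    annotations: dict[str, frozenset[str]] = {}
    for protein, comm in communities.items():
        k = int(rng.integers(spec.k_min, spec.k_max + 1))
        chosen: set[str] = set()
        while len(chosen) < k:
            if rng.random() < spec.within_rate:
                pool = blocks[comm]
            else:
                pool = leaves
            chosen.add(pool[int(rng.integers(len(pool)))])
        annotations[protein] = frozenset(chosen)
    return AnnotationSet(annotations=annotations), communities


def gen_ppi(spec: FixtureSpec, communities: dict[str, int]) -> nx.Graph:
    """Planted-partition PPI: edge probability p_in within a community,
    p_out between.  Warns (via graph attribute) when the fixture is
    signal-free (p_out >= p_in)."""
    rng = np.random.default_rng(spec.seed + 2)
    proteins = sorted(communities)
    g = nx.Graph()
    g.add_nodes_from(proteins)
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            p = spec.ppi_p_in if communities[a] == communities[b] else spec.ppi_p_out
            if rng.random() < p:
                g.add_edge(a, b)
    if spec.ppi_p_out >= spec.ppi_p_in:
        g.graph["warning"] = "p_out >= p_in: planted partition carries no signal"
    return g


def gen_fixture(spec: FixtureSpec):
    """Generate ontology, annotations, community map, and PPI in one call."""
    onto = gen_ontology(spec)
    ann, communities = gen_annotations(spec, onto)
    ppi = gen_ppi(spec, communities)
    return onto, ann, communities, ppi


def write_gaf(annotations: AnnotationSet, path: str | Path, taxon: str = "taxon:0") -> None:
    """Write annotations as a minimal GAF 2.2 file (17 columns)."""
    lines = ["!gaf-version: 2.2"]
    for protein in sorted(annotations.annotations):
        for term in sorted(annotations.annotations[protein]):
            fields = [
                "SYNTH", protein, protein, "involved_in", term, "SYNTH:0000001",
                "IEA", "", "P", "", "", "protein", taxon, "20200101", "SYNTH", "", "",
            ]
            lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write OBO, GAF, PPI edge-list TSV and community TSV under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    onto, ann, communities, ppi = gen_fixture(spec)
    paths = {
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "ppi": outdir / "ppi.tsv",
        "communities": outdir / "communities.tsv",
    }
    write_obo(onto, paths["obo"])
    write_gaf(ann, paths["gaf"])
    with open(paths["ppi"], "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in ppi.edges()):
            fh.write(f"{a}\t{b}\n")
    with open(paths["communities"], "w") as fh:
        for p in sorted(communities):
            fh.write(f"{p}\t{communities[p]}\n")
    return paths
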