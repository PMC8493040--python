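"""Information-content term similarity and Best-Match-Average protein similarity.

The information content of a GO term g is IC(g) = −log p(g), where p(g) is the
fraction of annotated proteins in the corpus annotated by g or any of its
descendants (more specific terms).  Rare, specific terms are informative; the
namespace root has p = 1 and IC = 0.

Two classic pairwise term measures are provided: Jiang–Conrath's distance-like
score 2·IC(g_c) − IC(g1) − IC(g2) (always ≤ 0, 0 at identity of IC) and the
Rel score [2·IC(g_c)/(IC(g1)+IC(g2))]·(1 − p(g_c)), Lin's ratio damped by the
MICA's commonness, in [0, 1).  Here g_c is the most informative common
ancestor (MICA).  Protein pairs are scored with the Best Match Average of
their annotation sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import networkx as nx

from .ontology import AnnotationSet, OntologyGraph


@dataclass
class ICTable:
    """Annotation frequency p and information content per term.

    p(g) = |proteins annotated by g or a descendant| / N, with N the total
    number of annotated proteins.  Terms never used get p = 0 and ic = +inf.
    """

    p: dict[str, float]
    ic: dict[str, float]
    N: int

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term\tp\tic\n")
            for term in sorted(self.p):
                fh.write(f"{term}\t{self.p[term]!r}\t{self.ic[term]!r}\n")


def compute_ic_table(ontology: OntologyGraph, annotations: AnnotationSet) -> ICTable:
    """Descendant-closed annotation frequencies over the directed DAG.

    Protein sets are propagated child→parent in topological order, so each
    term counts proteins annotated by itself or any descendant, then divided
    by N (total annotated proteins).
    """
    if not annotations.annotations:
        raise ValueError("empty annotation set")
    dag = ontology.directed()
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("directed relations contain a cycle")

    direct: dict[str, set[str]] = {t: set() for t in ontology.terms}
    for protein, terms in annotations.annotations.items():
        for term in terms:
            if term in direct:
                direct[term].add(protein)

    # children before parents: edges point child -> parent
    closed: dict[str, set[str]] = {}
    for term in nx.topological_sort(dag):
        s = set(direct[term])
        for child in dag.predecessors(term):
            s |= closed[child]
        closed[term] = s

    N = len(annotations.annotations)
    p = {t: len(s) / N for t, s in closed.items()}
    ic = {t: (-math.log(pt) if pt > 0 else math.inf) for t, pt in p.items()}
    return ICTable(p=p, ic=ic, N=N)


def _ancestor_sets(ontology: OntologyGraph) -> Callable[[str], frozenset[str]]:
    dag = ontology.directed()

    @lru_cache(maxsize=None)
    def ancestors(term: str) -> frozenset[str]:
        return frozenset(nx.descendants(dag, term)) | {term}

    return ancestors


def mica(
    g1: str, g2: str, ontology: OntologyGraph, ic_table: ICTable,
    _ancestors: Callable[[str], frozenset[str]] | None = None,
) -> str | None:
    """Most informative common ancestor of g1 and g2 (a term is its own ancestor).

    Among common ancestors with finite IC, returns the one with maximal IC
    (ties broken by term id for determinism).  Returns None when there is no
    common ancestor — e.g. terms from different namespaces.
    """
    ancestors = _ancestors or _ancestor_sets(ontology)
    common = ancestors(g1) & ancestors(g2)
    common = {t for t in common if math.isfinite(ic_table.ic[t])}
    if not common:
        return None
    return max(sorted(common), key=lambda t: ic_table.ic[t])


def sim_jc(
    g1: str, g2: str, ontology: OntologyGraph, ic_table: ICTable,
    _ancestors=None,
) -> float | None:
    """Jiang–Conrath score 2·IC(g_c) − IC(g1) − IC(g2); ≤ 0, undefined → None."""
    gc = mica(g1, g2, ontology, ic_table, _ancestors=_ancestors)
    if gc is None:
        return None
    ic1, ic2 = ic_table.ic[g1], ic_table.ic[g2]
    if not (math.isfinite(ic1) and math.isfinite(ic2)):
        return None
    return 2.0 * ic_table.ic[gc] - ic1 - ic2


def sim_rel(
    g1: str, g2: str, ontology: OntologyGraph, ic_table: ICTable,
    additive: bool = False, _ancestors=None,
) -> float | None:
    """Rel score: Lin's ratio times (1 − p(g_c)), in [0, 1).

    ``additive=True`` switches to adding (1 − p(g_c)) instead of multiplying.
    Both terms being roots (IC sum 0) gives 0 by convention.
    """
    gc = mica(g1, g2, ontology, ic_table, _ancestors=_ancestors)
    if gc is None:
        return None
    ic1, ic2 = ic_table.ic[g1], ic_table.ic[g2]
    if not (math.isfinite(ic1) and math.isfinite(ic2)):
        return None
    denom = ic1 + ic2
    if denom == 0.0:
        return 0.0
    lin = 2.0 * ic_table.ic[gc] / denom
    rarity = 1.0 - ic_table.p[gc]
    return lin + rarity if additive else lin * rarity


def bma(
    pm: str,
    pn: str,
    annotations: AnnotationSet,
    termsim: Callable[[str, str], float | None],
) -> float | None:
    """Best Match Average of two proteins' annotation sets.

    ½[(1/|G_m|) Σ_{g∈G_m} max_{g'∈G_n} sim(g,g') +
      (1/|G_n|) Σ_{g'∈G_n} max_{g∈G_m} sim(g,g')], with undefined term pairs
    skipped inside each max.  Returns None when every pair is undefined.
    """
    gm = sorted(annotations.annotations[pm])
    gn = sorted(annotations.annotations[pn])
    sims: dict[tuple[str, str], float | None] = {}
    for a in gm:
        for b in gn:
            sims[(a, b)] = termsim(a, b)

    def side(rows: list[str], cols: list[str], flip: bool) -> float | None:
        total, used = 0.0, 0
        for g in rows:
            vals = [
                sims[(g, h)] if not flip else sims[(h, g)]
                for h in cols
            ]
            vals = [v for v in vals if v is not None]
            if vals:
                total += max(vals)
                used += 1
        if used == 0:
            return None
        return total / len(rows)

    left = side(gm, gn, flip=False)
    right = side(gn, gm, flip=True)
    if left is None or right is None:
        return None
    return 0.5 * (left + right)


def make_termsim(
    ontology: OntologyGraph, ic_table: ICTable, method: str = "rel", **kw
) -> Callable[[str, str], float | None]:
    """Build a cached pairwise term-similarity function ('jc' or 'rel')."""
    ancestors = _ancestor_sets(ontology)
    base = {"jc": sim_jc, "rel": sim_rel}[method]
    cache: dict[tuple[str, str], float | None] = {}

    def fn(a: str, b: str) -> float | None:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = base(key[0], key[1], ontology, ic_table, _ancestors=ancestors, **kw)
        return cache[key]

    return fn
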