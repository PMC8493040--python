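"""Parsing of GO ontologies (OBO) and annotations (GAF), and graph construction.

The Gene Ontology is a DAG of terms in three namespaces (biological_process,
cellular_component, molecular_function) connected by typed relations (is_a,
part_of, regulates, ...).  For embedding purposes the DAG is flattened into an
undirected, unweighted *GO graph* — every relation becomes a plain edge
regardless of type and direction.  Combining the term–term edges with
term–protein annotation edges yields the heterogeneous *GOA graph*, whose
random walks mix terms and proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
from Bio.UniProt.GOA import GAF20FIELDS

logger = logging.getLogger(__name__)

NAMESPACES = frozenset(
    {"biological_process", "cellular_component", "molecular_function"}
)


@dataclass(frozen=True)
class Term:
    """A single non-obsolete GO term."""

    id: str
    namespace: str
    name: str = ""
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """Parsed GO DAG: typed terms plus typed child→parent relations.

    ``relations`` holds ``(child_id, parent_id, relation_type)`` triples,
    e.g. ``("GO:3", "GO:1", "is_a")``.  Only non-obsolete terms are kept, so
    no relation can touch an obsolete term.
    """

    terms: dict[str, Term] = field(default_factory=dict)
    relations: set[tuple[str, str, str]] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def canonical(self, term_id: str) -> str:
        """Map an alt_id accession to its canonical term id (identity otherwise)."""
        return self.alt_ids.get(term_id, term_id)

    def directed(self, relation_types: set[str] | None = None) -> nx.DiGraph:
        """Child→parent DiGraph over the selected relation types (default all)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent, rel in self.relations:
            if relation_types is None or rel in relation_types:
                g.add_edge(child, parent)
        return g

    def validate(self) -> None:
        for child, parent, rel in self.relations:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"relation ({child},{parent},{rel}) has unknown endpoint")


@dataclass
class AnnotationSet:
    """Protein → set of GO term ids, with optional evidence codes.

    ``dropped`` counts annotation rows whose term was absent from the
    companion ontology.
    """

    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)
    dropped: int = 0

    @property
    def proteins(self) -> list[str]:
        return sorted(self.annotations)

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.annotations[protein]


def parse_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are excluded; ``is_a`` and every ``relationship:`` line
    become typed relations; ``alt_id`` accessions map to their canonical id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # obonet skips obsolete stanzas and stanzas without an id by default
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    onto = OntologyGraph()
    for node, data in multigraph.nodes(data=True):
        onto.terms[node] = Term(
            id=node,
            namespace=data.get("namespace", ""),
            name=data.get("name", ""),
        )
        for alt in data.get("alt_id", []):
            onto.alt_ids[alt] = node
    for child, parent, rel in multigraph.edges(keys=True):
        if parent in onto.terms:
            onto.relations.add((child, parent, rel))
    logger.info(
        "parsed %s: %d terms, %d relations", path.name, len(onto.terms), len(onto.relations)
    )
    return onto


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    """Write an OBO-dialect flat file that :func:`parse_obo` round-trips."""
    lines = ["format-version: 1.2", ""]
    outgoing: dict[str, list[tuple[str, str]]] = {t: [] for t in ontology.terms}
    for child, parent, rel in sorted(ontology.relations):
        outgoing[child].append((parent, rel))
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        if term.name:
            lines.append(f"name: {term.name}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        for alt, canonical in sorted(ontology.alt_ids.items()):
            if canonical == tid:
                lines.append(f"alt_id: {alt}")
        for parent, rel in outgoing[tid]:
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def parse_gaf(
    path: str | Path,
    ontology: OntologyGraph,
    include_evidence: set[str] | None = None,
    exclude_evidence: set[str] | None = None,
) -> AnnotationSet:
    """Read a GAF 2.x file, keeping only terms present in *ontology*.

    Column 2 (DB Object ID) is the protein identifier and column 5 the GO id;
    alt_ids are mapped to canonical ids.  Evidence codes are not filtered
    unless an include/exclude list is given.  Rows citing unknown terms are
    dropped and counted; rows with fewer than 15 columns are skipped with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    col = {name: i for i, name in enumerate(GAF20FIELDS)}
    ann: dict[str, set[str]] = {}
    evidence: dict[tuple[str, str], str] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15:
                logger.warning("%s:%d: %d columns (<15), skipped", path.name, lineno, len(fields))
                continue
            protein = fields[col["DB_Object_ID"]]
            go_id = ontology.canonical(fields[col["GO_ID"]])
            code = fields[col["Evidence"]]
            if include_evidence is not None and code not in include_evidence:
                continue
            if exclude_evidence is not None and code in exclude_evidence:
                continue
            if go_id not in ontology.terms:
                dropped += 1
                continue
            ann.setdefault(protein, set()).add(go_id)
            evidence[(protein, go_id)] = code
    if not ann:
        raise ValueError(f"{path}: no usable annotation rows")
    result = AnnotationSet(
        annotations={p: frozenset(ts) for p, ts in ann.items()},
        evidence=evidence,
        dropped=dropped,
    )
    logger.info(
        "parsed %s: %d proteins, %d (protein,term) pairs, %d rows dropped",
        path.name,
        len(result.annotations),
        sum(len(t) for t in result.annotations.values()),
        dropped,
    )
    return result


def build_go_graph(
    ontology: OntologyGraph,
    namespaces: set[str] | None = None,
    relation_types: set[str] | None = None,
) -> nx.Graph:
    """Flatten the DAG into the undirected, unweighted GO graph.

    Every relation becomes one edge regardless of its type and direction;
    parallel relations between the same pair collapse.  All three namespaces
    are merged by default.
    """
    if not ontology.terms:
        raise ValueError("empty ontology")
    if namespaces is not None:
        unknown = namespaces - NAMESPACES
        if unknown:
            raise ValueError(f"unknown namespaces: {sorted(unknown)}")
        if not namespaces:
            raise ValueError("empty namespace selection")
    keep = {
        t
        for t, term in ontology.terms.items()
        if namespaces is None or term.namespace in namespaces
    }
    g = nx.Graph()
    g.add_nodes_from(keep, kind="term")
    for child, parent, rel in ontology.relations:
        if relation_types is not None and rel not in relation_types:
            continue
        if child in keep and parent in keep and child != parent:
            g.add_edge(child, parent)
    return g


def build_goa_graph(ontology: OntologyGraph, annotations: AnnotationSet) -> nx.Graph:
    """Combine flattened term–term edges with term–protein annotation edges.

    Protein and term id spaces must be disjoint.
    """
    g = build_go_graph(ontology)
    collisions = set(annotations.annotations) & set(ontology.terms)
    if collisions:
        raise ValueError(f"protein ids collide with GO accessions: {sorted(collisions)[:5]}")
    for protein, terms in annotations.annotations.items():
        g.add_node(protein, kind="protein")
        for term in terms:
            if term in ontology.terms:
                g.add_edge(protein, term)
    return g


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as 2-column TSV of sorted unordered pairs."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read a 2-column TSV edge list into an undirected graph."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, *_ = line.split("\t")
            g.add_edge(a, b)
    return g
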