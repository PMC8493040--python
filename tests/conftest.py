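import numpy as np
import networkx as nx
import pytest

from gosimnet.ontology import AnnotationSet, OntologyGraph, Term


def make_chain_ontology() -> OntologyGraph:
    """C is_a B is_a A, one namespace."""
    onto = OntologyGraph()
    for tid, name in [("GO:0000001", "A"), ("GO:0000002", "B"), ("GO:0000003", "C")]:
        onto.terms[tid] = Term(id=tid, namespace="molecular_function", name=name)
    onto.relations = {
        ("GO:0000002", "GO:0000001", "is_a"),
        ("GO:0000003", "GO:0000002", "is_a"),
    }
    return onto


@pytest.fixture
def chain_ontology():
    return make_chain_ontology()


@pytest.fixture
def chain_annotations():
    """Frequencies p(A)=1, p(B)=1/2, p(C)=1/4 over N=4 proteins."""
    return AnnotationSet(
        annotations={
            "P1": frozenset({"GO:0000003"}),
            "P2": frozenset({"GO:0000002"}),
            "P3": frozenset({"GO:0000001"}),
            "P4": frozenset({"GO:0000001"}),
        }
    )


@pytest.fixture
def hand_check_graph():
    """The 4-node graph {a-b, a-c, b-c, c-d} used for index hand checks."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])
    return g


def planted_two_community_graph(n=60, p_in=0.3, p_out=0.02, seed=0):
    """Planted 2-community graph with string node ids and a community map."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n)]
    comm = {v: int(i >= n // 2) for i, v in enumerate(nodes)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            p = p_in if comm[a] == comm[b] else p_out
            if rng.random() < p:
                g.add_edge(a, b)
    return g, comm


def mean_cosine_separation(embedding, communities):
    """Mean within-community cosine minus mean between-community cosine."""
    import itertools

    from gosimnet.protein_sim import cosine_similarity

    within, between = [], []
    for a, b in itertools.combinations(sorted(embedding.vectors), 2):
        s = cosine_similarity(embedding.vectors[a], embedding.vectors[b])
        if s is None:
            continue
        (within if communities[a] == communities[b] else between).append(s)
    return float(np.mean(within) - np.mean(between))
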