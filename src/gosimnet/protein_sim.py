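"""Protein–protein similarity from embeddings, and screened similarity networks.

Two routes are supported.  In the GO-graph route each protein is represented
by the ordered set of embedding vectors of its annotating terms, and two
proteins are compared with dynamic time warping (DTW) over those vector
sequences — the smaller the warped distance, the more similar the proteins.
In the GOA-graph route each protein has its own embedding vector ω and pairs
are compared with plain cosine similarity.

DTW recurrence (diagonal steps pay the local distance twice):

    D(i,j) = min( D(i−1,j) + d(i,j),
                  D(i,j−1) + d(i,j),
                  D(i−1,j−1) + 2·d(i,j) )

with D(1,1) = d(1,1) and cumulative-sum boundaries.  Raw DTW distances are
mapped to a similarity in (0, 1] via s = 1/(1 + D/(m+n)) so that threshold
(τ) and percentile-band screening apply uniformly to both routes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .embeddings import EmbeddingMap
from .ontology import AnnotationSet

logger = logging.getLogger(__name__)

LOCAL_METRICS = {"euclidean", "cosine"}


def vector_set(protein: str, annotations: AnnotationSet, embeddings: EmbeddingMap) -> np.ndarray | None:
    """Stack the term vectors annotating *protein*, rows in lexicographic term order.

    Returns None (undefined) when no annotating term has an embedding.
    """
    terms = [t for t in sorted(annotations.annotations[protein]) if t in embeddings]
    if not terms:
        return None
    return embeddings.matrix(terms)


def _local_distances(vm: np.ndarray, vn: np.ndarray, metric: str) -> np.ndarray:
    if metric not in LOCAL_METRICS:
        raise ValueError(f"unknown local metric {metric!r}")
    return cdist(vm, vn, metric=metric)


def dtw_distance(vm: np.ndarray, vn: np.ndarray, metric: str = "euclidean") -> float:
    """Minimum cumulative warping cost between two vector sequences.

    Vertical/horizontal steps add the local distance once, diagonal steps
    twice.  O(m·n·d).
    """
    vm = np.atleast_2d(np.asarray(vm, dtype=float))
    vn = np.atleast_2d(np.asarray(vn, dtype=float))
    if vm.size == 0 or vn.size == 0:
        raise ValueError("empty vector set")
    if vm.shape[1] != vn.shape[1]:
        raise ValueError(f"dimension mismatch: {vm.shape[1]} vs {vn.shape[1]}")
    local = _local_distances(vm, vn, metric)
    m, n = local.shape
    D = np.empty((m, n))
    D[0, 0] = local[0, 0]
    for j in range(1, n):
        D[0, j] = D[0, j - 1] + local[0, j]
    for i in range(1, m):
        D[i, 0] = D[i - 1, 0] + local[i, 0]
        for j in range(1, n):
            D[i, j] = min(
                D[i - 1, j] + local[i, j],
                D[i, j - 1] + local[i, j],
                D[i - 1, j - 1] + 2.0 * local[i, j],
            )
    return float(D[m - 1, n - 1])


def normalized_dtw_similarity(vm: np.ndarray, vn: np.ndarray, metric: str = "euclidean") -> float:
    """Map DTW distance to (0, 1]: s = 1/(1 + D/(m+n)).

    Dividing by m+n removes the bias of longer annotation lists; s = 1 iff
    the warped distance is 0.
    """
    m = np.atleast_2d(vm).shape[0]
    n = np.atleast_2d(vn).shape[0]
    d = dtw_distance(vm, vn, metric=metric)
    return 1.0 / (1.0 + d / (m + n))


def cosine_similarity(wm: np.ndarray, wn: np.ndarray) -> float | None:
    """Cosine of the angle between two protein vectors; None for a zero vector."""
    wm = np.asarray(wm, dtype=float)
    wn = np.asarray(wn, dtype=float)
    nm, nn = np.linalg.norm(wm), np.linalg.norm(wn)
    if nm == 0.0 or nn == 0.0:
        return None
    return float(np.dot(wm, wn) / (nm * nn))


@dataclass
class ScoreTable:
    """Symmetric protein-pair score table plus the list of undefined pairs."""

    scores: pd.DataFrame
    undefined: list[tuple[str, str]]
    mode: str

    def pairs(self) -> list[tuple[str, str, float]]:
        """Defined unordered pairs (a < b) with their scores."""
        prots = list(self.scores.index)
        undef = set(self.undefined)
        out = []
        for a, b in itertools.combinations(prots, 2):
            key = (a, b) if a < b else (b, a)
            if key in undef:
                continue
            val = self.scores.at[a, b]
            if np.isnan(val):
                continue
            out.append((key[0], key[1], float(val)))
        return out

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\tscore\n")
            for a, b, s in sorted(self.pairs()):
                fh.write(f"{a}\t{b}\t{s!r}\n")


def similarity_matrix(
    proteins: list[str],
    mode: str,
    embeddings: EmbeddingMap,
    annotations: AnnotationSet | None = None,
    metric: str = "euclidean",
) -> ScoreTable:
    """Score all C(n,2) protein pairs.

    ``mode="go_dtw"`` uses normalized DTW over annotating-term vector sets
    (requires annotations + term embeddings); ``mode="goa_cosine"`` uses
    cosine over protein vectors.  Pairs that cannot be scored (no embedded
    terms, missing or zero protein vector) are recorded as undefined.
    """
    proteins = sorted(proteins)
    n = len(proteins)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    undefined: list[tuple[str, str]] = []

    if mode == "go_dtw":
        if annotations is None:
            raise ValueError("go_dtw mode requires annotations")
        vsets = {p: vector_set(p, annotations, embeddings) for p in proteins}
        for i, a in enumerate(proteins):
            for j in range(i + 1, n):
                b = proteins[j]
                if vsets[a] is None or vsets[b] is None:
                    undefined.append((a, b))
                    continue
                mat[i, j] = mat[j, i] = normalized_dtw_similarity(vsets[a], vsets[b], metric)
    elif mode == "goa_cosine":
        for i, a in enumerate(proteins):
            for j in range(i + 1, n):
                b = proteins[j]
                if a not in embeddings or b not in embeddings:
                    undefined.append((a, b))
                    continue
                s = cosine_similarity(embeddings[a], embeddings[b])
                if s is None:
                    undefined.append((a, b))
                else:
                    mat[i, j] = mat[j, i] = s
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if undefined:
        logger.info("%d undefined pairs in %s scoring", len(undefined), mode)
    df = pd.DataFrame(mat, index=proteins, columns=proteins)
    return ScoreTable(scores=df, undefined=undefined, mode=mode)


def ic_score_table(
    proteins: list[str],
    annotations: AnnotationSet,
    termsim,
    mode: str = "ic",
) -> ScoreTable:
    """All-pairs Best-Match-Average scores for an IC-based term similarity."""
    from .term_ic import bma

    proteins = sorted(proteins)
    n = len(proteins)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    undefined: list[tuple[str, str]] = []
    for i, a in enumerate(proteins):
        for j in range(i + 1, n):
            b = proteins[j]
            s = bma(a, b, annotations, termsim)
            if s is None:
                undefined.append((a, b))
            else:
                mat[i, j] = mat[j, i] = s
    df = pd.DataFrame(mat, index=proteins, columns=proteins)
    return ScoreTable(scores=df, undefined=undefined, mode=mode)


def _ranked_pairs(table: ScoreTable) -> list[tuple[str, str, float]]:
    # stable ordering: score descending, then pair id ascending
    return sorted(table.pairs(), key=lambda t: (-t[2], t[0], t[1]))


def screen_network(
    table: ScoreTable,
    tau: float | None = None,
    band: str | tuple[float, float] | None = None,
    band_frac: float = 0.05,
) -> nx.Graph:
    """Keep protein pairs by similarity threshold or rank band.

    ``tau``: keep pairs with score strictly above τ.  ``band``: one of
    "top" (first ``band_frac`` of ranks, score descending), "middle"
    (band of the same width centered at the median rank), "last" (final
    ranks), or an explicit (lo, hi) rank-fraction interval.  Undefined pairs
    never enter the ranking denominator.  Self-pairs never become edges.
    """
    if (tau is None) == (band is None):
        raise ValueError("specify exactly one of tau or band")
    ranked = _ranked_pairs(table)
    if not ranked:
        raise ValueError("no defined pairs to screen")
    g = nx.Graph()
    g.add_nodes_from(table.scores.index)
    if tau is not None:
        kept = [(a, b, s) for a, b, s in ranked if s > tau]
        rule = f"tau>{tau}"
    else:
        npairs = len(ranked)
        width = int(round(band_frac * npairs))
        if isinstance(band, tuple):
            lo = int(round(band[0] * npairs))
            hi = int(round(band[1] * npairs))
        elif band == "top":
            lo, hi = 0, width
        elif band == "last":
            lo, hi = npairs - width, npairs
        elif band == "middle":
            mid = npairs // 2
            lo, hi = mid - width // 2, mid - width // 2 + width
        else:
            raise ValueError(f"unknown band {band!r}")
        if hi - lo > npairs or lo < 0 or hi > npairs:
            raise ValueError(f"band [{lo},{hi}) wider than the {npairs} available pairs")
        kept = ranked[lo:hi]
        rule = f"band:{band}:{band_frac}"
    for a, b, s in kept:
        g.add_edge(a, b, weight=s)
    g.graph["provenance"] = f"{table.mode}|{rule}"
    return g


def coincidence_degree(ea, eb) -> float:
    """|Ea ∩ Eb| normalized by the larger edge set, in [0, 1].

    Edge sets may be networkx graphs or iterables of pairs; pairs are
    canonicalized as unordered.
    """
    def canon(edges):
        if isinstance(edges, nx.Graph):
            edges = edges.edges()
        return {tuple(sorted(e)) for e in edges}

    sa, sb = canon(ea), canon(eb)
    if not sa or not sb:
        raise ValueError("empty edge set")
    return len(sa & sb) / max(len(sa), len(sb))
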