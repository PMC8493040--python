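"""Link-prediction evaluation of similarity networks.

The protocol: remove 20% of the network's edges (E_r, discarded entirely),
split the remaining 80% (E_s) into a training set E_p and a probe set E_t,
score every candidate pair (probes plus non-edges) with a structural index
computed on the training graph only, and ask how well probes outrank
non-edges.

Structural indexes over training-graph neighborhoods Γ(·):

    CN(x,y) = |Γ(x) ∩ Γ(y)|
    JC(x,y) = |Γ(x) ∩ Γ(y)| / |Γ(x) ∪ Γ(y)|
    RA(x,y) = Σ_{z ∈ Γ(x) ∩ Γ(y)} 1 / K_z

AUC is the exact tie-corrected rank statistic (probability a random probe
outscores a random non-edge, ties ½); AUCPR is the trapezoidal area under
the precision–recall curve, with precision@L = m/L and recall@L = m/|E_t|
for m probes among the top-L ranked pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class EdgeSplit:
    """The (E_r, E_p, E_t) partition of a network's edges."""

    e_r: set[Edge]
    e_p: set[Edge]
    e_t: set[Edge]
    seed: int

    @property
    def e_s(self) -> set[Edge]:
        return self.e_p | self.e_t


@dataclass
class EvalResult:
    auc: float
    aucpr: float
    precision_at: dict[int, float] = field(default_factory=dict)
    recall_at: dict[int, float] = field(default_factory=dict)
    auc_std: float | None = None
    aucpr_std: float | None = None

    def to_dict(self) -> dict:
        out = {"auc": self.auc, "aucpr": self.aucpr,
               "precision_at": self.precision_at, "recall_at": self.recall_at}
        if self.auc_std is not None:
            out["auc_std"] = self.auc_std
            out["aucpr_std"] = self.aucpr_std
        return out


def _canon(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def split_edges(
    graph: nx.Graph,
    remove_frac: float = 0.2,
    probe_frac: float = 0.2,
    seed: int = 0,
) -> EdgeSplit:
    """Uniformly partition edges into removed (E_r), training (E_p), probe (E_t).

    |E_r| = round(remove_frac·|E|); of the remainder E_s,
    |E_t| = round(probe_frac·|E_s|).  Deterministic under seed.
    """
    if not 0 < remove_frac < 1 or not 0 < probe_frac < 1:
        raise ValueError("fractions must lie in (0, 1)")
    edges = sorted(_canon(a, b) for a, b in graph.edges())
    n = len(edges)
    if n < 10:
        raise ValueError(f"network has only {n} edges; need >= 10 to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_r = int(round(remove_frac * n))
    n_t = int(round(probe_frac * (n - n_r)))
    if n_r == 0 or n_t == 0 or n - n_r - n_t == 0:
        raise ValueError("empty partition under the given fractions")
    e_r = {edges[i] for i in perm[:n_r]}
    e_t = {edges[i] for i in perm[n_r : n_r + n_t]}
    e_p = {edges[i] for i in perm[n_r + n_t :]}
    return EdgeSplit(e_r=e_r, e_p=e_p, e_t=e_t, seed=seed)


# ---------------------------------------------------------------------------
# Structural indexes (training graph only)


def cn_index(graph: nx.Graph, x: str, y: str) -> int:
    """Number of common neighbors of x and y."""
    if x not in graph or y not in graph:
        raise KeyError(f"unknown node in pair ({x}, {y})")
    return len(set(graph[x]) & set(graph[y]))


def jc_index(graph: nx.Graph, x: str, y: str) -> float:
    """Jaccard ratio of the two neighborhoods; 0 when both are empty."""
    if x not in graph or y not in graph:
        raise KeyError(f"unknown node in pair ({x}, {y})")
    nx_, ny_ = set(graph[x]), set(graph[y])
    union = nx_ | ny_
    if not union:
        return 0.0
    return len(nx_ & ny_) / len(union)


def ra_index(graph: nx.Graph, x: str, y: str) -> float:
    """Resource-allocation index: sum of reciprocal degrees of common neighbors."""
    if x not in graph or y not in graph:
        raise KeyError(f"unknown node in pair ({x}, {y})")
    return sum(1.0 / graph.degree(z) for z in set(graph[x]) & set(graph[y]))


INDEXES = {"cn": cn_index, "jc": jc_index, "ra": ra_index}


# ---------------------------------------------------------------------------
# Scoring and metrics


@dataclass
class ScoredPairs:
    """Candidate pairs with index scores and probe/non-edge labels."""

    pairs: list[Edge]
    scores: np.ndarray
    labels: np.ndarray  # True = probe, False = non-edge


def score_candidates(
    train: nx.Graph,
    split: EdgeSplit,
    index: str,
    seed: int = 0,
    exhaustive_limit: int = 2000,
    neg_ratio: int = 10,
) -> ScoredPairs:
    """Score probe edges and non-edges with a structural index on E_p.

    Removed edges (E_r) are excluded entirely — neither probes nor non-edges.
    Non-edges are exhaustive up to ``exhaustive_limit`` nodes, otherwise a
    uniform sample of ``neg_ratio``·|E_t| under seed.
    """
    fn = INDEXES[index]
    nodes = sorted(train.nodes())
    known = split.e_r | split.e_p | split.e_t
    probes = sorted(split.e_t)

    if len(nodes) <= exhaustive_limit:
        non_edges = [
            p for p in itertools.combinations(nodes, 2) if _canon(*p) not in known
        ]
    else:
        rng = np.random.default_rng(seed)
        want = neg_ratio * len(probes)
        seen: set[Edge] = set()
        non_edges = []
        while len(non_edges) < want:
            i, j = rng.integers(len(nodes), size=2)
            if i == j:
                continue
            e = _canon(nodes[i], nodes[j])
            if e in known or e in seen:
                continue
            seen.add(e)
            non_edges.append(e)

    pairs = probes + non_edges
    labels = np.zeros(len(pairs), dtype=bool)
    labels[: len(probes)] = True
    scores = np.array([fn(train, a, b) for a, b in pairs], dtype=float)
    return ScoredPairs(pairs=pairs, scores=scores, labels=labels)


def auc(scored: ScoredPairs) -> float:
    """Exact rank-based AUC: P(probe outscores non-edge), ties counting ½."""
    pos = scored.labels.sum()
    neg = len(scored.labels) - pos
    if pos == 0 or neg == 0:
        raise ValueError("need at least one probe and one non-edge")
    ranks = rankdata(scored.scores)
    u = ranks[scored.labels].sum() - pos * (pos + 1) / 2.0
    return float(u / (pos * neg))


def auc_sampled(scored: ScoredPairs, n_samples: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo AUC estimator: (wins + 0.5·ties)/n over random comparisons."""
    rng = np.random.default_rng(seed)
    pos_scores = scored.scores[scored.labels]
    neg_scores = scored.scores[~scored.labels]
    ps = pos_scores[rng.integers(len(pos_scores), size=n_samples)]
    ns = neg_scores[rng.integers(len(neg_scores), size=n_samples)]
    return float(((ps > ns).sum() + 0.5 * (ps == ns).sum()) / n_samples)


def precision_recall_curve(
    scored: ScoredPairs,
    recall_denominator: str = "probes",
    m_removed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision/recall at every cutoff L, plus trapezoidal AUCPR.

    Pairs are ranked by score descending with stable tie-break on pair id.
    precision@L = m/L and recall@L = m/M with M = |E_t| (probes) by default;
    ``recall_denominator="removed-complement"`` uses M = |E| − |E_r| instead
    (requires ``m_removed`` = |E_p| + |E_t|).
    """
    order = sorted(
        range(len(scored.pairs)),
        key=lambda i: (-scored.scores[i], scored.pairs[i]),
    )
    hits = np.cumsum(scored.labels[order])
    L = np.arange(1, len(order) + 1)
    if recall_denominator == "probes":
        M = int(scored.labels.sum())
    elif recall_denominator == "removed-complement":
        if m_removed is None:
            raise ValueError("m_removed required for the removed-complement denominator")
        M = m_removed
    else:
        raise ValueError(f"unknown recall denominator {recall_denominator!r}")
    if M == 0:
        raise ValueError("recall denominator M = 0")
    precision = hits / L
    recall = hits / M
    # anchor the curve at recall 0 with the initial precision before integrating
    aucpr = float(
        np.trapezoid(np.concatenate([[precision[0]], precision]), np.concatenate([[0.0], recall]))
    )
    return precision, recall, aucpr


def evaluate_split(
    network: nx.Graph,
    index: str,
    remove_frac: float = 0.2,
    probe_frac: float = 0.2,
    seed: int = 0,
    precision_cutoffs: tuple[int, ...] = (10, 50, 100),
) -> EvalResult:
    """One split → score → AUC/AUCPR/precision@L evaluation."""
    split = split_edges(network, remove_frac, probe_frac, seed)
    train = nx.Graph()
    train.add_nodes_from(network.nodes())
    train.add_edges_from(split.e_p)
    scored = score_candidates(train, split, index, seed=seed)
    a = auc(scored)
    precision, recall, aucpr = precision_recall_curve(scored)
    p_at, r_at = {}, {}
    for L in precision_cutoffs:
        if L <= len(precision):
            p_at[L] = float(precision[L - 1])
            r_at[L] = float(recall[L - 1])
    return EvalResult(auc=a, aucpr=aucpr, precision_at=p_at, recall_at=r_at)


def run_experiment(
    network: nx.Graph,
    index: str,
    remove_frac: float = 0.2,
    probe_frac: float = 0.2,
    seed: int = 0,
    repeats: int = 10,
) -> EvalResult:
    """Repeat the split/score/evaluate cycle and report mean ± std."""
    if index not in INDEXES:
        raise ValueError(f"unknown index {index!r}")
    aucs, aucprs = [], []
    last = None
    for r in range(repeats):
        last = evaluate_split(network, index, remove_frac, probe_frac, seed=seed + r)
        aucs.append(last.auc)
        aucprs.append(last.aucpr)
    return EvalResult(
        auc=float(np.mean(aucs)),
        aucpr=float(np.mean(aucprs)),
        precision_at=last.precision_at,
        recall_at=last.recall_at,
        auc_std=float(np.std(aucs)),
        aucpr_std=float(np.std(aucprs)),
    )
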