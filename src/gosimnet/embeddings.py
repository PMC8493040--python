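"""Graph-embedding methods: DeepWalk, Node2vec, LINE and SDNE.

All four learn a fixed-dimension real vector per node of an undirected,
unweighted graph.  DeepWalk and Node2vec sample truncated random walks
(uniform, or biased by the return parameter p and in-out parameter q) and feed
them to a skip-gram model with negative sampling; DeepWalk is exactly the
p = q = 1 special case and shares the code path.  LINE optimizes edge-wise
first- and/or second-order proximity objectives with negative sampling.  SDNE
trains an adjacency-row autoencoder whose bottleneck is the embedding, with a
Laplacian first-order penalty tying neighbors together.

Everything is implemented with seeded numpy and is bitwise-reproducible for a
fixed seed on a given machine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class WalkParams:
    """Random-walk hyperparameters.

    p > 1 discourages returning to the previous node; q < 1 favors outward
    (DFS-like) moves, q > 1 inward (BFS-like) moves.  p = q = 1 is the
    uniform DeepWalk walk.
    """

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    num_walks: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 1 or self.num_walks < 1:
            raise ValueError("walk_length and num_walks must be >= 1")


@dataclass
class WalkCorpus:
    walks: list[list[str]]
    walk_length: int
    num_walks: int

    def __len__(self) -> int:
        return len(self.walks)


@dataclass
class EmbeddingMap:
    """Node id → d-dimensional vector, tagged with the producing method."""

    vectors: dict[str, np.ndarray]
    d: int
    method: str
    isolated: set[str] = field(default_factory=set)

    def __getitem__(self, node: str) -> np.ndarray:
        return self.vectors[node]

    def __contains__(self, node: str) -> bool:
        return node in self.vectors

    def matrix(self, nodes: list[str]) -> np.ndarray:
        return np.stack([self.vectors[n] for n in nodes])

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for node in sorted(self.vectors):
                vals = "\t".join(repr(float(x)) for x in self.vectors[node])
                fh.write(f"{node}\t{vals}\n")

    def save_word2vec(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.d}\n")
            for node in sorted(self.vectors):
                vals = " ".join(repr(float(x)) for x in self.vectors[node])
                fh.write(f"{node} {vals}\n")

    @classmethod
    def load_tsv(cls, path: str | Path, method: str = "loaded") -> "EmbeddingMap":
        vectors = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        d = len(next(iter(vectors.values())))
        return cls(vectors=vectors, d=d, method=method)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


# ---------------------------------------------------------------------------
# Random walks


def node2vec_transition(
    graph: nx.Graph, prev: str | None, curr: str, params: WalkParams
) -> dict[str, float]:
    """Second-order transition distribution over the neighbors of *curr*.

    Unnormalized weight for a neighbor x: 1/p if x is the previous node,
    1 if x is adjacent to the previous node, 1/q otherwise.  With no previous
    node (first step) the distribution is uniform.  Returns an empty dict for
    an isolated node (the walk terminates).
    """
    neighbors = sorted(graph.neighbors(curr))
    if not neighbors:
        return {}
    if prev is None or (params.p == 1.0 and params.q == 1.0):
        w = 1.0 / len(neighbors)
        return {x: w for x in neighbors}
    weights = np.empty(len(neighbors))
    prev_nbrs = set(graph.neighbors(prev))
    for i, x in enumerate(neighbors):
        if x == prev:
            weights[i] = 1.0 / params.p
        elif x in prev_nbrs:
            weights[i] = 1.0
        else:
            weights[i] = 1.0 / params.q
    weights /= weights.sum()
    return dict(zip(neighbors, weights))


def generate_walks(graph: nx.Graph, params: WalkParams) -> WalkCorpus:
    """Sample ``num_walks`` truncated (biased) random walks from every node.

    Node order is shuffled each epoch under the seed; consecutive nodes in a
    walk are always adjacent in the graph.  Isolated nodes yield length-1
    walks.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(params.seed)
    nodes = sorted(graph.nodes())
    nbrs = {n: sorted(graph.neighbors(n)) for n in nodes}
    uniform = params.p == 1.0 and params.q == 1.0
    walks: list[list[str]] = []
    for _ in range(params.num_walks):
        order = rng.permutation(len(nodes))
        for idx in order:
            walk = [nodes[idx]]
            while len(walk) < params.walk_length:
                curr = walk[-1]
                cn = nbrs[curr]
                if not cn:
                    break
                if uniform or len(walk) == 1:
                    nxt = cn[rng.integers(len(cn))]
                else:
                    dist = node2vec_transition(graph, walk[-2], curr, params)
                    keys = list(dist)
                    nxt = keys[rng.choice(len(keys), p=np.array(list(dist.values())))]
                walk.append(nxt)
            walks.append(walk)
    return WalkCorpus(walks=walks, walk_length=params.walk_length, num_walks=params.num_walks)


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling (minibatched SGD, pure numpy)


def train_skipgram(
    corpus: WalkCorpus,
    d: int = 128,
    window: int = 10,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
    lr: float = 0.025,
    batch_size: int = 1024,
    method: str = "deepwalk",
) -> EmbeddingMap:
    """Learn node vectors from a walk corpus via skip-gram + negative sampling.

    Windowed (center, context) co-occurrences are the positive pairs; negative
    contexts are drawn from the unigram distribution raised to the 3/4 power.
    The learning rate decays linearly over all updates.
    """
    if d <= 0 or window <= 0:
        raise ValueError("d and window must be positive")
    if not corpus.walks:
        raise ValueError("empty corpus")
    vocab = sorted({n for w in corpus.walks for n in w})
    index = {n: i for i, n in enumerate(vocab)}
    n = len(vocab)
    rng = np.random.default_rng(seed)

    counts = np.zeros(n)
    centers_list, contexts_list = [], []
    for walk in corpus.walks:
        ids = [index[x] for x in walk]
        for i, c in enumerate(ids):
            counts[c] += 1
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers_list.append(c)
                    contexts_list.append(ids[j])
    centers = np.array(centers_list, dtype=np.int64)
    contexts = np.array(contexts_list, dtype=np.int64)

    W = (rng.random((n, d)) - 0.5) / d
    C = np.zeros((n, d))
    trained = set(np.unique(centers).tolist())
    isolated = {v for v in vocab if index[v] not in trained}

    if len(centers) > 0:
        noise = counts**0.75
        noise /= noise.sum()
        total_batches = epochs * max(1, int(np.ceil(len(centers) / batch_size)))
        step = 0
        for _ in range(epochs):
            order = rng.permutation(len(centers))
            for start in range(0, len(order), batch_size):
                sel = order[start : start + batch_size]
                cw, cx = centers[sel], contexts[sel]
                alpha = lr * max(1e-4, 1.0 - step / total_batches)
                step += 1
                neg = rng.choice(n, size=(len(sel), negative), p=noise)
                w = W[cw]  # (B, d)
                vpos = C[cx]  # (B, d)
                vneg = C[neg]  # (B, k, d)
                gpos = _sigmoid((w * vpos).sum(1)) - 1.0  # (B,)
                gneg = _sigmoid((w[:, None, :] * vneg).sum(2))  # (B, k)
                gneg[neg == cx[:, None]] = 0.0  # a negative equal to the true context is no evidence
                grad_w = gpos[:, None] * vpos + (gneg[:, :, None] * vneg).sum(1)
                np.add.at(W, cw, -alpha * grad_w)
                np.add.at(C, cx, -alpha * gpos[:, None] * w)
                np.add.at(
                    C,
                    neg.ravel(),
                    (-alpha * gneg[:, :, None] * w[:, None, :]).reshape(-1, d),
                )

    vectors = {v: W[index[v]].copy() for v in vocab}
    return EmbeddingMap(vectors=vectors, d=d, method=method, isolated=isolated)


def deepwalk_embed(
    graph: nx.Graph,
    d: int = 128,
    walk_length: int = 80,
    num_walks: int = 10,
    window: int = 10,
    epochs: int = 5,
    seed: int = 0,
    **kw,
) -> EmbeddingMap:
    """Uniform random walks + skip-gram (Node2vec with p = q = 1)."""
    params = WalkParams(p=1.0, q=1.0, walk_length=walk_length, num_walks=num_walks, seed=seed)
    corpus = generate_walks(graph, params)
    return train_skipgram(
        corpus, d=d, window=window, epochs=epochs, seed=seed + 1, method="deepwalk", **kw
    )


def node2vec_embed(
    graph: nx.Graph,
    d: int = 128,
    p: float = 1.0,
    q: float = 1.0,
    walk_length: int = 80,
    num_walks: int = 10,
    window: int = 10,
    epochs: int = 5,
    seed: int = 0,
    **kw,
) -> EmbeddingMap:
    """Biased (p, q) random walks + skip-gram."""
    params = WalkParams(p=p, q=q, walk_length=walk_length, num_walks=num_walks, seed=seed)
    corpus = generate_walks(graph, params)
    return train_skipgram(
        corpus, d=d, window=window, epochs=epochs, seed=seed + 1, method="node2vec", **kw
    )


# ---------------------------------------------------------------------------
# LINE


def line_embed(
    graph: nx.Graph,
    d: int = 128,
    order: str = "first",
    epochs: int = 50,
    seed: int = 0,
    negative: int = 5,
    lr: float = 0.025,
    batch_size: int = 1024,
) -> EmbeddingMap:
    """Edge-sampling embedding optimizing first- and/or second-order proximity.

    First order maximizes log σ(w_u·w_v) over observed edges with negative
    sampling; second order uses separate context vectors, log σ(w_u·c_v).
    ``order="concatenated"`` trains both at d/2 and concatenates.
    """
    if graph.number_of_edges() < 1:
        raise ValueError("graph needs at least one edge")
    if order not in {"first", "second", "concatenated"}:
        raise ValueError(f"unknown order {order!r}")
    if order == "concatenated":
        if d % 2:
            raise ValueError("d must be even for order='concatenated'")
        e1 = line_embed(graph, d // 2, "first", epochs, seed, negative, lr, batch_size)
        e2 = line_embed(graph, d // 2, "second", epochs, seed + 1, negative, lr, batch_size)
        vectors = {
            v: np.concatenate([e1.vectors[v], e2.vectors[v]]) for v in e1.vectors
        }
        return EmbeddingMap(vectors=vectors, d=d, method="line", isolated=e1.isolated)

    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    # both directions of every undirected edge
    src, dst = [], []
    for a, b in graph.edges():
        src += [index[a], index[b]]
        dst += [index[b], index[a]]
    src = np.array(src, dtype=np.int64)
    dst = np.array(dst, dtype=np.int64)

    rng = np.random.default_rng(seed)
    deg = np.zeros(n)
    np.add.at(deg, src, 1.0)
    noise = deg**0.75
    noise[noise == 0] = 1e-12
    noise /= noise.sum()

    W = (rng.random((n, d)) - 0.5) / d
    ctx = np.zeros((n, d)) if order == "second" else W

    n_edges = len(src)
    total_batches = epochs * max(1, int(np.ceil(n_edges / batch_size)))
    step = 0
    for _ in range(epochs):
        perm = rng.permutation(n_edges)
        for start in range(0, n_edges, batch_size):
            sel = perm[start : start + batch_size]
            u, v = src[sel], dst[sel]
            alpha = lr * max(1e-4, 1.0 - step / total_batches)
            step += 1
            neg = rng.choice(n, size=(len(sel), negative), p=noise)
            w = W[u]
            vpos = ctx[v]
            vneg = ctx[neg]
            gpos = _sigmoid((w * vpos).sum(1)) - 1.0
            gneg = _sigmoid((w[:, None, :] * vneg).sum(2))
            gneg[neg == v[:, None]] = 0.0  # drop negatives that hit the true target
            grad_w = gpos[:, None] * vpos + (gneg[:, :, None] * vneg).sum(1)
            np.add.at(W, u, -alpha * grad_w)
            np.add.at(ctx, v, -alpha * gpos[:, None] * w)
            np.add.at(
                ctx, neg.ravel(), (-alpha * gneg[:, :, None] * w[:, None, :]).reshape(-1, d)
            )

    isolated = {v for v in nodes if deg[index[v]] == 0}
    vectors = {v: W[index[v]].copy() for v in nodes}
    return EmbeddingMap(vectors=vectors, d=d, method="line", isolated=isolated)


# ---------------------------------------------------------------------------
# SDNE (adjacency-row autoencoder + Laplacian first-order penalty)


def sdne_embed(
    graph: nx.Graph,
    d: int = 128,
    hidden: int | None = None,
    alpha: float = 1e-5,
    beta: float = 5.0,
    epochs: int = 200,
    seed: int = 0,
    lr: float = 0.01,
) -> EmbeddingMap:
    """Deep autoencoder embedding of adjacency rows.

    Input S_i is node i's adjacency row.  The total loss is the reconstruction
    error Σ‖(S′_i − S_i) ⊙ b_i‖² with nonzero entries up-weighted by *beta*,
    plus *alpha* times the Laplacian first-order term Σ_ij A_ij‖z_i − z_j‖².
    Architecture: one sigmoid hidden layer of size min(256, n) on both the
    encoder and decoder sides, linear bottleneck and output, trained
    full-batch with Adam.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if d >= n:
        raise ValueError(f"embedding dimension d={d} must be < number of nodes {n}")
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    S = nx.to_numpy_array(graph, nodelist=nodes)
    B = np.where(S > 0, beta, 1.0)
    L = np.diag(S.sum(1)) - S  # graph Laplacian

    h = min(256, n) if hidden is None else hidden
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=(fan_in, fan_out))

    params = {
        "W1": glorot(n, h), "b1": np.zeros(h),
        "W2": glorot(h, d), "b2": np.zeros(d),
        "W3": glorot(d, h), "b3": np.zeros(h),
        "W4": glorot(h, n), "b4": np.zeros(n),
    }
    m_adam = {k: np.zeros_like(v) for k, v in params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in params.items()}
    b1m, b2m, eps = 0.9, 0.999, 1e-8

    for t in range(1, epochs + 1):
        H1 = _sigmoid(S @ params["W1"] + params["b1"])
        Z = H1 @ params["W2"] + params["b2"]
        H2 = _sigmoid(Z @ params["W3"] + params["b3"])
        Sp = H2 @ params["W4"] + params["b4"]

        R = (Sp - S) * B  # weighted residual
        loss = (R * (Sp - S)).sum() + 2.0 * alpha * np.trace(Z.T @ L @ Z)
        if not np.isfinite(loss):
            raise FloatingPointError(f"SDNE loss diverged at epoch {t} (loss={loss})")

        dSp = 2.0 * (Sp - S) * B
        grads = {}
        grads["W4"] = H2.T @ dSp
        grads["b4"] = dSp.sum(0)
        dH2 = dSp @ params["W4"].T * H2 * (1 - H2)
        grads["W3"] = Z.T @ dH2
        grads["b3"] = dH2.sum(0)
        dZ = dH2 @ params["W3"].T + 4.0 * alpha * (L @ Z)
        grads["W2"] = H1.T @ dZ
        grads["b2"] = dZ.sum(0)
        dH1 = dZ @ params["W2"].T * H1 * (1 - H1)
        grads["W1"] = S.T @ dH1
        grads["b1"] = dH1.sum(0)

        for k in params:
            m_adam[k] = b1m * m_adam[k] + (1 - b1m) * grads[k]
            v_adam[k] = b2m * v_adam[k] + (1 - b2m) * grads[k] ** 2
            mhat = m_adam[k] / (1 - b1m**t)
            vhat = v_adam[k] / (1 - b2m**t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    H1 = _sigmoid(S @ params["W1"] + params["b1"])
    Z = H1 @ params["W2"] + params["b2"]
    isolated = {v for v in nodes if graph.degree(v) == 0}
    vectors = {v: Z[index[v]].copy() for v in nodes}
    return EmbeddingMap(vectors=vectors, d=d, method="sdne", isolated=isolated)


METHODS = {
    "deepwalk": deepwalk_embed,
    "node2vec": node2vec_embed,
    "line": line_embed,
    "sdne": sdne_embed,
}


def embed(graph: nx.Graph, method: str, **kwargs) -> EmbeddingMap:
    """Dispatch to one of the four embedding methods by name."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return METHODS[method](graph, **kwargs)
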