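"""Node embeddings from second-order biased random walks.

The cohort subgraph is walked in its undirected view (directed walks would
drift monotonically toward hierarchy roots or leaves and starve sibling
co-occurrence), and a skip-gram model with negative sampling is trained on the
walk corpus.  Both stages run single-threaded with an explicit
counter-advanced RNG, so a fixed seed reproduces embeddings bit-for-bit —
the determinism contract the downstream clustering relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .ontology import CohortSubgraph

# Defaults match the embedding configuration used throughout the pipeline.
DEFAULT_P = 3.0
DEFAULT_Q = 1.5
DEFAULT_WALK_LENGTH = 20
DEFAULT_NUM_WALKS = 20
DEFAULT_DIM = 128
DEFAULT_WINDOW = 10
DEFAULT_SEED = 42


@dataclass
class WalkCorpus:
    """Random-walk corpus over subgraph nodes.

    ``walks`` holds node indices into ``ids``; rows are padded with -1 past
    each walk's end (isolated nodes yield length-1 walks).
    """

    ids: list[str]
    walks: np.ndarray  # (n_walks, walk_length) int32, -1 padded
    p: float
    q: float
    walk_length: int
    num_walks: int
    seed: int

    def as_sentences(self) -> list[list[str]]:
        out = []
        for row in self.walks:
            out.append([self.ids[i] for i in row if i >= 0])
        return out


@dataclass
class EmbeddingMatrix:
    """Fixed-dimension vectors per concept."""

    ids: list[str]
    vectors: np.ndarray  # (n_nodes, dim) float32
    dim: int
    window: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {cid: i for i, cid in enumerate(self.ids)}

    def __contains__(self, cid) -> bool:
        return cid in self._index

    def vector(self, cid: str) -> np.ndarray:
        return self.vectors[self._index[cid]]

    def take(self, nodes) -> np.ndarray:
        try:
            rows = [self._index[n] for n in nodes]
        except KeyError as exc:
            raise KeyError(f"node without embedding vector: {exc.args[0]!r}") from exc
        return self.vectors[rows]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.vectors, index=pd.Index(self.ids, name="concept_id")
        )


@njit(cache=True)
def _xorshift(state):
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True)
def _rand_uniform(state):
    state = _xorshift(state)
    return state, np.float64(state >> np.uint64(11)) / np.float64(1 << 53)


@njit(cache=True)
def _rand_below(state, n):
    state, u = _rand_uniform(state)
    return state, np.int64(u * n)


@njit(cache=True)
def _is_neighbor(indptr, indices, node, candidate):
    lo, hi = indptr[node], indptr[node + 1]
    while lo < hi:  # neighbor lists are sorted
        mid = (lo + hi) // 2
        if indices[mid] == candidate:
            return True
        if indices[mid] < candidate:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def _walk_kernel(indptr, indices, order, walk_length, num_walks, p, q, seed):
    n = order.shape[0]
    walks = np.full((num_walks * n, walk_length), -1, dtype=np.int32)
    state = np.uint64(seed * 2654435761 + 1)
    weights = np.empty(indices.shape[0] if indices.shape[0] > 0 else 1, np.float64)
    w = 0
    for r in range(num_walks):
        for oi in range(n):
            start = order[oi]
            walks[w, 0] = start
            deg0 = indptr[start + 1] - indptr[start]
            if deg0 == 0:
                w += 1
                continue
            # first step: uniform over neighbors
            state, j = _rand_below(state, deg0)
            walks[w, 1] = indices[indptr[start] + j]
            for step in range(2, walk_length):
                prev = walks[w, step - 2]
                cur = walks[w, step - 1]
                lo, hi = indptr[cur], indptr[cur + 1]
                deg = hi - lo
                if deg == 0:
                    break
                total = 0.0
                for k in range(deg):
                    x = indices[lo + k]
                    if x == prev:
                        wk = 1.0 / p
                    elif _is_neighbor(indptr, indices, prev, x):
                        wk = 1.0
                    else:
                        wk = 1.0 / q
                    weights[k] = wk
                    total += wk
                state, u = _rand_uniform(state)
                target = u * total
                acc = 0.0
                chosen = indices[hi - 1]
                for k in range(deg):
                    acc += weights[k]
                    if target < acc:
                        chosen = indices[lo + k]
                        break
                walks[w, step] = chosen
            w += 1
    return walks


def _undirected_csr(sub: CohortSubgraph):
    ids = sorted(sub.graph.nodes)
    index = {cid: i for i, cid in enumerate(ids)}
    neighbors: list[set[int]] = [set() for _ in ids]
    for u, v in sub.graph.edges:
        ui, vi = index[u], index[v]
        neighbors[ui].add(vi)
        neighbors[vi].add(ui)
    indptr = np.zeros(len(ids) + 1, dtype=np.int64)
    flat = []
    for i, ns in enumerate(neighbors):
        srt = sorted(ns)
        flat.extend(srt)
        indptr[i + 1] = indptr[i] + len(srt)
    indices = np.asarray(flat, dtype=np.int32)
    return ids, indptr, indices


def generate_walks(
    sub: CohortSubgraph,
    p: float = DEFAULT_P,
    q: float = DEFAULT_Q,
    walk_length: int = DEFAULT_WALK_LENGTH,
    num_walks: int = DEFAULT_NUM_WALKS,
    seed: int = DEFAULT_SEED,
) -> WalkCorpus:
    """Second-order biased walks over the undirected subgraph view.

    From previous node ``t`` at current node ``v``, a candidate ``x`` is drawn
    with unnormalized weight ``1/p`` if ``x == t``, ``1`` if ``x`` is adjacent
    to ``t``, else ``1/q``.  ``num_walks`` walks start at every node; the
    first step is uniform.  Identical seeds yield identical corpora.
    """
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    ids, indptr, indices = _undirected_csr(sub)
    order = np.arange(len(ids), dtype=np.int64)
    walks = _walk_kernel(
        indptr, indices, order, walk_length, num_walks, float(p), float(q), seed
    )
    return WalkCorpus(ids, walks, p, q, walk_length, num_walks, seed)


@njit(cache=True)
def _sgns_kernel(
    tokens, offsets, W, C, noise_cdf, window, epochs, negative, alpha0, min_alpha, seed
):
    dim = W.shape[1]
    n_sent = offsets.shape[0] - 1
    total_tokens = tokens.shape[0]
    state = np.uint64(seed * 6364136223846793005 + 1442695040888963407)
    processed = 0
    total = epochs * total_tokens
    for _ in range(epochs):
        for s in range(n_sent):
            lo, hi = offsets[s], offsets[s + 1]
            for i in range(lo, hi):
                center = tokens[i]
                alpha = alpha0 - (alpha0 - min_alpha) * (processed / total)
                processed += 1
                state, b = _rand_below(state, window)
                wlo = i - (window - b)
                whi = i + (window - b)
                if wlo < lo:
                    wlo = lo
                if whi > hi - 1:
                    whi = hi - 1
                for j in range(wlo, whi + 1):
                    if j == i:
                        continue
                    context = tokens[j]
                    # positive pair + `negative` noise pairs
                    for neg in range(negative + 1):
                        if neg == 0:
                            target = context
                            label = 1.0
                        else:
                            state, u = _rand_uniform(state)
                            target = np.searchsorted(noise_cdf, u)
                            if target == center:
                                continue
                            label = 0.0
                        dot = 0.0
                        for d in range(dim):
                            dot += W[center, d] * C[target, d]
                        if dot > 8.0:
                            sig = 1.0
                        elif dot < -8.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - sig) * alpha
                        for d in range(dim):
                            tmp = W[center, d]
                            W[center, d] += g * C[target, d]
                            C[target, d] += g * tmp


def train_embeddings(
    corpus: WalkCorpus,
    dim: int = DEFAULT_DIM,
    window: int = DEFAULT_WINDOW,
    seed: int = DEFAULT_SEED,
    epochs: int = 5,
    negative: int = 5,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> EmbeddingMatrix:
    """Skip-gram-with-negative-sampling embeddings of the walk corpus.

    Single-threaded streaming SGD with a dynamically shrunk context window
    (word2vec convention) and a unigram^0.75 noise distribution.  Repeated
    runs with the same corpus and seed are bit-identical.
    """
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if corpus.walks.size == 0:
        raise ValueError("empty walk corpus")

    flat: list[int] = []
    offsets = [0]
    for row in corpus.walks:
        sent = row[row >= 0]
        flat.extend(int(t) for t in sent)
        offsets.append(len(flat))
    tokens = np.asarray(flat, dtype=np.int64)
    offs = np.asarray(offsets, dtype=np.int64)

    n_vocab = len(corpus.ids)
    counts = np.bincount(tokens, minlength=n_vocab).astype(np.float64)
    unwalked = np.flatnonzero(counts == 0)
    if unwalked.size:
        warnings.warn(
            f"{unwalked.size} node(s) absent from every walk receive no trained vector",
            stacklevel=2,
        )
    noise = counts**0.75
    noise_sum = noise.sum()
    noise_cdf = np.cumsum(noise / noise_sum)

    rng = np.random.default_rng(seed)
    W = ((rng.random((n_vocab, dim)) - 0.5) / dim).astype(np.float64)
    C = np.zeros((n_vocab, dim), dtype=np.float64)
    _sgns_kernel(
        tokens, offs, W, C, noise_cdf, window, epochs, negative,
        float(alpha), float(min_alpha), seed,
    )
    return EmbeddingMatrix(
        list(corpus.ids),
        W.astype(np.float32),
        dim,
        window,
        seed,
        params={
            "p": corpus.p, "q": corpus.q, "walk_length": corpus.walk_length,
            "num_walks": corpus.num_walks, "epochs": epochs,
            "negative": negative, "alpha": alpha, "min_alpha": min_alpha,
        },
    )


def embed_subgraph(sub: CohortSubgraph, seed: int = DEFAULT_SEED, **kw) -> EmbeddingMatrix:
    """Convenience wrapper: walks + training with shared seed."""
    walk_kw = {k: kw.pop(k) for k in ("p", "q", "walk_length", "num_walks") if k in kw}
    corpus = generate_walks(sub, seed=seed, **walk_kw)
    return train_embeddings(corpus, seed=seed, **kw)


def embedding_distances(emb: EmbeddingMatrix, nodes, metric: str = "cosine") -> np.ndarray:
    """Symmetric pairwise distance matrix over ``nodes``.

    Cosine distance is ``1 - cosine similarity``; the diagonal is exactly 0.
    """
    if metric not in ("cosine", "euclidean"):
        raise ValueError(f"unsupported metric {metric!r}")
    X = emb.take(nodes).astype(np.float64)
    D = cdist(X, X, metric=metric)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def save_embeddings(emb: EmbeddingMatrix, path, meta_path=None) -> None:
    """Write embeddings as TSV plus an optional run-metadata sidecar."""
    emb.to_frame().to_csv(path, sep="\t")
    if meta_path is not None:
        import json

        meta = {"dim": emb.dim, "window": emb.window, "seed": emb.seed, **emb.params}
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
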