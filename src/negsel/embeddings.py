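"""Shallow node-embedding methods.

Seven methods are available through :func:`embed_graph`:

* ``deepwalk-cbow`` / ``deepwalk-skipgram`` — first-order uniform random
  walks feeding a word2vec-style trainer with negative sampling (SGNS):
  SkipGram predicts the context nodes from the central node, CBOW predicts
  the central node from the mean of its context vectors. The embedding is
  the trained input-layer weight matrix.
* ``walklets-cbow`` / ``walklets-skipgram`` — the same walks, subsampled so
  that adjacent tokens at scale *i* are exactly *i* hops apart; one
  embedding is trained per scale and the scales are concatenated, with the
  total dimension split evenly across scales.
* ``line1`` / ``line2`` — first/second-order LINE: a logistic
  edge-existence objective over positive edges and noise-sampled negative
  endpoints; second order learns separate node and context matrices.
* ``hope`` — truncated SVD of the common-neighbor proximity matrix
  S[u, v] = |N(u) ∩ N(v)|, returning source = U_k Σ_k^{1/2} and
  destination = V_k Σ_k^{1/2} so their inner product reconstructs S at
  rank k (the optimal rank-k approximation).

Negative nodes during SGNS/LINE training are drawn from the unigram (token
frequency, resp. degree) distribution raised to the 3/4 power — this is the
phase-1 noise distribution of word2vec practice and is independent of the
UNS/DANS evaluation samplers.

All trainers are plain numpy with mini-batch SGD and per-epoch learning-rate
decay; fixed seeds give bit-identical matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .graph import Graph, degree_vector

__all__ = [
    "EmbeddingConfig",
    "EmbeddingMatrix",
    "WalkCorpus",
    "generate_walks",
    "walklets_corpora",
    "train_word2vec",
    "train_line",
    "hope_embed",
    "embed_graph",
    "default_config",
    "write_embedding",
    "EMBEDDING_METHODS",
]

EMBEDDING_METHODS = (
    "deepwalk-cbow",
    "deepwalk-skipgram",
    "walklets-cbow",
    "walklets-skipgram",
    "line1",
    "line2",
    "hope",
)

PAD = -1  # walk padding token (dead ends / subsampled tails)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the shallow embedders.

    Defaults follow the random-walk models' published settings: 128-step
    walks, 100 walks per source node, window 5, 10 negative samples with
    noise exponent 3/4, learning-rate decay 0.9 per epoch. LINE uses 100
    epochs at rate 0.05 (see :func:`default_config`).
    """

    dimension: int = 100
    epochs: int = 30
    learning_rate: float = 0.010
    learning_rate_decay: float = 0.9
    window_size: int = 5
    negative_samples: int = 10
    noise_exponent: float = 0.75
    walk_length: int = 128
    iterations: int = 100
    max_neighbors: int = 100
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self):
        if min(self.dimension, self.epochs, self.window_size, self.walk_length) <= 0:
            raise ValueError("config values must be positive")
        if self.window_size >= self.walk_length:
            raise ValueError("window_size must be smaller than walk_length")


def default_config(method: str, **overrides) -> EmbeddingConfig:
    """Per-method defaults: DeepWalk 30 epochs / lr 0.010 / window 5;
    Walklets window 4; first/second-order LINE 100 epochs / lr 0.050."""
    if method not in EMBEDDING_METHODS:
        raise ValueError(f"unknown method {method!r}")
    base = {}
    if method.startswith("walklets"):
        base = {"window_size": 4}
    elif method in ("line1", "line2"):
        base = {"epochs": 100, "learning_rate": 0.050}
    base.update(overrides)
    return EmbeddingConfig(**base)


@dataclass(frozen=True)
class EmbeddingMatrix:
    primary: np.ndarray  # (n_nodes, d)
    method: str
    secondary: np.ndarray | None = None  # destination/context matrix
    loss_history: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.primary).all():
            raise ValueError("embedding contains non-finite entries")
        if self.secondary is not None and not np.isfinite(self.secondary).all():
            raise ValueError("secondary embedding contains non-finite entries")

    @property
    def dimension(self) -> int:
        return self.primary.shape[1]


@dataclass(frozen=True)
class WalkCorpus:
    """Random-walk corpus as a PAD-padded (n_walks, walk_length) int array."""

    walks: np.ndarray
    n_nodes: int
    walk_length: int
    iterations: int
    max_neighbors: int
    scale: int = 1  # hop distance between adjacent tokens

    def as_lists(self) -> list:
        return [row[row != PAD].tolist() for row in self.walks]


def generate_walks(g: Graph, config: EmbeddingConfig, seed: int | None = None) -> WalkCorpus:
    """First-order uniform-neighbor walks, ``iterations`` per source node.

    Dead ends (isolated nodes) truncate the walk. When a node's degree
    exceeds ``max_neighbors`` the step samples uniformly among a per-step
    uniformly subsampled neighbor list, which is distributionally identical
    to a uniform choice among all neighbors; the walker therefore draws
    uniformly in all cases.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    indptr, indices = g.csr_adjacency()
    deg = (indptr[1:] - indptr[:-1]).astype(np.int64)
    sources = np.repeat(np.arange(g.n_nodes, dtype=np.int64), config.iterations)
    n_walks = len(sources)
    walks = np.full((n_walks, config.walk_length), PAD, dtype=np.int64)
    walks[:, 0] = sources
    cur = sources.copy()
    alive = deg[cur] > 0
    for step in range(1, config.walk_length):
        if not alive.any():
            break
        d = deg[cur[alive]]
        offs = (rng.random(d.shape[0]) * d).astype(np.int64)
        nxt = indices[indptr[cur[alive]] + offs]
        cur[alive] = nxt
        walks[alive, step] = nxt
        alive = alive & (deg[cur] > 0)
    return WalkCorpus(
        walks=walks,
        n_nodes=g.n_nodes,
        walk_length=config.walk_length,
        iterations=config.iterations,
        max_neighbors=config.max_neighbors,
    )


def walklets_corpora(corpus: WalkCorpus, max_power: int) -> list[WalkCorpus]:
    """Scale-i corpora (i = 1..max_power): every i-th token of each walk from
    each of the i phase offsets, so adjacent tokens are exactly i hops apart.

    Walks shorter than i + 1 tokens contribute nothing at scale i.
    """
    if max_power < 1:
        raise ValueError("max_power must be >= 1")
    out = []
    for i in range(1, max_power + 1):
        subs = [corpus.walks[:, off::i] for off in range(i)]
        width = max(s.shape[1] for s in subs)
        padded = [
            np.pad(s, ((0, 0), (0, width - s.shape[1])), constant_values=PAD) for s in subs
        ]
        walks = np.concatenate(padded, axis=0)
        walks = walks[(walks != PAD).sum(axis=1) >= 2]  # need at least one pair
        out.append(replace(corpus, walks=walks, walk_length=width, scale=i))
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _noise_table(weights: np.ndarray, exponent: float) -> np.ndarray:
    """Cumulative distribution for alias-free noise sampling by searchsorted."""
    w = np.asarray(weights, dtype=float) ** exponent
    total = w.sum()
    if total == 0:
        w = np.ones_like(w)
        total = w.sum()
    return np.cumsum(w) / total


def _sample_noise(cdf: np.ndarray, rng: np.random.Generator, shape) -> np.ndarray:
    return np.searchsorted(cdf, rng.random(shape), side="right").astype(np.int64)


def _skipgram_pairs(walks: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for delta in range(1, window + 1):
        left = walks[:, :-delta]
        right = walks[:, delta:]
        valid = (left != PAD) & (right != PAD)
        centers.append(left[valid])
        contexts.append(right[valid])
        centers.append(right[valid])
        contexts.append(left[valid])
    return np.concatenate(centers), np.concatenate(contexts)


def _cbow_dataset(walks: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """(centers, context blocks) where each block holds up to 2*window
    context tokens, PAD-filled."""
    n_walks, length = walks.shape
    padded = np.full((n_walks, length + 2 * window), PAD, dtype=np.int64)
    padded[:, window : window + length] = walks
    blocks, centers = [], []
    for j in range(length):
        block = padded[:, j : j + 2 * window + 1]
        block = np.delete(block, window, axis=1)
        centers.append(walks[:, j])
        blocks.append(block)
    centers = np.concatenate(centers)
    blocks = np.concatenate(blocks, axis=0)
    valid = centers != PAD
    centers, blocks = centers[valid], blocks[valid]
    has_ctx = (blocks != PAD).any(axis=1)
    return centers[has_ctx], blocks[has_ctx]


def train_word2vec(
    corpus: WalkCorpus,
    config: EmbeddingConfig,
    objective: str = "skipgram",
    seed: int | None = None,
    method_label: str | None = None,
) -> EmbeddingMatrix:
    """SGNS or CBOW over a walk corpus; returns the input-layer weights.

    Noise distribution: token frequency in the corpus raised to
    ``noise_exponent``; ``negative_samples`` noise tokens per positive;
    learning rate decays by ``learning_rate_decay`` each epoch.
    """
    if objective not in ("skipgram", "cbow"):
        raise ValueError(f"unknown objective {objective!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, d, k = corpus.n_nodes, config.dimension, config.negative_samples
    W = (rng.random((n, d)) - 0.5) / d
    C = np.zeros((n, d))
    tokens = corpus.walks[corpus.walks != PAD]
    if tokens.size == 0:
        raise ValueError("empty walk corpus")
    freq = np.bincount(tokens, minlength=n).astype(float)
    cdf = _noise_table(freq, config.noise_exponent)

    if objective == "skipgram":
        centers, contexts = _skipgram_pairs(corpus.walks, config.window_size)
    else:
        centers, blocks = _cbow_dataset(corpus.walks, config.window_size)
    n_examples = len(centers)
    losses = []
    if n_examples == 0:
        # single-node walks: no context pairs, training is a no-op
        return EmbeddingMatrix(W, method_label or f"deepwalk-{objective}", loss_history=())
    lr = config.learning_rate
    for _ in range(config.epochs):
        perm = rng.permutation(n_examples)
        epoch_loss = 0.0
        for start in range(0, n_examples, config.batch_size):
            idx = perm[start : start + config.batch_size]
            tgt = centers[idx] if objective == "cbow" else contexts[idx]
            neg = _sample_noise(cdf, rng, (len(idx), k))
            if objective == "skipgram":
                h = W[centers[idx]]
            else:
                blk = blocks[idx]
                mask = blk != PAD
                counts = mask.sum(axis=1, keepdims=True)
                h = (W[np.where(mask, blk, 0)] * mask[:, :, None]).sum(axis=1) / counts
            pos_s = _sigmoid(np.einsum("bd,bd->b", h, C[tgt]))
            neg_s = _sigmoid(np.einsum("bd,bkd->bk", h, C[neg]))
            epoch_loss += float(
                -np.log(np.clip(pos_s, 1e-10, None)).sum()
                - np.log(np.clip(1.0 - neg_s, 1e-10, None)).sum()
            )
            g_h = (pos_s - 1.0)[:, None] * C[tgt] + np.einsum("bk,bkd->bd", neg_s, C[neg])
            g_tgt = (pos_s - 1.0)[:, None] * h
            g_neg = neg_s[:, :, None] * h[:, None, :]
            np.add.at(C, tgt, -lr * g_tgt)
            np.add.at(C, neg.ravel(), -lr * g_neg.reshape(-1, d))
            if objective == "skipgram":
                np.add.at(W, centers[idx], -lr * g_h)
            else:
                g_ctx = (g_h / counts)[:, None, :] * mask[:, :, None]
                np.add.at(W, np.where(mask, blk, 0).ravel(), -lr * g_ctx.reshape(-1, d))
                # PAD slots were redirected to node 0 with zero gradient (mask)
        losses.append(epoch_loss / n_examples)
        lr *= config.learning_rate_decay
    return EmbeddingMatrix(
        W, method_label or f"deepwalk-{objective}", loss_history=tuple(losses)
    )


def train_line(
    g: Graph, order: int, config: EmbeddingConfig, seed: int | None = None
) -> EmbeddingMatrix:
    """First- or second-order LINE.

    Logistic objective: existing edges score high, noise pairs (one true
    endpoint, one degree^0.75-sampled node) score low. No check that noise
    pairs avoid true edges (false negatives are tolerated during training).
    Order 2 keeps a separate context matrix and returns it as ``secondary``.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if g.n_edges == 0:
        raise ValueError("LINE requires at least one edge")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, d, k = g.n_nodes, config.dimension, config.negative_samples
    # O(1/sqrt(d))-scale init keeps initial inner products away from the
    # zero fixed point of the shared-matrix first-order objective
    W = rng.standard_normal((n, d)) / np.sqrt(d)
    C = np.zeros((n, d)) if order == 2 else W
    deg = degree_vector(g)
    cdf = _noise_table(deg.astype(float), config.noise_exponent)
    # symmetrize: each undirected edge trains in both orientations
    src = np.concatenate([g.edges[:, 0], g.edges[:, 1]])
    dst = np.concatenate([g.edges[:, 1], g.edges[:, 0]])
    n_examples = len(src)
    lr = config.learning_rate
    losses = []
    for _ in range(config.epochs):
        perm = rng.permutation(n_examples)
        epoch_loss = 0.0
        for start in range(0, n_examples, config.batch_size):
            idx = perm[start : start + config.batch_size]
            u, v = src[idx], dst[idx]
            neg = _sample_noise(cdf, rng, (len(idx), k))
            h = W[u]
            pos_s = _sigmoid(np.einsum("bd,bd->b", h, C[v]))
            neg_s = _sigmoid(np.einsum("bd,bkd->bk", h, C[neg]))
            epoch_loss += float(
                -np.log(np.clip(pos_s, 1e-10, None)).sum()
                - np.log(np.clip(1.0 - neg_s, 1e-10, None)).sum()
            )
            g_h = (pos_s - 1.0)[:, None] * C[v] + np.einsum("bk,bkd->bd", neg_s, C[neg])
            g_v = (pos_s - 1.0)[:, None] * h
            g_neg = neg_s[:, :, None] * h[:, None, :]
            np.add.at(W, u, -lr * g_h)
            np.add.at(C, v, -lr * g_v)
            np.add.at(C, neg.ravel(), -lr * g_neg.reshape(-1, d))
        losses.append(epoch_loss / n_examples)
        lr *= config.learning_rate_decay
    return EmbeddingMatrix(
        W,
        f"line{order}",
        secondary=C if order == 2 else None,
        loss_history=tuple(losses),
    )


def hope_embed(g: Graph, dimension: int, diagonal: str = "degree") -> EmbeddingMatrix:
    """HOPE on the common-neighbor proximity matrix.

    S = A @ A counts common neighbors off-diagonal; its diagonal is the node
    degree (kept by default, zeroed with ``diagonal="zero"``). Truncated SVD
    gives source = U_k sqrt(Σ_k), destination = V_k sqrt(Σ_k); when the
    requested dimension exceeds the numerical rank the tail is zero-padded
    with a warning.
    """
    if dimension > g.n_nodes:
        raise ValueError("dimension must not exceed the node count")
    if diagonal not in ("degree", "zero"):
        raise ValueError("diagonal must be 'degree' or 'zero'")
    A = np.zeros((g.n_nodes, g.n_nodes))
    if g.n_edges:
        A[g.edges[:, 0], g.edges[:, 1]] = 1.0
        A[g.edges[:, 1], g.edges[:, 0]] = 1.0
    S = A @ A
    if diagonal == "zero":
        np.fill_diagonal(S, 0.0)
    U, s, Vt = np.linalg.svd(S)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    k = dimension
    if k > rank:
        warnings.warn(
            f"requested dimension {k} exceeds proximity rank {rank}; zero-padding",
            stacklevel=2,
        )
    keep = min(k, rank)
    root = np.sqrt(s[:keep])
    source = np.zeros((g.n_nodes, k))
    destination = np.zeros((g.n_nodes, k))
    source[:, :keep] = U[:, :keep] * root
    destination[:, :keep] = Vt[:keep].T * root
    return EmbeddingMatrix(source, "hope", secondary=destination)


def _split_dimension(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def embed_graph(
    g: Graph, method: str, config: EmbeddingConfig | None = None, seed: int | None = None
) -> EmbeddingMatrix:
    """Train one of the seven embedders on a graph."""
    if method not in EMBEDDING_METHODS:
        raise ValueError(f"unknown method {method!r} (expected one of {EMBEDDING_METHODS})")
    config = config if config is not None else default_config(method)
    seed = config.seed if seed is None else seed
    if method == "hope":
        return hope_embed(g, config.dimension)
    if method in ("line1", "line2"):
        return train_line(g, int(method[-1]), config, seed=seed)
    objective = method.split("-")[1]
    corpus = generate_walks(g, config, seed=seed)
    if method.startswith("deepwalk"):
        emb = train_word2vec(corpus, config, objective, seed=seed + 1, method_label=method)
        return emb
    # walklets: one embedding per scale, concatenated
    scales = walklets_corpora(corpus, config.window_size)
    dims = _split_dimension(config.dimension, len(scales))
    parts, losses = [], []
    for i, (sub, di) in enumerate(zip(scales, dims)):
        if di == 0:
            continue
        sub_cfg = replace(config, dimension=di)
        emb = train_word2vec(sub, sub_cfg, objective, seed=seed + 1 + i, method_label=method)
        parts.append(emb.primary)
        losses.extend(emb.loss_history)
    return EmbeddingMatrix(np.concatenate(parts, axis=1), method, loss_history=tuple(losses))


def write_embedding(emb: EmbeddingMatrix, g: Graph, path) -> None:
    """Headered TSV: node label + one column per dimension."""
    labels = np.asarray(g.node_labels, dtype=object)
    df = pd.DataFrame(emb.primary, columns=[f"dim_{i}" for i in range(emb.dimension)])
    df.insert(0, "node", labels)
    df.to_csv(path, sep="\t", index=False)
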