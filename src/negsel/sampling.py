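"""Negative-edge samplers: uniform node sampling (UNS) and degree-aware node
sampling (DANS), with collision handling and preferential-attachment (PA)
diagnostics.

UNS draws both endpoints of a candidate negative edge uniformly from the node
set; on a degree-skewed graph this yields negatives whose endpoints are mostly
low-degree, unlike the hub-heavy positives. DANS instead draws two existing
edges uniformly at random, orients each with an independent fair coin, and
joins the source of the first to the destination of the second — each
endpoint is then chosen with probability d(u)/(2|E|), i.e. proportionally to
degree, so negatives mimic the degree profile of the positives.

Both samplers reject self-loops, optionally reject collisions with existing
edges and duplicates within the sampled set, and resample; candidate
generation before rejection is exposed through :func:`candidate_stream` so the
pre-rejection endpoint marginals can be checked against enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph import Graph, degree_vector, potential_edge_count

__all__ = [
    "NegativeEdgeSet",
    "PADistribution",
    "PADivergence",
    "sample_uns",
    "sample_dans",
    "sample_negative_edges",
    "candidate_stream",
    "preferential_attachment",
    "pa_divergence",
]

STRATEGIES = ("uns", "dans")


@dataclass(frozen=True)
class NegativeEdgeSet:
    """Sampled non-edges with provenance."""

    edges: np.ndarray  # (m, 2) canonical pairs
    strategy: str
    seed: int
    n_requested: int
    n_rejected: int

    def to_frame(self, g: Graph) -> pd.DataFrame:
        labels = np.asarray(g.node_labels, dtype=object)
        return pd.DataFrame(
            {
                "source": labels[self.edges[:, 0]],
                "destination": labels[self.edges[:, 1]],
                "label": 0,
                "strategy": self.strategy,
                "seed": self.seed,
            }
        )


def candidate_stream(
    g: Graph, strategy: str, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Raw candidate pairs before any rejection (may contain self-loops,
    collisions and repeats). Column 0 / 1 are the two endpoint draws.

    UNS: both endpoints i.i.d. uniform over nodes. DANS: endpoint 0 is the
    source of a uniformly drawn, coin-oriented edge e1; endpoint 1 is the
    destination of an independently drawn, coin-oriented edge e2.
    """
    if strategy == "uns":
        return rng.integers(0, g.n_nodes, size=(size, 2))
    if strategy == "dans":
        if g.n_edges == 0:
            raise ValueError("DANS requires at least one edge")
        e1 = rng.integers(0, g.n_edges, size=size)
        o1 = rng.integers(0, 2, size=size)
        e2 = rng.integers(0, g.n_edges, size=size)
        o2 = rng.integers(0, 2, size=size)
        src = g.edges[e1, o1]  # source of e1 under orientation o1
        dst = g.edges[e2, 1 - o2]  # destination of e2 under orientation o2
        return np.column_stack([src, dst])
    raise ValueError(f"unknown strategy {strategy!r} (expected one of {STRATEGIES})")


def sample_negative_edges(
    g: Graph,
    strategy: str,
    m: int,
    seed: int,
    avoid_collisions: bool = True,
    reject_duplicates: bool = True,
    collision_edge_type=None,
    max_attempts_factor: int = 100,
) -> NegativeEdgeSet:
    """Sample ``m`` negative edges by rejection.

    Self-loops are always rejected. With ``avoid_collisions`` (default),
    candidates colliding with existing edges are rejected — against ALL edge
    types of the reference graph unless ``collision_edge_type`` narrows the
    check. Duplicate pairs within the returned set are rejected by default.
    Deterministic given (graph, strategy, m, seed).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    distinct_pairs = len(np.unique(g.edges[:, 0] * g.n_nodes + g.edges[:, 1]))
    if avoid_collisions and m > potential_edge_count(g.n_nodes) - distinct_pairs:
        raise ValueError(
            f"requested {m} negatives but only "
            f"{potential_edge_count(g.n_nodes) - distinct_pairs} non-edges exist"
        )
    rng = np.random.default_rng(seed)
    cap = max_attempts_factor * m
    accepted = np.empty((0, 2), dtype=np.int64)
    accepted_keys = np.empty(0, dtype=np.int64)
    attempts = 0
    while len(accepted) < m:
        if attempts >= cap:
            raise RuntimeError(
                f"resampling cap ({cap} attempts) exceeded after "
                f"{len(accepted)}/{m} accepted — graph is near-complete"
            )
        batch = min(cap - attempts, max(2 * (m - len(accepted)), 64))
        cand = candidate_stream(g, strategy, batch, rng)
        attempts += batch
        keep = cand[:, 0] != cand[:, 1]
        cand = np.column_stack([cand.min(axis=1), cand.max(axis=1)])[keep]
        if avoid_collisions and len(cand):
            cand = cand[~g.has_edges(cand, edge_type=collision_edge_type)]
        if reject_duplicates and len(cand):
            keys = cand[:, 0] * g.n_nodes + cand[:, 1]
            first = np.unique(keys, return_index=True)[1]
            cand = cand[np.sort(first)]
            keys = cand[:, 0] * g.n_nodes + cand[:, 1]
            cand = cand[~np.isin(keys, accepted_keys)]
        if len(cand):
            accepted = np.concatenate([accepted, cand])[:m]
            accepted_keys = accepted[:, 0] * g.n_nodes + accepted[:, 1]
    return NegativeEdgeSet(
        edges=accepted,
        strategy=strategy,
        seed=seed,
        n_requested=m,
        n_rejected=attempts - m,
    )


def sample_uns(g: Graph, m: int, seed: int, avoid_collisions: bool = True, **kw) -> NegativeEdgeSet:
    """Uniform node sampling of negative edges."""
    return sample_negative_edges(g, "uns", m, seed, avoid_collisions=avoid_collisions, **kw)


def sample_dans(g: Graph, m: int, seed: int, avoid_collisions: bool = True, **kw) -> NegativeEdgeSet:
    """Degree-aware node sampling of negative edges."""
    return sample_negative_edges(g, "dans", m, seed, avoid_collisions=avoid_collisions, **kw)


@dataclass(frozen=True)
class PADistribution:
    """Multiset of preferential-attachment values PA = d(u) * d(v)."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.int64)
        if (values < 0).any():
            raise ValueError("PA values must be non-negative")
        object.__setattr__(self, "values", values)

    def mean(self) -> float:
        return float(self.values.mean())

    def summary(self) -> dict:
        """Quantiles and a log1p-scale histogram (PA spans orders of magnitude)."""
        q = np.quantile(self.values, [0.0, 0.25, 0.5, 0.75, 1.0])
        log_vals = np.log1p(self.values)
        counts, edges = np.histogram(log_vals, bins=20)
        return {
            "quantiles": {p: float(v) for p, v in zip((0, 25, 50, 75, 100), q)},
            "mean": self.mean(),
            "log1p_hist_counts": counts.tolist(),
            "log1p_hist_edges": edges.tolist(),
        }


def preferential_attachment(g: Graph, pairs, edge_type=None) -> PADistribution:
    """PA = d(u) * d(v) per pair, degrees from the full reference graph
    (all edge types) unless ``edge_type`` restricts them."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    deg = degree_vector(g, edge_type)
    return PADistribution(values=deg[pairs[:, 0]] * deg[pairs[:, 1]])


@dataclass(frozen=True)
class PADivergence:
    ks_statistic: float
    ks_pvalue: float
    wasserstein_log1p: float


def pa_divergence(positive: PADistribution, negative: PADistribution) -> PADivergence:
    """How far a negative set's PA distribution sits from the positives'.

    Two-sample Kolmogorov-Smirnov statistic plus the Wasserstein-1 distance on
    log1p(PA); lower values mean the negatives look more like the positives.
    """
    if len(positive.values) == 0 or len(negative.values) == 0:
        raise ValueError("PA distributions must be non-empty")
    ks = stats.ks_2samp(positive.values, negative.values)
    w = stats.wasserstein_distance(np.log1p(positive.values), np.log1p(negative.values))
    return PADivergence(
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        wasserstein_log1p=float(w),
    )
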