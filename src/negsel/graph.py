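"""Undirected (optionally heterogeneous) graph container and degree statistics.

The container is deliberately minimal: integer-indexed nodes, an ``(m, 2)``
edge array with each unordered pair stored as ``(min, max)``, and optional
per-edge / per-node type labels. Node indices are assigned by lexicographic
sort of the external labels so that runs are bit-reproducible across
platforms. Self-loops are rejected by default. A node pair may carry edges of
several types (e.g. both a protein-protein association and a synthetic
lethality interaction), but duplicates within one type are collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Graph",
    "DegreeSummary",
    "load_edge_list",
    "write_edge_list",
    "degree_vector",
    "top_k_degree_summary",
    "largest_connected_component",
    "potential_edge_count",
    "merge_graphs",
    "remove_edges",
]


def _canonical_pairs(pairs: np.ndarray) -> np.ndarray:
    """Sort each row so that u < v."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return np.column_stack([pairs.min(axis=1), pairs.max(axis=1)])


@dataclass(frozen=True)
class Graph:
    """Immutable undirected graph with dense integer node indices."""

    n_nodes: int
    node_labels: tuple
    edges: np.ndarray  # (m, 2) int64, each row (u, v) with u < v
    edge_types: np.ndarray | None = None  # (m,) str, or None for homogeneous
    node_types: np.ndarray | None = None
    directed: bool = False
    _adjacency: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size and (edges.min() < 0 or edges.max() >= self.n_nodes):
            raise ValueError("edge endpoint index out of range")
        edges.setflags(write=False)
        object.__setattr__(self, "edges", edges)

    @classmethod
    def from_label_pairs(
        cls,
        pairs,
        edge_types=None,
        node_types: dict | None = None,
        extra_labels=(),
        allow_self_loops: bool = False,
    ) -> "Graph":
        """Build a graph from (source_label, destination_label) pairs.

        Labels are mapped to indices in lexicographic order. Duplicate
        unordered pairs within one edge type are collapsed; self-loops raise
        unless ``allow_self_loops``.
        """
        pairs = list(pairs)
        labels = sorted(
            {str(s) for s, d in pairs}
            | {str(d) for s, d in pairs}
            | {str(x) for x in extra_labels}
        )
        index = {lab: i for i, lab in enumerate(labels)}
        types = list(edge_types) if edge_types is not None else None
        rows, row_types, seen = [], [], set()
        for k, (s, d) in enumerate(pairs):
            u, v = index[str(s)], index[str(d)]
            if u == v and not allow_self_loops:
                raise ValueError(f"self-loop on node {s!r} (use allow_self_loops to keep)")
            t = types[k] if types is not None else None
            key = (min(u, v), max(u, v), t)
            if key in seen:
                continue
            seen.add(key)
            rows.append((min(u, v), max(u, v)))
            row_types.append(t)
        edges = np.array(rows, dtype=np.int64).reshape(-1, 2)
        etypes = np.array(row_types, dtype=object) if types is not None else None
        ntypes = None
        if node_types is not None:
            ntypes = np.array([node_types.get(lab) for lab in labels], dtype=object)
        return cls(len(labels), tuple(labels), edges, etypes, ntypes)

    # -- cached derived structures ------------------------------------------

    def _cache(self, key, fn):
        if key not in self._adjacency:
            self._adjacency[key] = fn()
        return self._adjacency[key]

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def edge_keys(self, edge_type=None) -> np.ndarray:
        """Sorted int64 keys u * n + v for membership tests."""

        def build():
            e = self._edges_of_type(edge_type)
            return np.sort(e[:, 0] * self.n_nodes + e[:, 1])

        return self._cache(("keys", edge_type), build)

    def _edges_of_type(self, edge_type):
        if edge_type is None:
            return self.edges
        if self.edge_types is None:
            raise ValueError(f"graph has no edge types; asked for {edge_type!r}")
        mask = self.edge_types == edge_type
        if not mask.any():
            raise ValueError(f"unknown edge type {edge_type!r}")
        return self.edges[mask]

    def has_edges(self, pairs: np.ndarray, edge_type=None) -> np.ndarray:
        """Boolean mask: which unordered pairs are existing edges."""
        pairs = _canonical_pairs(pairs)
        keys = pairs[:, 0] * self.n_nodes + pairs[:, 1]
        table = self.edge_keys(edge_type)
        pos = np.searchsorted(table, keys)
        pos = np.minimum(pos, len(table) - 1) if len(table) else pos
        if len(table) == 0:
            return np.zeros(len(pairs), dtype=bool)
        return table[pos] == keys

    def neighbor_sets(self, edge_type=None) -> list:
        def build():
            nbrs = [set() for _ in range(self.n_nodes)]
            for u, v in self._edges_of_type(edge_type):
                nbrs[u].add(int(v))
                nbrs[v].add(int(u))
            return nbrs

        return self._cache(("nbrs", edge_type), build)

    def csr_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) of the symmetric adjacency, for fast walks."""

        def build():
            u, v = self.edges[:, 0], self.edges[:, 1]
            src = np.concatenate([u, v])
            dst = np.concatenate([v, u])
            order = np.argsort(src, kind="stable")
            src, dst = src[order], dst[order]
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.add.at(indptr, src + 1, 1)
            np.cumsum(indptr, out=indptr)
            return indptr, dst

        return self._cache(("csr", None), build)

    def edge_type_labels(self) -> list:
        if self.edge_types is None:
            return []
        return sorted(set(self.edge_types))


@dataclass(frozen=True)
class DegreeSummary:
    degree_histogram: dict
    mean_degree: float
    top_k_nodes: tuple
    top_k_mean_degree: float
    top_k_edge_coverage_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "mean_degree",
                    "top_k_mean_degree",
                    "top_k_edge_coverage_fraction",
                    "top_k_nodes",
                ],
                "value": [
                    self.mean_degree,
                    self.top_k_mean_degree,
                    self.top_k_edge_coverage_fraction,
                    ",".join(str(n) for n in self.top_k_nodes),
                ],
            }
        )


def load_edge_list(
    path,
    source_column=None,
    destination_column=None,
    score_column=None,
    min_score=None,
    edge_type_column=None,
    allow_self_loops: bool = False,
    delimiter=None,
) -> Graph:
    """Read a headered TSV/CSV edge list (gzip transparently supported).

    Rows with score below ``min_score`` are dropped, duplicate unordered
    pairs (per edge type) collapsed, and node labels mapped to dense indices
    in sorted order.
    """
    if delimiter is None:
        name = str(path)
        delimiter = "," if name.endswith((".csv", ".csv.gz")) else "\t"
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two identifier columns")
    src = source_column or df.columns[0]
    dst = destination_column or df.columns[1]
    bad = df.index[df[src].isna() | df[dst].isna()]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based numbering
        raise ValueError(f"{path}: malformed row at line {int(bad[0]) + 2}")
    if score_column is not None and min_score is not None:
        scores = pd.to_numeric(df[score_column], errors="coerce")
        if scores.isna().any():
            line = int(scores.index[scores.isna()][0]) + 2
            raise ValueError(f"{path}: non-numeric score at line {line}")
        df = df[scores >= min_score]
    if df.empty:
        raise ValueError(f"{path}: no edges remain after filtering")
    etypes = df[edge_type_column].tolist() if edge_type_column else None
    return Graph.from_label_pairs(
        zip(df[src], df[dst]), edge_types=etypes, allow_self_loops=allow_self_loops
    )


def write_edge_list(g: Graph, path) -> None:
    """Write the standard headered TSV consumed by load_edge_list."""
    labels = np.asarray(g.node_labels, dtype=object)
    data = {
        "source": labels[g.edges[:, 0]],
        "destination": labels[g.edges[:, 1]],
    }
    if g.edge_types is not None:
        data["edge_type"] = g.edge_types
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def degree_vector(g: Graph, edge_type=None) -> np.ndarray:
    """Per-node edge count d(u), optionally restricted to one edge type."""
    edges = g._edges_of_type(edge_type)
    deg = np.zeros(g.n_nodes, dtype=np.int64)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    return deg


def top_k_degree_summary(g: Graph, k: int, edge_type=None) -> DegreeSummary:
    """Degree statistics of the k highest-degree nodes.

    Ties are broken by ascending node index (the coverage fraction depends on
    this rule, hence it is fixed and documented).
    """
    if not 0 < k <= g.n_nodes:
        raise ValueError(f"k={k} out of range (1..{g.n_nodes})")
    deg = degree_vector(g, edge_type)
    # stable sort on -degree keeps ascending index order within ties
    top = np.argsort(-deg, kind="stable")[:k]
    edges = g._edges_of_type(edge_type)
    in_top = np.zeros(g.n_nodes, dtype=bool)
    in_top[top] = True
    covered = int((in_top[edges[:, 0]] | in_top[edges[:, 1]]).sum())
    values, counts = np.unique(deg, return_counts=True)
    return DegreeSummary(
        degree_histogram={int(a): int(b) for a, b in zip(values, counts)},
        mean_degree=float(deg.mean()) if g.n_nodes else 0.0,
        top_k_nodes=tuple(int(i) for i in top),
        top_k_mean_degree=float(deg[top].mean()),
        top_k_edge_coverage_fraction=covered / len(edges) if len(edges) else 0.0,
    )


def largest_connected_component(g: Graph) -> Graph:
    """Induced subgraph on the largest component (ties: component containing
    the smallest node index). Node labels are retained, so the relabeling map
    is recoverable by label lookup."""
    if g.n_nodes == 0:
        return g
    if g.n_edges == 0:
        keep = np.array([0])
    else:
        data = np.ones(2 * g.n_edges)
        rows = np.concatenate([g.edges[:, 0], g.edges[:, 1]])
        cols = np.concatenate([g.edges[:, 1], g.edges[:, 0]])
        adj = csr_matrix((data, (rows, cols)), shape=(g.n_nodes, g.n_nodes))
        n_comp, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels, minlength=n_comp)
        best = int(np.argmax(sizes))  # argmax takes the first = lowest label
        keep = np.flatnonzero(labels == best)
    keep_mask = np.zeros(g.n_nodes, dtype=bool)
    keep_mask[keep] = True
    remap = -np.ones(g.n_nodes, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    emask = keep_mask[g.edges[:, 0]] & keep_mask[g.edges[:, 1]]
    new_edges = remap[g.edges[emask]]
    return Graph(
        n_nodes=len(keep),
        node_labels=tuple(np.asarray(g.node_labels, dtype=object)[keep]),
        edges=new_edges,
        edge_types=g.edge_types[emask] if g.edge_types is not None else None,
        node_types=g.node_types[keep] if g.node_types is not None else None,
    )


def potential_edge_count(n: int) -> int:
    """Number of unordered node pairs, n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n - 1) // 2


def merge_graphs(a: Graph, b: Graph, tag_a: str, tag_b: str) -> Graph:
    """Union two graphs by node label into one heterogeneous graph.

    Existing edge types are kept; untyped edges receive the given tag. A pair
    present in both inputs yields one edge per type (duplicates within a type
    collapse).
    """
    pairs, types = [], []
    node_types: dict = {}
    for g, tag in ((a, tag_a), (b, tag_b)):
        labels = np.asarray(g.node_labels, dtype=object)
        if g.node_types is not None:
            for lab, nt in zip(labels, g.node_types):
                if nt is None:
                    continue
                if node_types.get(lab, nt) != nt:
                    raise ValueError(f"conflicting node types for label {lab!r}")
                node_types[lab] = nt
        gtypes = g.edge_types
        for i, (u, v) in enumerate(g.edges):
            pairs.append((labels[u], labels[v]))
            t = gtypes[i] if gtypes is not None and gtypes[i] is not None else tag
            types.append(t)
    all_labels = set(np.asarray(a.node_labels, dtype=object)) | set(
        np.asarray(b.node_labels, dtype=object)
    )
    return Graph.from_label_pairs(
        pairs,
        edge_types=types,
        node_types=node_types if node_types else None,
        extra_labels=all_labels,
    )


def remove_edges(g: Graph, pairs: np.ndarray, edge_type=None) -> Graph:
    """Graph with the given unordered pairs removed (all types, or one type).

    Used to hold test positives out of the embedding-training graph.
    """
    pairs = _canonical_pairs(pairs)
    drop_keys = set((pairs[:, 0] * g.n_nodes + pairs[:, 1]).tolist())
    keys = g.edges[:, 0] * g.n_nodes + g.edges[:, 1]
    hit = np.fromiter((k in drop_keys for k in keys), dtype=bool, count=len(keys))
    if edge_type is not None:
        hit &= g.edge_types == edge_type
    keep = ~hit
    return Graph(
        n_nodes=g.n_nodes,
        node_labels=g.node_labels,
        edges=g.edges[keep],
        edge_types=g.edge_types[keep] if g.edge_types is not None else None,
        node_types=g.node_types,
    )
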