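"""Per-edge feature construction for the perceptron classifier.

Three families:

* ``degree_pair`` — the two endpoint degrees as a 2-D integer vector, in
  (max, min) canonical order so the feature is invariant to endpoint order.
* four classic topological indices over common neighbors N(u) ∩ N(v):
  Adamic-Adar, Jaccard, resource allocation, preferential attachment.
* ``hadamard`` — elementwise product of the endpoint node embeddings,
  [f(u) ⊡ f(v)]_i = f_i(u) × f_i(v).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import Graph, degree_vector

__all__ = [
    "EdgeFeatureMatrix",
    "degree_pair",
    "topological_index",
    "hadamard",
    "TOPOLOGICAL_SCHEMES",
]

TOPOLOGICAL_SCHEMES = ("adamic_adar", "jaccard", "resource_allocation", "preferential_attachment")


@dataclass(frozen=True)
class EdgeFeatureMatrix:
    scheme: str
    matrix: np.ndarray  # (n_pairs, d)
    edge_index: np.ndarray  # (n_pairs, 2), the pairs in row order

    def __post_init__(self):
        if not np.isfinite(self.matrix).all():
            raise ValueError("edge features must be finite")

    def to_frame(self, g: Graph) -> pd.DataFrame:
        labels = np.asarray(g.node_labels, dtype=object)
        df = pd.DataFrame(
            self.matrix,
            columns=[f"{self.scheme}_{i}" for i in range(self.matrix.shape[1])],
        )
        df.insert(0, "destination", labels[self.edge_index[:, 1]])
        df.insert(0, "source", labels[self.edge_index[:, 0]])
        return df


def _as_pairs(pairs) -> np.ndarray:
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def degree_pair(g: Graph, pairs, edge_type=None) -> EdgeFeatureMatrix:
    """Row = (max(d(u), d(v)), min(d(u), d(v))) — raw integers, no scaling."""
    pairs = _as_pairs(pairs)
    deg = degree_vector(g, edge_type)
    du, dv = deg[pairs[:, 0]], deg[pairs[:, 1]]
    matrix = np.column_stack([np.maximum(du, dv), np.minimum(du, dv)]).astype(float)
    return EdgeFeatureMatrix("degree_pair", matrix, pairs)


def topological_index(
    g: Graph, pairs, scheme: str, exclude_self_edge: bool = False, edge_type=None
) -> EdgeFeatureMatrix:
    """One of the four classic link-prediction indices.

    AA = Σ_w 1/ln d(w); Jaccard = |N∩|/|N∪|; RA = Σ_w 1/d(w);
    PA = d(u)·d(v), with w ranging over common neighbors of u and v.
    With ``exclude_self_edge`` the query pair's own edge (if present) is
    removed from the neighborhoods before scoring, so positive training edges
    are not scored with the answer leaked into their own neighborhood.
    """
    if scheme not in TOPOLOGICAL_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r} (expected one of {TOPOLOGICAL_SCHEMES})")
    pairs = _as_pairs(pairs)
    deg = degree_vector(g, edge_type)
    nbrs = g.neighbor_sets(edge_type)
    values = np.zeros(len(pairs), dtype=float)
    warned = False
    for i, (u, v) in enumerate(pairs):
        u, v = int(u), int(v)
        nu, nv = nbrs[u], nbrs[v]
        du, dv = int(deg[u]), int(deg[v])
        if exclude_self_edge and v in nu:
            nu = nu - {v}
            nv = nv - {u}
            du -= 1
            dv -= 1
        if scheme == "preferential_attachment":
            values[i] = du * dv
            continue
        common = nu & nv
        if scheme == "jaccard":
            union = len(nu | nv)
            values[i] = len(common) / union if union else 0.0
        elif scheme == "resource_allocation":
            values[i] = sum(1.0 / deg[w] for w in common)
        else:  # adamic_adar
            total = 0.0
            for w in common:
                dw = int(deg[w])
                if exclude_self_edge and (w == u or w == v):
                    dw -= 1  # unreachable for simple graphs, kept for safety
                if dw <= 1:
                    if not warned:
                        warnings.warn(
                            "skipping degree-1 common neighbor in Adamic-Adar (ln 1 = 0)",
                            stacklevel=2,
                        )
                        warned = True
                    continue
                total += 1.0 / math.log(dw)
            values[i] = total
    return EdgeFeatureMatrix(scheme, values.reshape(-1, 1), pairs)


def hadamard(embedding, pairs) -> EdgeFeatureMatrix:
    """Elementwise product of endpoint embeddings.

    For asymmetric embedders (HOPE, second-order LINE) the source matrix
    supplies u and the destination/context matrix supplies v.
    """
    pairs = _as_pairs(pairs)
    primary = embedding.primary
    secondary = embedding.secondary if embedding.secondary is not None else primary
    if pairs.size and pairs.max() >= primary.shape[0]:
        raise ValueError("pair endpoint not covered by the embedding")
    matrix = primary[pairs[:, 0]] * secondary[pairs[:, 1]]
    return EdgeFeatureMatrix("hadamard", matrix, pairs)
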