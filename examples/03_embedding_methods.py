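"""Train the seven shallow embedders on a small graph and inspect them.

Uses reduced walk counts, epochs and dimensions so the script finishes in
about a minute; the defaults mirror the published settings (walk length 128,
100 walks per node, dimension 100).
"""

import numpy as np

from negsel import (
    EMBEDDING_METHODS,
    SyntheticConfig,
    default_config,
    embed_graph,
    hub_skewed_graph,
)

g = hub_skewed_graph(SyntheticConfig(n_nodes=400, n_positive_edges=250, n_hubs=10, seed=2))
print(f"graph: {g.n_nodes} nodes, {g.n_edges} edges\n")

for method in EMBEDDING_METHODS:
    cfg = default_config(
        method, dimension=16, epochs=3, walk_length=16, iterations=4, negative_samples=5
    )
    emb = embed_graph(g, method, cfg, seed=5)
    norms = np.linalg.norm(emb.primary, axis=1)
    tail = f", final loss {emb.loss_history[-1]:.3f}" if emb.loss_history else ""
    two = " (separate source/destination matrices)" if emb.secondary is not None else ""
    print(f"{method:20s} -> {emb.primary.shape} mean row norm {norms.mean():.3f}{tail}{two}")

print(
    "\nEach row is one node's learned vector; Hadamard products of row pairs"
    "\nbecome edge features for the perceptron (see example 04)."
)
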