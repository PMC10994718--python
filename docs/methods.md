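# Methods

## Samplers

A negative-edge sampler proposes node pairs that are not edges of the
reference graph. Both samplers here generate candidates i.i.d. and apply
rejection: self-loops are always rejected; candidates colliding with an
existing edge of *any* edge type are rejected when collision avoidance is on
(a protein-association edge must not serve as an interaction negative);
duplicate pairs within one sampled set are rejected by default. Rejection is
capped at 100·m candidate draws, after which the sampler raises — on a
near-complete graph rejection sampling is the wrong tool. The pre-rejection
candidate stream is exposed (`candidate_stream`) so the endpoint marginals
can be tested directly against enumeration.

**UNS** draws both endpoints uniformly from V. Its pre-rejection endpoint
marginal is exactly uniform.

**DANS** draws, per endpoint, one edge uniformly from E and orients it with
an independent fair coin; the candidate joins the source of the first
oriented edge to the destination of the second. For an undirected graph the
coin makes endpoint choice exactly degree-proportional, P(u) = d(u)/(2|E|):
node u appears as the source of an oriented edge in d(u) of the 2|E|
(edge, orientation) pairs. The orientation coin is the undirected
generalization of the directed pseudocode; without it, storing each pair as
(min, max) would bias endpoint roles.

**Diagnostics.** The preferential attachment of a pair, PA = d(u)·d(v),
summarizes how hub-like it is. `pa_divergence` compares a negative set's PA
multiset with the positives' by the two-sample Kolmogorov–Smirnov statistic
and by the Wasserstein-1 distance on log1p(PA) — the log scale because PA
spans orders of magnitude on scale-free graphs, and KS because it is
invariant to that choice.

## Evaluation protocol

"Ten-fold cross validation with training size 0.75" is realized as ten
Monte-Carlo repeated holdouts at a 75/25 positive split — standard k-fold
at k = 10 would force a 0.9 train fraction, so repeated holdout is the only
protocol consistent with both numbers. Per replicate, training negatives
(|train positives| of them) and evaluation negatives (|test positives|) are
sampled independently with their respective strategies, collision-checked
against the full graph, giving balanced classes in both phases. The
perceptron is a single linear layer with logistic output trained by
mini-batch gradient descent on binary cross-entropy (100 epochs, rate 0.01,
batch 32 — deliberately unremarkable defaults, since the effect under study
is in the evaluation data, not the model). Degree features stay raw
integers; embedding features are standardized with moments fitted on the
training split only.

The 2×2 grid crosses the training-phase sampler with the evaluation-phase
sampler. Within a replicate the positive split is shared across all
conditions and negatives are keyed by (replicate, phase, strategy), so the
design is paired; `inflation_test` runs the one-sided paired t-test that
eval=UNS exceeds eval=DANS. Metrics are MCC (zero returned on a zero
denominator), AUROC, AUPRC and F1, the latter two via scikit-learn.

**Leakage control.** Test positive edges are removed from the graph before
embeddings are trained (otherwise the embedder sees the test labels); this
is toggleable (`remove_test_edges=False`) for ablation. Structural features
(degree pairs, topological indices) are computed on the full reference
graph — they describe the graph as a user would see it, and removing test
edges would perturb every candidate's degree, not just the test pairs'.
The topological indices optionally exclude the query pair's own edge from
its neighborhoods (`exclude_self_edge`), since whether positive training
edges should be scored with their own edge present is genuinely ambiguous;
the default keeps it, matching the graph-as-given convention.

## Embedders

Walk corpora are first-order uniform-neighbor walks, by default 100 walks
per source node of length 128. The `max_neighbors` cap (100) is implemented
as per-step uniform subsampling of the neighbor list; a uniform choice from
a uniformly drawn subset is marginally uniform, so the walker simply draws
uniformly — the parameter is kept for interface fidelity. Walklets corpora
take every i-th token of each walk from each of the i phase offsets
(i = 1..window), so adjacent tokens at scale i are exactly i hops apart;
one embedding is trained per scale and the total dimension is split evenly
across scales and concatenated, following the original multi-scale
formulation.

SkipGram and CBOW are trained with negative sampling: 10 noise tokens per
positive from the corpus unigram distribution raised to 3/4, learning-rate
decay ×0.9 per epoch, 30 epochs at rate 0.010, window 5 (DeepWalk) or 4
(Walklets). CBOW aggregates the context window by the mean of its input
vectors. The embedding is the input-layer weight matrix. LINE (100 epochs,
rate 0.050) optimizes a logistic edge-existence objective over both
orientations of each edge against degree^0.75 noise endpoints, without
false-negative filtering; second order keeps a separate context matrix.
These phase-1 noise distributions are internal to embedding training and
independent of the UNS/DANS evaluation samplers. LINE's matrices are
initialized at scale 1/√d (a near-zero init is a fixed point of the
shared-matrix first-order objective). HOPE computes the common-neighbor
proximity S = A², whose diagonal is the node degree (kept by default,
zeroable), and returns U_k√Σ_k and V_k√Σ_k from the truncated SVD — the
optimal rank-k factorization, so the reconstruction error equals the sum of
squared discarded singular values exactly.

All trainers are plain numpy; a fixed seed reproduces matrices bit-for-bit.
Embedding dimension defaults to 100 (the convention of the library family
these methods come from); experiments in the tests and acceptance script
run at dimension 32 and reduced walk counts/epochs, stated below.

## Synthetic graphs

`scale_free_graph` draws degrees from a zeta distribution (minimum degree
1, default γ = 2.3, giving mean degree ≈ 2.8) truncated at the structural
cutoff √(⟨k⟩·n), wires them with the configuration model, collapses
parallel edges, drops self-loops, and restores lost stubs by a bounded
rewiring pass (erroring if more than 5% of stubs remain). The cutoff is
required: above it a simple uncorrelated graph cannot realize the hub's
stubs. The configuration model was chosen over preferential-attachment
growth because it makes γ directly controllable, and the bias effect
depends on degree skew, not on a growth mechanism. `target_mean_degree` is
a diagnostic (warn if realized mean is >25% off), not a constraint — with a
zeta law the mean is already determined by γ.

`hub_skewed_sli_overlay` adds a second edge type concentrated on the
top-degree nodes of the base: exactly round(target·m) overlay edges join a
uniform hub to a uniform non-isolated node, the rest join uniform non-hub
pairs. The hub-branch count is exact rather than Bernoulli so the realized
coverage stays within the ±5-percentage-point contract even for small m.
The default configuration (3000 nodes, 2445 overlay edges, 20 hubs at 85.1%
coverage) echoes a literature-curated synthetic-lethality network in scale
and skew; it reproduces a top-20 mean degree of ~105 against an overall
mean of ~3. What it does *not* emulate: biological community structure,
node-type semantics, correlated study bias between the two layers, or any
edge semantics at all — so passing experiments demonstrate that the
*sampling* machinery behaves as analyzed on degree-skewed topology, not
that any particular biological prediction is correct.

`signal_planted_graph` is a two-block graph (p_in ≫ p_out) giving features
and embedders genuine learnable signal for smoke tests.

## Experiment scales

Problem sizes used by the tests and the acceptance script, chosen so the
full battery runs in a few minutes on one core: PA-distribution comparison
on the default 3000-node graph with negatives = 100× positives, 20 runs;
degree-feature grid on the same graph, 10 replicates; degree-homogeneous
control on G(n=800, m=8000) — mean degree 20, where the relative degree
spread 1/√20 is small enough that positives and uniform negatives are
indistinguishable by degree (sparser ER graphs are *not* degree-homogeneous
in this sense: size-biased endpoint degrees alone yield an MCC gap ≈ 0.15
at mean degree 6); Walklets-SkipGram grid on an 800-node, 600-positive
graph at dimension 32, 5 walks of length 24 per node, 3 epochs, 3
replicates. At that reduced scale the DANS-trained classifier arm sits at
chance and only the pooled and train=UNS comparisons are stable across
seeds; the full-scale effect is reported per arm by the degree-feature
grid.

## Numerical conventions

MCC returns 0 whenever a denominator factor is zero. AUROC uses rank
statistics with ties averaged. Ties in top-k degree selection break by
ascending node index (coverage fractions depend on this, so it is fixed).
Node indices are assigned by lexicographic label sort for cross-platform
reproducibility. All randomness flows from a master seed through a
spawn-key seed sequence keyed by stage-name tags, so adding a stage never
perturbs another stage's stream; identical seeds give byte-identical
outputs, including CLI artifacts (provenance sidecars carry no timestamps).

## Known limitations

The embedders are reference implementations in numpy: faithful and
deterministic, but not tuned for graphs beyond ~10⁴ nodes. DANS matches the
*marginal* degree distribution of positives, not their joint (degree,
degree) structure; positives whose two endpoints' degrees are correlated
can still be distinguished from DANS negatives. Directed graphs are
represented but the experiment drivers assume undirected edges. No
hyperparameter search is performed anywhere, by design.
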