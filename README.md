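# negsel

Negative-edge sampling strategies and bias-aware evaluation of link
prediction on degree-skewed biomedical graphs.

## The problem

Link prediction in biomedical knowledge graphs (protein–protein
associations, synthetic lethality, drug–target edges) is almost always
evaluated against *sampled* negatives, because databases record positives
only. The standard recipe — **uniform node sampling (UNS)** — draws both
endpoints of each negative uniformly from the node set. But biomedical
graphs are approximately scale-free (P(k) ~ k^−γ): positives concentrate on
a few heavily studied hub genes while uniform negatives are overwhelmingly
low-degree pairs. A classifier can then separate positives from negatives
by degree alone, and the measured performance says little about the real
task of ranking candidate edges *around the hubs*.

**Degree-aware node sampling (DANS)** removes this artifact. To draw one
negative, sample two existing edges e₁ = (s₁, d₁) and e₂ = (s₂, d₂)
uniformly from E (orienting each with a fair coin) and join s₁ to d₂. Each
endpoint is then chosen with probability

    P(u) = d(u) / (2|E|),

i.e. proportionally to its degree, so the negatives mimic the degree
profile — and the preferential attachment PA = d(u)·d(v) — of the
positives. Collisions with existing edges are handled by resampling.

The library provides both samplers plus everything needed to *measure* the
bias they induce: seven shallow node embedders (DeepWalk/Walklets ×
CBOW/SkipGram, first/second-order LINE, HOPE), per-edge features (degree
pairs, Adamic–Adar, Jaccard, resource allocation, preferential attachment,
Hadamard products of embeddings), a perceptron classifier with
MCC/AUROC/AUPRC/F1, Monte-Carlo cross-validation with a paired 2×2
train-sampler × eval-sampler grid, and seeded synthetic generators for
scale-free, hub-skewed heterogeneous graphs — so every claim is testable
without downloading external data.

## Worked example

`examples/01_sampling_bias.py` builds the default synthetic graph — a
scale-free association layer with a hub-dominated interaction layer on top
(3000 nodes, 2445 positive edges, 20 hubs covering ~85% of them) — and
compares negative sets of 100× the positives:

```
graph: 3000 nodes, 5890 edges, 2445 positive (sli) edges
top-20 hub coverage of positives: 85.1% (top-20 mean degree 105.0)

mean PA  positives:    723.5
mean PA  DANS negs:   1271.4
mean PA  UNS  negs:     14.1

KS(positives, UNS)  = 0.842
KS(positives, DANS) = 0.459
```

UNS negatives live two orders of magnitude below the positives in
preferential attachment; DANS negatives sit beside them.
`examples/02_degree_feature_inflation.py` shows what that does to measured
performance. A perceptron trained on nothing but the two endpoint degrees,
evaluated over ten Monte-Carlo 75/25 holdouts:

```
  train=dans eval=dans  MCC = +0.185 ± 0.162
  train=dans eval=uns   MCC = +0.465 ± 0.343
  train=uns  eval=dans  MCC = +0.370 ± 0.038
  train=uns  eval=uns   MCC = +0.823 ± 0.032

train=uns: eval=UNS exceeds eval=DANS by +0.454 (p = 1.5e-13)
```

An MCC of 0.82 from degree features alone is not link prediction — it is
the evaluation sampler leaking degree information. Under degree-matched
negatives the same model drops to 0.37. The other examples train the
embedding methods (`03`), repeat the experiment with Walklets-SkipGram +
Hadamard features (`04`), and drive the whole pipeline from the shell
(`05`).

## Command line

```bash
negsel simulate --n-nodes 3000 --seed 1 --out graph.tsv
negsel sample   --graph graph.tsv --strategy dans --num 1000 --seed 2 --out neg.tsv
negsel embed    --graph graph.tsv --method walklets-skipgram --dim 32 --out emb.tsv
negsel evaluate --graph graph.tsv --positive-type sli --features degree \
                --train-sampler uns --eval-sampler dans --out res.tsv
negsel grid     --graph graph.tsv --positive-type sli --features degree \
                --out-dir results/
negsel pipeline --master-seed 1 --out-dir run/
```

All outputs are headered TSVs with JSON provenance sidecars; identical
seeds give byte-identical artifacts.

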