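#!/usr/bin/env bash
# End-to-end run from the shell: simulate a hub-skewed graph, sample
# negatives with both strategies, and run the 2x2 sampler grid.
set -euo pipefail
out=$(mktemp -d)

negsel simulate --n-nodes 500 --n-positive-edges 300 --n-hubs 10 --seed 1 \
    --out "$out/graph.tsv"
negsel sample --graph "$out/graph.tsv" --strategy uns  --num 100 --seed 2 \
    --out "$out/neg_uns.tsv"
negsel sample --graph "$out/graph.tsv" --strategy dans --num 100 --seed 2 \
    --out "$out/neg_dans.tsv"
negsel grid --graph "$out/graph.tsv" --positive-type sli --features degree \
    --replicates 5 --seed 3 --out-dir "$out/grid"

echo "--- results ---"
cat "$out/grid/results_summary.json"
echo "artifacts in $out"
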