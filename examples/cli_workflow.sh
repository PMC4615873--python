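#!/usr/bin/env bash
# The same workflow from the shell: simulate -> correct -> evaluate.
set -euo pipefail

out=$(mktemp -d)
echo "working in $out"

readfix simulate -od "$out" --n-transcripts 8 --n-reads 3000 \
    --error-rate 0.005 --seed 11

readfix correct -s "$out/reads.fq" -k 23 -od "$out/corrected"

readfix evaluate --raw "$out/reads.fq" \
    -i "$out/corrected/reads.cor.fq" \
    --truth "$out/truth.tsv" -o "$out/metrics.tsv"

cat "$out/metrics.tsv"
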