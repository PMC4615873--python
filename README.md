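# readfix

Error correction for Illumina RNA-seq reads.

Most short-read error correctors assume roughly uniform genome coverage:
a k-mer seen only a few times is probably an error. That assumption fails
on transcriptome data, where coverage tracks expression — a 5× k-mer may
be noise on a 500× gene yet perfectly genuine on a rare transcript.
`readfix` implements a k-spectrum corrector built for this setting: it is
intended for anyone cleaning bulk or single-cell RNA-seq reads ahead of
transcript assembly, alignment, or quantification.

## Method

A De Bruijn graph is built from all k-mers occurring more than once in
the read set (canonical form, strands pooled), with their multiplicities
M(u). For each read the corrector finds the closest graph path —
the likely transcript of origin — and substitutes the read onto it:

1. **Local solidity threshold.** A k-mer is *solid* when its count
   exceeds `f(t, r) = min(g(t), h(r))`, where
   `g(t) = αt + 6√(αt)` with `t = max_c M(S(u, c))`, the strongest of the
   four possible continuations at the preceding graph node, and
   `h(r) = g(x)` with `x` the multiplicity before the first sharp
   (>2-fold) drop in the read's sorted k-mer multiplicity curve. The
   variation coefficient α is calibrated per dataset from high-count
   k-mers (the 95th-percentile ratio of second-highest to highest
   successor counts), so thresholds scale with local coverage instead of
   being global.
2. **Minimum-change path search.** Starting from the read's longest
   stretch of solid bases, the graph is walked one base at a time in both
   directions. Every solid continuation is explored (to allow splice
   variants and paralogs); disagreements with the read are counted as
   corrections, capped per read and per k-base window, and the surviving
   path with the fewest changes rewrites the read.
3. **Refinements.** Nearby corrections whose pre-correction k-mers have
   similar counts (ratio in (0.5, 2)) are reverted — the read likely
   comes from a low-expression paralog, not from clustered errors. Reads
   still over budget get a stepwise lowered `h(r)` (next multiplicity
   drop) and are flagged *unfixable* (and left unchanged) if that fails.
   Mostly-A/T k-mers (polyA tails) are ignored throughout. Mate pairs are
   corrected under the smaller of their two read-level thresholds, which
   protects mate-private low-expression isoform sequence.

The package also ships a synthetic-data generator (tiered-expression
transcriptomes, paralogs, polyA tails, reads with ground-truth
substitution errors) and a per-base evaluator (TP/FP/FN, recall,
precision, F-score), so the whole system is testable offline.

## Worked example

`examples/worked_example.py` runs the classic k=4 illustration: read
`AAGTCATAA` whose suffix after the solid `AAGTC` prefix is an artifact.

```
read: AAGTCATAA  (k = 4, alpha = 0.05)
successor counts of AGTC: {'A': 4, 'C': 494, 'G': 450, 'T': 1}
  -> t = max = 494; the read's own continuation GTCA has count 4 and is pruned
read-level threshold h(r) = 55.0; anchor k-mers (0, 2) (the solid AAGT/AGTC stretch)
surviving paths:
  AAGTCGTTA  corrections=2 min_count=420
  ...
  AAGTCCGTC  corrections=4 min_count=480
selected (minimum change): AAGTCGTTA
corrected read: AAGTCGTTA  status=corrected
```

The read's own path and the count-1 `GTCT` branch fall below the local
threshold (≈54.5) and are pruned; of the surviving branches, the
two-correction path beats the four-correction one despite slightly lower
counts.

`examples/simulate_correct_evaluate.py` runs the full pipeline on 4,000
simulated 100 bp reads (12 transcripts, 0.5% error rate, k=23):

```
overall: TP=2008 FP=0 FN=48  recall=0.977 precision=1.000 F=0.988
  high    recall=0.995 precision=1.000
  medium  recall=0.696 precision=1.000
  low     recall=0.000 precision=0.000
```

Recall drops with expression tier, as expected: low-expression reads
leave mostly singleton k-mers, which never enter the graph. TP + FN
always equals the number of injected errors.

Other examples: `adaptive_thresholds.py` (the g/h/f algebra),
`paired_end_correction.py` (mate-pair threshold sharing),
`cli_workflow.sh` (the same pipeline from the shell).

## Command line

```sh
readfix simulate -od sim --n-reads 20000 --seed 1
readfix correct  -s sim/reads.fq -k 23 -od out      # or -1/-2 for pairs
readfix evaluate --raw sim/reads.fq -i out/reads.cor.fq \
                 --truth sim/truth.tsv -o metrics.tsv
readfix count    -s sim/reads.fq -k 23 -o table.tsv
```

Corrected reads keep their order and pairing; headers gain ` cor` or
` unfixable_error` suffixes (disable with `--no-tag`). Algorithm knobs:
`--alpha`, `--drop-factor`, `--max-cor`, `--max-cor-window`,
`--max-paths`, `--min-count`, `--stranded`.

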