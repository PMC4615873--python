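# Methods

## Problem setting

Substitution errors in Illumina RNA-seq reads corrupt k-mers and inflate
graph complexity for assemblers and aligners. k-spectrum correctors fix a
read by replacing untrusted k-mers with trusted ones, where "trusted"
normally means "count above a global cutoff". Transcriptome coverage is
proportional to expression and spans four to five orders of magnitude, so
a single cutoff either destroys rare transcripts or trusts every error on
abundant ones. `readfix` replaces the global cutoff with a threshold
assembled per k-mer, per read.

## The k-mer graph

`dbg.build_table` performs exact two-pass counting: count every k-mer
window, then discard counts below `min_count` (default 2). Errors are
overwhelmingly singletons, so the surviving table approximates the true
transcript k-mer spectrum; its memory is proportional to the number of
distinct multi-occurrence k-mers, which at desk scale is small. A k-mer
and its reverse complement are pooled under the lexicographically smaller
of the two, making the table usable on unstranded libraries; `stranded`
disables pooling (counting only — the corrector itself assumes canonical
tables). Windows containing non-ACGT characters are never counted and
never solid. The De Bruijn graph is implicit: `successor_counts(u)`
returns the multiplicities of `u[1:] + c` for the four bases; the 3'→5'
analogue is the same query on the reverse complement.

## Thresholds

**k-mer level.** `g(t) = αt + 6√(αt)` with `t` the largest multiplicity
among the four continuations at the current node. Interpreting αt as the
expected count of a spurious sibling of a t-count k-mer, g is that mean
plus six standard deviations of a Poisson-like noise term: a continuation
must clear it to be trusted.

**Calibrating α.** For up to `sample_size` (10⁶) stored k-mers with
multiplicity above `high_count_cutoff` (10³), the ratio of second-highest
to highest successor multiplicity is collected (k-mers with fewer than
two nonzero successors are skipped — their ratio, 0, carries no signal);
α is the smallest ratio larger than 95% of the sample, operationalized as
the 1-based order statistic ⌊0.95·n⌋+1, capped at n. This makes α the
scale at which genuinely co-occurring alternatives (SNPs, isoforms,
paralogs) stop looking like noise. Sampling is seeded and without
replacement; when no k-mer qualifies (small fixtures and desk-scale
simulations), α falls back to 0.05 with a logged warning — near the value
high-coverage datasets typically calibrate to — and can always be pinned
with `--alpha`.

**Read level.** Sorting a read's k-mer multiplicities decreasingly gives
a curve with plateaus at the expression tiers the read touches. `h(r) =
g(x)` where `x` is the multiplicity before the first >2-fold drop
(`drop_factor`). When no drop exists the curve is a single tier and `x`
is its minimum positive value. `drop_index` selects later drops — the
relaxation ladder used for unfixable reads. Zero-count k-mers are
excluded from the curve, as are polyA k-mers (their counts mix many
transcripts' tails and would fake a tier).

**Combined.** `f(t, r) = min(g(t), h(r))`; comparisons are strict
(`count > f`), so even f = 0 excludes absent and singleton k-mers.

## Solidity and anchoring

A base's *variant maximum* is the largest multiplicity among the four
single-base variants at its position, probed through both the k-mer
ending at the base and the k-mer starting at it (`variant_max_counts`);
probing both directions keeps a competing variant visible no matter which
side its shared context lies on, and makes the mask strand-symmetric. The
k-mer at position i is *solid* when its count exceeds
`min(g(t_i), h)` with `t_i` the largest variant maximum over the bases it
covers. Two consequences matter:

* an error k-mer is shadowed by its true variant (t ≈ coverage), so even
  an error that recurs a few times at high coverage stays non-solid;
* a genuine low-count k-mer with no strong competitor justifies itself
  (t equals its own count), so rare transcripts can anchor.

Bases covered by a run of two or more consecutive solid k-mers are solid
bases; the longest such run (leftmost on ties) is the anchor, and solid
bases are never altered.

## Path search

From the anchor's edges a depth-first search extends one base per step;
at each step the admissible continuations are the successors with count
above `f(t, r)`, the read base explored first, alternatives in decreasing
count order. Choosing an alternative records a correction; paths
exceeding the read budget (8) or the per-k-window budget (4) are pruned.
When explored branches exceed `max_paths` (100) the read budget is
lowered by one and the search restarts; at budget 0 the search gives up.
The 3'→5' pass is a 5'→3' pass on the reverse complement with corrections
mapped back; each non-anchor position is reachable from exactly one
direction, so the passes never conflict.

Among complete paths the winner has the fewest corrections; ties go to
the larger minimum k-mer count along the path, then to the candidate
retaining the read base at the leftmost position where the tied
candidates differ. On small instances the winner's correction count is
verified in the test suite against an exhaustive-enumeration oracle.

A step whose next read k-mer is polyA accepts the read base untested
(polyA k-mers are transparent); corrections into polyA k-mers are never
proposed. A node with no stored continuation at all ends the path — the
corrector does not guess across coverage gaps, which keeps unfixable
reads unchanged.

## Refinements

**Clustered corrections.** Under a random-error model two errors within
k bases of each other are rare; such clusters usually mean the read comes
from a low-expression paralog of a stronger transcript. For corrected
positions i < j with j − i < k, the multiplicities of the *uncorrected*
read's k-mers ending at i and j are compared; a ratio strictly inside
(0.5, 2) reverts both corrections, and corrections within k of a reverted
one are iteratively re-tested against it. A zero-count k-mer lies on no
stored path and never triggers reversion — clustered genuine errors
(whose k-mers are absent) therefore stay corrected.

**Unfixable reads.** If the net (post-reversion) corrections exceed
either budget, or no admissible path reaches a read end, `h(r)` is
lowered to the next multiplicity drop and the attempt repeats, up to
`max_relaxations` (4) times or until the curve has no further drop. Reads
that still fail are emitted unchanged with status `unfixable` — never
dropped, so downstream pairing survives. Reads shorter than k, and reads
consisting entirely of polyA k-mers, pass through as `clean`.

**Paired ends.** Both mates are corrected under
`min(h(r1), h(r2))`: a fragment from a low-expression isoform may put one
mate on isoform-private (low-count) sequence and the other on sequence
shared with stronger transcripts, and the smaller threshold represents
the originating transcript. The common threshold replaces each mate's own
h for the first attempt; subsequent relaxation steps use the minimum of
the common threshold and the mate's own ladder value, so the sequence of
thresholds is non-increasing.

## Synthetic data

`simulate` emulates the structure, not the letter, of a real RNA-seq
experiment: i.i.d.-uniform random transcripts (default 20, 500–1,500 bp)
on low/medium/high expression tiers weighted 1:20:400; optional paralog
pairs (a copy with exactly d substitutions at a configurable abundance
ratio) and polyA tails; reads drawn proportional to abundance × effective
length with uniform starts and random strand (paired mode draws
normal-length fragments and emits reverse-complement second mates); flat
(or linearly 3'-ramped) per-base substitution errors with the changed
positions and original bases recorded as ground truth. Defaults mirror
the package's reference benchmark: 20,000 × 100 bp single-end reads at a
0.5% error rate, corrected with k = 23. polyA tails and paralogs default
to 0 and are switched on where a test targets those refinements.

What the generator does *not* emulate: real transcript sequence
composition (repeats beyond the explicit paralogs, low-complexity
regions), splicing-graph isoform structure, empirical position/context
error profiles, indels, and quality-score realism. Passing tests
therefore demonstrate the algorithm's behavior under its own model
assumptions — informative about the machinery, not a claim about any
particular instrument's error process.

Everything is deterministic under the configured seed; the mutated reads
and the truth records are mutually consistent by construction (reverting
all truths reproduces the clean reads exactly).

## Evaluation

Per base, against the ground truth: an error base restored to its
original nucleotide is a true positive; an error base unchanged or
changed to another wrong base is a false negative; an error-free base
that was changed is a false positive (true negatives are not tracked).
Recall = TP/(TP+FN), Precision = TP/(TP+FP), F their harmonic mean; a
zero denominator reports 0 with a `degenerate` flag, which tiny fixtures
do hit. Unfixable reads are scored like any other — their unchanged
errors count as false negatives. Tier-stratified counts are a group-by
over the same per-read counts and sum to the overall counts; TP + FN
equals the number of injected errors on every run.

On the reference benchmark (seed 1) the corrector reaches overall recall
≈ 0.99 at precision 1.0, with recall ordered high > medium > low tier —
low-tier reads (≈0.7× coverage) leave mostly singleton k-mers, which
never enter the graph; these numbers are recomputed by
`tests/test_acceptance.py` on every run, not quoted from anywhere.

## Numerical and design choices

* 0-based, half-open coordinates internally; substitutions only, so
  sequence length is always preserved.
* Search order is fully deterministic (fixed nucleotide order,
  stable tie-breaks), giving byte-identical outputs under fixed seeds.
* Correction budgets (8 per read, 4 per k-window) are permissive enough
  for a 1%-error 100 bp read while catching paralog misassignment; both
  are flags.
* The budget check applies to net corrections, after reversion.
* Desk-scale problem sizes throughout (20k reads, tables of ~10⁵ k-mers)
  keep the full suite in tens of seconds on one core; the algorithm
  itself is independent of these sizes.

## Known limitations

* Indels are out of scope; a single indel shifts every downstream k-mer
  and such reads typically end unfixable.
* Quality scores are read and passed through but never consulted.
* Exact in-memory counting is the right trade-off at desk scale but not
  for 10⁸-read datasets, which would want probabilistic counting.
* `stranded` counting is exposed for table inspection, but correction
  assumes strand-pooled tables.
* Single-threaded by design.
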