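"""Per-base scoring of corrections against simulated ground truth.

A true positive is an error base restored to its original nucleotide; a
false negative is an error base left unchanged or changed to another
wrong base; a false positive is an error-free base that was changed.
Error-free unchanged bases are not tracked. Recall = TP/(TP+FN),
Precision = TP/(TP+FP), F = their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

from .io_fastx import ReadRecord
from .simulate import ErrorTruth

_EMPTY_TRUTH = ErrorTruth("", [], [])


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


@dataclass
class Metrics:
    recall: float
    precision: float
    f_score: float
    degenerate: bool = False  # some denominator was zero


def _seq(x) -> str:
    return (x if isinstance(x, str) else x.sequence).upper()


def classify_bases(mutated, corrected, truth: Optional[ErrorTruth]) -> EvalCounts:
    """Score one read position by position against its truth record.

    ``truth`` may be ``None`` for a read with no injected errors.
    """
    mseq, cseq = _seq(mutated), _seq(corrected)
    if len(mseq) != len(cseq):
        raise ValueError(
            f"length mismatch: mutated {len(mseq)} vs corrected {len(cseq)}")
    truth = truth or _EMPTY_TRUTH
    originals = dict(zip(truth.positions, truth.original_bases))
    tp = fp = fn = 0
    for pos, orig in originals.items():
        if cseq[pos] == orig.upper():
            tp += 1
        else:
            fn += 1
    for pos, (mb, cb) in enumerate(zip(mseq, cseq)):
        if mb != cb and pos not in originals:
            fp += 1
    return EvalCounts(tp, fp, fn)


def metrics(counts: EvalCounts) -> Metrics:
    """Recall/precision/F; a zero denominator reports 0 and sets the flag."""
    degenerate = False
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if recall + precision == 0:
        f, degenerate = 0.0, True
    else:
        f = 2 * recall * precision / (recall + precision)
    return Metrics(recall, precision, f, degenerate)


def evaluate_run(mutated: Sequence[ReadRecord], corrected: Sequence,
                 truths: Mapping[str, ErrorTruth]
                 ) -> Tuple[EvalCounts, Dict[str, EvalCounts]]:
    """Aggregate counts overall and stratified by expression tier.

    ``corrected`` entries may be ReadRecords, CorrectionResults, or plain
    sequences, matched to ``mutated`` by order. Unfixable reads are scored
    like any other (their unchanged errors count as FN). Reads without a
    tier label land in the ``""`` stratum.
    """
    if len(mutated) != len(corrected):
        raise ValueError("mutated and corrected runs differ in length")
    overall = EvalCounts()
    by_tier: Dict[str, EvalCounts] = {}
    for mrec, crec in zip(mutated, corrected):
        cseq = getattr(crec, "corrected_sequence", None)
        if cseq is None:
            cseq = crec if isinstance(crec, str) else crec.sequence
        truth = truths.get(mrec.read_id)
        counts = classify_bases(mrec.sequence, cseq, truth)
        overall = overall + counts
        tier = truth.tier if truth else ""
        by_tier[tier] = by_tier.get(tier, EvalCounts()) + counts
    return overall, by_tier


def report_lines(overall: EvalCounts, by_tier: Mapping[str, EvalCounts]
                 ) -> Iterable[str]:
    """TSV report: one row overall plus one per tier."""
    yield "stratum\ttp\tfp\tfn\trecall\tprecision\tf_score\tdegenerate"

    def row(name: str, c: EvalCounts) -> str:
        m = metrics(c)
        return (f"{name}\t{c.tp}\t{c.fp}\t{c.fn}\t{m.recall:.6f}\t"
                f"{m.precision:.6f}\t{m.f_score:.6f}\t{int(m.degenerate)}")

    yield row("overall", overall)
    for tier in sorted(by_tier):
        yield row(tier or "unlabeled", by_tier[tier])
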