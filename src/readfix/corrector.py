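"""Minimum-change path search over the k-mer graph, with refinements.

A read is corrected by anchoring on its longest stretch of solid bases
(bases covered by a run of two or more k-mers whose counts clear the
read-level threshold), then extending the anchor one base at a time in
both directions. At every step the admissible continuations are the
successor k-mers whose multiplicity clears the local threshold
f(t, r) = min(g(t), h(r)); a continuation that disagrees with the read
base counts as a correction. Among all surviving paths that reach the
read end, the one with the fewest corrections wins.

Refinements: clustered corrections whose pre-correction k-mers have
similar counts are reverted (likely a low-expression paralog, not
errors); reads exceeding the correction budget trigger a stepwise
relaxation of h(r) and are flagged unfixable if that fails; k-mers that
are mostly A or T (polyA tails) are transparent to the whole procedure;
mate pairs share the smaller of their two read-level thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from . import thresholds as th
from .dbg import NUCLEOTIDES, KmerTable, reverse_complement
from .io_fastx import ReadRecord
from .thresholds import ThresholdConfig

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class CorrectionParams:
    """Every tunable of the corrector in one place.

    k: k-mer size.
    alpha: variation coefficient of the k-mer-level threshold g(t).
    max_corrections_read: correction budget over the whole read.
    max_corrections_window: correction budget inside any window of k bases.
    max_paths: explored-branch cap; exceeding it lowers the read budget by
        one and restarts the search.
    max_relaxations: depth of the h(r) relaxation ladder.
    polya_fraction: A (or T) fraction at which a k-mer is treated as polyA.
    """

    k: int = 23
    alpha: float = 0.05
    max_corrections_read: int = 8
    max_corrections_window: int = 4
    max_paths: int = 100
    max_relaxations: int = 4
    polya_fraction: float = 0.9
    threshold_config: ThresholdConfig = field(default_factory=ThresholdConfig)

    def __post_init__(self):
        if self.max_corrections_window > self.max_corrections_read:
            raise ValueError("window budget cannot exceed the read budget")
        for name in ("max_corrections_read", "max_corrections_window",
                     "max_paths", "max_relaxations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class Correction:
    """One substitution: read offset (0-based), original and new base."""

    position: int
    from_base: str
    to_base: str
    reverted: bool = False

    def __post_init__(self):
        if self.from_base == self.to_base:
            raise ValueError("a correction must change the base")


@dataclass
class CorrectionResult:
    read_id: str
    corrected_sequence: str
    corrections: List[Correction]
    status: str  # clean | corrected | unfixable
    h_used: float = 0.0
    relaxation_steps: int = 0

    @property
    def net_corrections(self) -> List[Correction]:
        return [c for c in self.corrections if not c.reverted]


class _Exploded(Exception):
    """Raised when the explored-branch count exceeds max_paths."""


def is_polya_kmer(kmer: str, fraction: float) -> bool:
    """True when the k-mer is >= ``fraction`` A bases, or >= ``fraction`` T."""
    k = len(kmer)
    return kmer.count("A") / k >= fraction or kmer.count("T") / k >= fraction


def solid_mask(read, table: KmerTable, threshold,
               polya_fraction: Optional[float] = None) -> List[bool]:
    """Per k-mer position: multiplicity strictly above ``threshold``.

    ``threshold`` may be a single value or one value per k-mer position.
    PolyA k-mers (when ``polya_fraction`` is given) and k-mers containing
    non-ACGT characters are never solid.
    """
    seq = (read if isinstance(read, str) else read.sequence).upper()
    k = table.k
    n = len(seq) - k + 1
    cutoffs = list(threshold) if hasattr(threshold, "__len__") \
        else [threshold] * n
    if len(cutoffs) != n:
        raise ValueError("one threshold per k-mer position required")
    mask = []
    for i in range(n):
        w = seq[i:i + k]
        if polya_fraction is not None and is_polya_kmer(w, polya_fraction):
            mask.append(False)
        else:
            mask.append(table.multiplicity(w) > cutoffs[i])
    return mask


def variant_max_counts(seq: str, table: KmerTable) -> List[int]:
    """Per base: the largest multiplicity among the four single-base
    variants at that position, probed through both the k-mer ending at
    the base (the successor set of the preceding graph node) and the
    k-mer starting at it (the predecessor-side analogue). Probing both
    directions keeps a competing variant visible regardless of which
    side of the base its shared context lies on, and makes the resulting
    mask strand symmetric."""
    k = table.k
    mult = table.multiplicity
    L = len(seq)
    out = []
    for p in range(L):
        t = 0
        if p >= k - 1:
            prefix = seq[p - k + 1:p]
            t = max(mult(prefix + c) for c in NUCLEOTIDES)
        if p <= L - k:
            suffix = seq[p + 1:p + k]
            t = max(t, max(mult(c + suffix) for c in NUCLEOTIDES))
        out.append(t)
    return out


def local_solid_mask(read, table: KmerTable, h_value: float,
                     params: CorrectionParams) -> List[bool]:
    """Solidity under the position-local threshold f(t, r) = min(g(t), h).

    t for the k-mer at position i is the largest single-base variant
    multiplicity over the bases it covers (:func:`variant_max_counts`):
    a genuine low-count k-mer with no strong competing variant stays
    solid even in a read that also holds high-count k-mers, while a
    low-count k-mer shadowed anywhere by a high-count variant (a likely
    error, or a paralog/isoform mismatch) is not.
    """
    seq = (read if isinstance(read, str) else read.sequence).upper()
    k = table.k
    vm = variant_max_counts(seq, table)
    cutoffs = []
    for i in range(len(seq) - k + 1):
        t = max(vm[i:i + k])
        cutoffs.append(min(th.kmer_level_threshold(t, params.alpha), h_value))
    return solid_mask(seq, table, cutoffs, params.polya_fraction)


def _runs(mask: Sequence[bool]):
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            yield start, i
            start = None
    if start is not None:
        yield start, len(mask)


def solid_bases(mask: Sequence[bool], k: int) -> List[bool]:
    """Bases covered by a run of >= 2 consecutive solid k-mers."""
    out = [False] * (len(mask) + k - 1)
    for s, e in _runs(mask):
        if e - s >= 2:
            for i in range(s, e + k - 1):
                out[i] = True
    return out


def find_anchor(mask: Sequence[bool]) -> Optional[Tuple[int, int]]:
    """Longest run of >= 2 consecutive solid k-mer positions, leftmost on ties.

    Returned as a half-open [start, end) interval of k-mer positions, or
    ``None`` when no such run exists.
    """
    best = None
    for s, e in _runs(mask):
        if e - s >= 2 and (best is None or e - s > best[1] - best[0]):
            best = (s, e)
    return best


@dataclass(frozen=True)
class PathCandidate:
    """One surviving extension: the whole read with its corrections applied."""

    sequence: str
    corrections: Tuple[Correction, ...]
    min_multiplicity: float


def _apply(seq: str, corrections) -> str:
    if not corrections:
        return seq
    chars = list(seq)
    for c in corrections:
        chars[c.position] = c.to_base
    return "".join(chars)


def _extend_right(seq: str, anchor_last_kpos: int, table: KmerTable,
                  h_value: float, params: CorrectionParams,
                  base_solid: Sequence[bool], budget: int,
                  ) -> List[Tuple[Tuple[Correction, ...], float]]:
    """DFS from the k-mer at ``anchor_last_kpos`` to the 3' read end.

    Returns (corrections, min multiplicity along checked steps) for every
    complete path; raises :class:`_Exploded` past ``params.max_paths``
    explored branches.
    """
    k = params.k
    alpha = params.alpha
    L = len(seq)
    polyf = params.polya_fraction
    window = params.max_corrections_window
    mult = table.multiplicity
    results: List[Tuple[Tuple[Correction, ...], float]] = []
    counter = 0

    # iterative DFS; frames: (p, tail = last k-1 path chars, corrections, min_mult)
    stack = [(anchor_last_kpos + k, seq[anchor_last_kpos + 1:anchor_last_kpos + k],
              (), float("inf"))]
    while stack:
        p, tail, corrections, min_mult = stack.pop()
        if p == L:
            results.append((corrections, min_mult))
            continue
        counter += 1
        if counter > params.max_paths:
            raise _Exploded
        read_base = seq[p]
        read_kmer = tail + read_base
        # polyA k-mers are transparent: keep the read base, no test
        if polyf is not None and read_base in "AT" and \
                is_polya_kmer(read_kmer, polyf):
            stack.append((p + 1, read_kmer[1:], corrections, min_mult))
            continue
        # solid positions are never altered
        if base_solid[p]:
            stack.append((p + 1, read_kmer[1:], corrections, min_mult))
            continue
        sc: Dict[str, int] = {}
        for c in NUCLEOTIDES:
            m = mult(tail + c)
            if m and polyf is not None and is_polya_kmer(tail + c, polyf):
                m = 0  # never correct into a polyA k-mer
            sc[c] = m
        t = max(sc.values())
        if t <= 0:
            continue  # dead end: no stored continuation at all
        f = min(th.kmer_level_threshold(t, alpha), h_value)
        cands = [c for c in NUCLEOTIDES if sc[c] > f]
        # read base first, then alternatives by decreasing count;
        # stack is LIFO, so push in reverse preference order
        cands.sort(key=lambda c: (c != read_base, -sc[c], c), reverse=True)
        for c in cands:
            new_min = min(min_mult, sc[c])
            if c == read_base:
                stack.append((p + 1, tail[1:] + c, corrections, new_min))
                continue
            if len(corrections) + 1 > budget:
                continue
            n_window = 1 + sum(1 for cc in corrections if cc.position > p - k)
            if n_window > window:
                continue
            corr = Correction(p, read_base, c)
            stack.append((p + 1, tail[1:] + c, corrections + (corr,), new_min))
    return results


def search_paths(read, anchor: Tuple[int, int], direction: str,
                 table: KmerTable, h_value: float, params: CorrectionParams,
                 mask: Optional[Sequence[bool]] = None) -> List[PathCandidate]:
    """All surviving extensions of ``anchor`` to the read end.

    ``direction`` is ``"5to3"`` (extend right of the anchor) or ``"3to5"``
    (extend left, implemented as a 5'->3' pass on the reverse complement).
    When the explored-branch count passes ``params.max_paths``, the
    per-read correction budget is lowered by one and the search restarts;
    at budget 0 the search gives up and returns an empty list.
    """
    seq = (read if isinstance(read, str) else read.sequence).upper()
    if mask is None:
        mask = local_solid_mask(seq, table, h_value, params)
    k = params.k
    L = len(seq)
    a, b = anchor
    if direction == "5to3":
        work_seq, work_mask = seq, list(mask)
        last_kpos = b - 1
    elif direction == "3to5":
        # k-mer at rc position i is the reverse complement of the k-mer at
        # L - k - i, so the mask simply reverses (canonical counts are
        # strand symmetric)
        work_seq = reverse_complement(seq)
        work_mask = list(mask)[::-1]
        last_kpos = L - k - a
    else:
        raise ValueError(f"unknown direction {direction!r}")
    base_solid = solid_bases(work_mask, k)

    budget = params.max_corrections_read
    raw = None
    while budget >= 1:
        try:
            raw = _extend_right(work_seq, last_kpos, table, h_value, params,
                                base_solid, budget)
            break
        except _Exploded:
            budget -= 1
    if raw is None:
        return []

    out: List[PathCandidate] = []
    for corrections, min_mult in raw:
        if direction == "3to5":
            corrections = tuple(
                Correction(L - 1 - c.position,
                           _COMPLEMENT_BASE[c.from_base],
                           _COMPLEMENT_BASE[c.to_base])
                for c in reversed(corrections))
        out.append(PathCandidate(_apply(seq, corrections), corrections, min_mult))
    return out


def select_path(candidates: Sequence[PathCandidate],
                read=None) -> Optional[PathCandidate]:
    """Minimum-change winner.

    Ties go to the larger minimum k-mer multiplicity along the path, then
    to the candidate retaining the original base at the leftmost position
    where the tied candidates differ.
    """
    if not candidates:
        return None
    read_seq = None
    if read is not None:
        read_seq = (read if isinstance(read, str) else read.sequence).upper()

    best = candidates[0]
    for cand in candidates[1:]:
        if _prefer(cand, best, read_seq):
            best = cand
    return best


def _prefer(a: PathCandidate, b: PathCandidate, read_seq: Optional[str]) -> bool:
    if len(a.corrections) != len(b.corrections):
        return len(a.corrections) < len(b.corrections)
    if a.min_multiplicity != b.min_multiplicity:
        return a.min_multiplicity > b.min_multiplicity
    for i, (ca, cb) in enumerate(zip(a.sequence, b.sequence)):
        if ca != cb:
            if read_seq is not None:
                if ca == read_seq[i]:
                    return True
                if cb == read_seq[i]:
                    return False
            return ca < cb
    return False


def revert_clustered(read, corrections: Sequence[Correction],
                     table: KmerTable) -> List[Correction]:
    """Revert correction clusters that look like a low-expression paralog.

    For corrected positions i < j with j - i < k, the multiplicities of
    the *uncorrected* read's k-mers ending at i and j are compared; a
    ratio strictly inside (0.5, 2) means both k-mers plausibly sit on one
    stored path, so both corrections are reverted. Corrections within k of
    a reverted one are then iteratively re-tested against it. A k-mer with
    multiplicity 0 lies on no stored path and never triggers reversion.
    """
    seq = (read if isinstance(read, str) else read.sequence).upper()
    k = table.k
    corrections = sorted(corrections, key=lambda c: c.position)

    def ending_mult(p: int) -> int:
        w = seq[p - k + 1:p + 1] if p >= k - 1 else seq[0:k]
        return table.multiplicity(w) if len(w) == k else 0

    mult = {c.position: ending_mult(c.position) for c in corrections}

    def similar(p: int, q: int) -> bool:
        mp, mq = mult[p], mult[q]
        return mp > 0 and mq > 0 and 0.5 < mp / mq < 2.0

    reverted = set(c.position for c in corrections if c.reverted)
    positions = [c.position for c in corrections]
    for ii in range(len(positions)):
        for jj in range(ii + 1, len(positions)):
            pi, pj = positions[ii], positions[jj]
            if pj - pi >= k:
                break
            if similar(pi, pj):
                reverted.add(pi)
                reverted.add(pj)
    changed = True
    while changed:
        changed = False
        for p in positions:
            if p in reverted:
                continue
            for r in reverted:
                if abs(p - r) < k and similar(p, r):
                    reverted.add(p)
                    changed = True
                    break
    return [replace(c, reverted=(c.position in reverted)) for c in corrections]


def _max_window_load(positions: Sequence[int], k: int) -> int:
    """Largest number of corrections inside any window of k bases."""
    if not positions:
        return 0
    positions = sorted(positions)
    best = 0
    j = 0
    for i in range(len(positions)):
        while positions[i] - positions[j] >= k:
            j += 1
        best = max(best, i - j + 1)
    return best


def _h_basis(seq: str, table: KmerTable, params: CorrectionParams) -> List[int]:
    """Positive multiplicities of the read's non-polyA k-mers (h(r) input)."""
    k = table.k
    out = []
    polyf = params.polya_fraction
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if polyf is not None and is_polya_kmer(w, polyf):
            continue
        m = table.multiplicity(w)
        if m > 0:
            out.append(m)
    return out


def read_threshold(read, table: KmerTable, params: CorrectionParams,
                   drop_index: int = 1) -> float:
    """h(r) for this corrector: polyA k-mers excluded from the curve."""
    seq = (read if isinstance(read, str) else read.sequence).upper()
    mults = _h_basis(seq, table, params)
    x = th.drop_value(mults, params.threshold_config.drop_factor, drop_index)
    return th.kmer_level_threshold(x, params.alpha)


def _as_record(read) -> ReadRecord:
    return ReadRecord("read", read) if isinstance(read, str) else read


def _attempt(read_id: str, seq: str, raw_seq: str, table: KmerTable,
             h: float, params: CorrectionParams) -> Optional[CorrectionResult]:
    """One correction attempt at threshold h; None when it fails or overruns."""
    k = params.k
    L = len(seq)
    mask = local_solid_mask(seq, table, h, params)
    anchor = find_anchor(mask)
    if anchor is None:
        return None
    a, b = anchor
    corrections: List[Correction] = []
    if b - 1 + k < L:
        best = select_path(
            search_paths(seq, anchor, "5to3", table, h, params, mask=mask), seq)
        if best is None:
            return None
        corrections.extend(best.corrections)
    if a > 0:
        best = select_path(
            search_paths(seq, anchor, "3to5", table, h, params, mask=mask), seq)
        if best is None:
            return None
        corrections.extend(best.corrections)
    corrections = revert_clustered(seq, corrections, table)
    net = [c for c in corrections if not c.reverted]
    if len(net) > params.max_corrections_read:
        return None
    if _max_window_load([c.position for c in net], k) > params.max_corrections_window:
        return None
    out_seq = _apply(raw_seq, net)
    status = "corrected" if net else "clean"
    return CorrectionResult(read_id, out_seq, corrections, status, h_used=h)


def correct_read(read, table: KmerTable, params: CorrectionParams,
                 h_override: Optional[float] = None) -> CorrectionResult:
    """Correct one read end to end.

    Computes h(r) (capped by ``h_override`` in paired mode), anchors,
    extends in both directions, reverts clustered corrections, and checks
    the budgets; on overrun the read-level threshold is relaxed to the
    next sharp multiplicity drop, up to ``params.max_relaxations`` times.
    A read that still cannot be fixed is returned unchanged with status
    ``unfixable``. Reads shorter than k pass through as ``clean``.
    """
    rec = _as_record(read)
    raw_seq = rec.sequence
    seq = raw_seq.upper()
    if len(seq) < params.k:
        return CorrectionResult(rec.read_id, raw_seq, [], "clean")
    tc = params.threshold_config
    k = params.k
    if params.polya_fraction is not None and all(
            is_polya_kmer(seq[i:i + k], params.polya_fraction)
            for i in range(len(seq) - k + 1)):
        # pure polyA/polyT read: every k-mer is transparent, nothing to do
        return CorrectionResult(rec.read_id, raw_seq, [], "clean")
    mults = _h_basis(seq, table, params)
    n_drops = th.count_drops(mults, tc.drop_factor)
    h = 0.0
    steps = 0
    for step in range(params.max_relaxations):
        drop_index = step + 1
        x = th.drop_value(mults, tc.drop_factor, drop_index)
        h_own = th.kmer_level_threshold(x, params.alpha)
        if h_override is None:
            h = h_own
        elif step == 0:
            h = h_override  # pair-common threshold governs the first attempt
        else:
            h = min(h_override, h_own)
        steps = step
        result = _attempt(rec.read_id, seq, raw_seq, table, h, params)
        if result is not None:
            result.relaxation_steps = step
            return result
        if drop_index > n_drops:
            break  # the curve has no further sharp drop
    return CorrectionResult(rec.read_id, raw_seq, [], "unfixable",
                            h_used=h, relaxation_steps=steps)


def correct_pair(r1, r2, table: KmerTable, params: CorrectionParams
                 ) -> Tuple[CorrectionResult, CorrectionResult]:
    """Correct both mates under the smaller of their read-level thresholds.

    The shared threshold models a fragment from a low-expression isoform:
    the mate private to that isoform has the lower h(r), and using it for
    both prevents the shared mate's high counts from overwriting the
    private mate's low-count (but genuine) k-mers.
    """
    rec1, rec2 = _as_record(r1), _as_record(r2)
    hs = []
    for rec in (rec1, rec2):
        if len(rec.sequence) >= params.k:
            hs.append(read_threshold(rec, table, params, drop_index=1))
    h_common = min(hs) if hs else None
    return (correct_read(rec1, table, params, h_override=h_common),
            correct_read(rec2, table, params, h_override=h_common))
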