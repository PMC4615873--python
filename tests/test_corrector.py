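"""Path-search correction engine and its refinements."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readfix.corrector import (Correction, CorrectionParams, correct_pair,
                               correct_read, find_anchor, is_polya_kmer,
                               local_solid_mask, read_threshold,
                               revert_clustered, search_paths, select_path,
                               solid_bases, solid_mask, PathCandidate)
from readfix.dbg import KmerTable, build_table, canonical, reverse_complement
from readfix.io_fastx import ReadRecord
from readfix.thresholds import ThresholdConfig, kmer_level_threshold


def _params(k, alpha=0.05, **kw):
    kw.setdefault("threshold_config", ThresholdConfig(alpha=alpha))
    return CorrectionParams(k=k, alpha=alpha, **kw)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# --- solidity and anchoring ---------------------------------------------------

class TestSolidity:
    def test_all_high_counts_all_solid(self):
        table = build_table(["AAGTCC"] * 100, k=4)
        assert solid_mask("AAGTCC", table, 10.0) == [True, True, True]

    def test_absent_kmers_never_solid(self):
        table = KmerTable(k=4, counts={})
        assert solid_mask("AAGTCC", table, 0.0) == [False] * 3

    def test_one_error_breaks_exactly_k_kmers(self, rng):
        """A substitution corrupts the k windows that cover it."""
        k = 7
        base = _random_seq(rng, 60)
        table = build_table([base] * 100, k=k)
        read = list(base)
        read[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[30]]
        mask = solid_mask("".join(read), table, 10.0)
        assert mask.count(False) == k
        assert all(not mask[i] for i in range(30 - k + 1, 31))

    def test_polya_kmers_never_solid(self):
        table = build_table(["AAAAAA"] * 100, k=4)
        assert solid_mask("AAAAAA", table, 0.0, polya_fraction=0.9) == \
            [False] * 3

    def test_solid_bases_require_run_of_two(self):
        assert solid_bases([True, False, True], 3) == [False] * 5
        assert solid_bases([True, True, False], 3) == \
            [True, True, True, True, False]

    @pytest.mark.parametrize("mask,expected", [
        ("TTFFTTT", (4, 7)),   # longest run wins
        ("TTFFTT", (0, 2)),    # leftmost on ties
        ("TFTFT", None),       # no run of >= 2
    ])
    def test_find_anchor(self, mask, expected):
        bools = [c == "T" for c in mask]
        assert find_anchor(bools) == expected


# --- the worked example -------------------------------------------------------

class TestWorkedExample:
    def test_pruning_and_survivors(self, fig1):
        table, read, params = fig1
        h = read_threshold(read, table, params)
        mask = local_solid_mask(read.sequence, table, h, params)
        anchor = find_anchor(mask)
        assert anchor == (0, 2)  # AAGT, AGTC
        cands = search_paths(read, anchor, "5to3", table, h, params, mask=mask)
        seqs = {c.sequence for c in cands}
        by_n = {len(c.corrections): c.sequence for c in sorted(
            cands, key=lambda c: len(c.corrections), reverse=True)}
        assert "AAGTCCGTC" in seqs          # four-correction branch survives
        assert by_n[2] == "AAGTCGTTA"       # two-correction branch survives
        assert read.sequence not in seqs    # original path pruned at GTCA
        assert not any("GTCT" in s for s in seqs)  # count-1 vertex pruned

    def test_minimum_change_path_selected(self, fig1):
        table, read, params = fig1
        result = correct_read(read, table, params)
        assert result.status == "corrected"
        assert result.corrected_sequence == "AAGTCGTTA"
        assert [(c.position, c.from_base, c.to_base)
                for c in result.net_corrections] == \
            [(5, "A", "G"), (7, "A", "T")]

    def test_deterministic(self, fig1):
        table, read, params = fig1
        a = correct_read(read, table, params)
        b = correct_read(read, table, params)
        assert a.corrected_sequence == b.corrected_sequence
        assert a.corrections == b.corrections


# --- path selection -----------------------------------------------------------

class TestSelectPath:
    def test_fewest_corrections_wins(self):
        c1 = PathCandidate("AAAA", (Correction(0, "C", "A"),), 100)
        c2 = PathCandidate("CAAA", (), 10)
        assert select_path([c1, c2]) is c2

    def test_tie_broken_by_min_multiplicity(self):
        c1 = PathCandidate("AAAA", (Correction(0, "C", "A"),), 40)
        c2 = PathCandidate("GAAA", (Correction(0, "C", "G"),), 400)
        assert select_path([c1, c2]) is c2
        assert select_path([c2, c1]) is c2

    def test_tie_broken_by_original_base(self):
        read = "CTTT"
        c1 = PathCandidate("ATTT", (Correction(0, "G", "A"),), 50)
        c2 = PathCandidate("CTTT", (Correction(1, "G", "T"),), 50)
        # both one correction, same min count; c2 keeps the read base at
        # position 0, the leftmost position where they differ
        assert select_path([c1, c2], read) is c2

    def test_empty_and_singleton(self):
        assert select_path([]) is None
        only = PathCandidate("AAAA", (), 1)
        assert select_path([only]) is only


# --- refinements --------------------------------------------------------------

class TestRevertClustered:
    def test_nearby_similar_counts_reverted(self, rng):
        k = 23
        seq = _random_seq(rng, 80)
        counts = {canonical(seq[p - k + 1:p + 1]): m
                  for p, m in [(30, 10), (34, 15)]}
        table = KmerTable(k=k, counts=counts)
        corrections = [Correction(30, seq[30], "A" if seq[30] != "A" else "C"),
                       Correction(34, seq[34], "A" if seq[34] != "A" else "C")]
        out = revert_clustered(seq, corrections, table)
        assert all(c.reverted for c in out)  # 10/15 in (0.5, 2)

    def test_dissimilar_counts_kept(self, rng):
        k = 23
        seq = _random_seq(rng, 80)
        counts = {canonical(seq[p - k + 1:p + 1]): m
                  for p, m in [(30, 10), (34, 50)]}
        table = KmerTable(k=k, counts=counts)
        corrections = [Correction(30, seq[30], "A" if seq[30] != "A" else "C"),
                       Correction(34, seq[34], "A" if seq[34] != "A" else "C")]
        out = revert_clustered(seq, corrections, table)
        assert not any(c.reverted for c in out)  # ratio 0.2 outside (0.5, 2)

    def test_distant_corrections_untouched(self, rng):
        k = 23
        seq = _random_seq(rng, 80)
        counts = {canonical(seq[p - k + 1:p + 1]): m
                  for p, m in [(30, 10), (60, 15)]}
        table = KmerTable(k=k, counts=counts)
        corrections = [Correction(30, seq[30], "A" if seq[30] != "A" else "C"),
                       Correction(60, seq[60], "A" if seq[60] != "A" else "C")]
        out = revert_clustered(seq, corrections, table)
        assert not any(c.reverted for c in out)  # 30 bases apart >= k

    def test_zero_count_kmers_never_revert(self, rng):
        """Error-containing k-mers (count 0) are genuine errors, not paralogs."""
        k = 23
        seq = _random_seq(rng, 80)
        table = KmerTable(k=k, counts={})
        corrections = [Correction(30, seq[30], "A" if seq[30] != "A" else "C"),
                       Correction(34, seq[34], "A" if seq[34] != "A" else "C")]
        out = revert_clustered(seq, corrections, table)
        assert not any(c.reverted for c in out)

    def test_iterative_chain_reversion(self, rng):
        """A correction within k of a reverted pair is re-tested and reverted."""
        k = 23
        seq = _random_seq(rng, 120)
        counts = {canonical(seq[p - k + 1:p + 1]): m
                  for p, m in [(30, 10), (40, 15), (60, 12)]}
        # 30-40 similar (revert); 60 is within k of 40 only, ratio 12/15 ok
        table = KmerTable(k=k, counts=counts)
        corrections = [
            Correction(p, seq[p], "A" if seq[p] != "A" else "C")
            for p in (30, 40, 60)]
        out = revert_clustered(seq, corrections, table)
        assert all(c.reverted for c in out)


class TestPolyA:
    @pytest.mark.parametrize("kmer,fraction,expected", [
        ("AAAAAAAAAA", 0.9, True),
        ("AAAAAAAAAC", 0.9, True),    # 9/10 A
        ("ACGTACGTAC", 0.9, False),
        ("TTTTTTTTTT", 0.9, True),    # polyT counts too
    ])
    def test_is_polya_kmer(self, kmer, fraction, expected):
        assert is_polya_kmer(kmer, fraction) == expected

    def test_polya_only_read_unchanged(self):
        table = build_table(["ACGTACGTACGTACGT"] * 50, k=8)
        read = ReadRecord("tail", "A" * 40)
        params = _params(k=8)
        result = correct_read(read, table, params)
        assert result.status == "clean"
        assert result.corrected_sequence == read.sequence

    def test_polya_tail_bases_left_unchanged(self, rng):
        """Errors inside a transcript body are fixed; the polyA tail is not touched."""
        k = 9
        body = _random_seq(rng, 60)
        transcript = body + "A" * 30
        table = build_table([transcript] * 100, k=k)
        read = transcript[40:]  # 20 body bases + 30 tail bases
        mutated = list(read)
        mutated[35] = "C"  # error deep inside the tail
        result = correct_read(ReadRecord("r", "".join(mutated)), table,
                              _params(k=k))
        assert result.corrected_sequence[35] == "C"  # tail never corrected


# --- end-to-end behavior ------------------------------------------------------

class TestCorrectRead:
    def test_error_free_read_is_clean(self, rng):
        base = _random_seq(rng, 80)
        table = build_table([base] * 100, k=9)
        result = correct_read(ReadRecord("r", base), table, _params(k=9))
        assert result.status == "clean"
        assert result.corrected_sequence == base

    def test_foreign_read_is_unfixable_and_unchanged(self, rng):
        table = build_table([_random_seq(rng, 80)] * 100, k=9)
        foreign = _random_seq(rng, 50)
        result = correct_read(ReadRecord("r", foreign), table, _params(k=9))
        assert result.status == "unfixable"
        assert result.corrected_sequence == foreign

    def test_single_error_corrected(self, rng):
        base = _random_seq(rng, 80)
        table = build_table([base] * 100, k=9)
        read = list(base)
        read[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[40]]
        result = correct_read(ReadRecord("r", "".join(read)), table,
                              _params(k=9))
        assert result.status == "corrected"
        assert result.corrected_sequence == base
        assert len(result.net_corrections) == 1

    def test_errors_near_both_ends_corrected(self, rng):
        """The 3'->5' pass fixes errors left of the anchor."""
        base = _random_seq(rng, 80)
        table = build_table([base] * 100, k=9)
        read = list(base)
        for p in (2, 77):
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        result = correct_read(ReadRecord("r", "".join(read)), table,
                              _params(k=9))
        assert result.corrected_sequence == base

    def test_over_budget_read_unfixable(self, rng):
        """More scattered mismatches than the budget: emitted unchanged."""
        k = 9
        base = _random_seq(rng, 160)
        table = build_table([base] * 100, k=k)
        read = list(base)
        positions = list(range(5, 160, 12))  # 13 mismatches, spaced > window
        for p in positions:
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        read = "".join(read)
        result = correct_read(ReadRecord("r", read), table, _params(k=k))
        assert result.status == "unfixable"
        assert result.corrected_sequence == read

    def test_short_read_passes_through(self):
        table = KmerTable(k=23, counts={})
        result = correct_read(ReadRecord("r", "ACGT"), table, _params(k=23))
        assert result.status == "clean"
        assert result.corrected_sequence == "ACGT"

    def test_solid_bases_never_altered(self, rng):
        base = _random_seq(rng, 90)
        k = 9
        table = build_table([base] * 100, k=k)
        read = list(base)
        read[45] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[45]]
        read = "".join(read)
        params = _params(k=k)
        result = correct_read(ReadRecord("r", read), table, params)
        mask = local_solid_mask(read, table, result.h_used, params)
        solid = solid_bases(mask, k)
        for i, is_solid in enumerate(solid):
            if is_solid:
                assert result.corrected_sequence[i] == read[i]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_length_preserved_and_budget_respected(self, seed):
        rng = np.random.default_rng(seed)
        base = _random_seq(rng, 70)
        k = 7
        table = build_table([base] * int(rng.integers(2, 60)), k=k)
        read = list(base[:50])
        n_err = int(rng.integers(0, 5))
        for p in rng.choice(50, size=n_err, replace=False):
            read[p] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(read)
        params = _params(k=k)
        result = correct_read(ReadRecord("r", read), table, params)
        assert len(result.corrected_sequence) == len(read)
        net = result.net_corrections
        assert len(net) <= params.max_corrections_read
        if result.status == "unfixable":
            assert result.corrected_sequence == read
        if result.status == "clean":
            assert result.corrected_sequence == read


class TestPairedEnd:
    @staticmethod
    def _two_isoform_fixture():
        rng = np.random.default_rng(5)
        U = _random_seq(rng, 30)      # 5' exon private to the low isoform
        R = _random_seq(rng, 60)      # region shared ancestry with paralog
        Rp = list(R)
        for pos in (5, 28):
            Rp[pos] = "A" if R[pos] != "A" else "C"
        low_iso = U + R               # coverage 8
        paralog = "".join(Rp)         # coverage 200
        table = build_table([low_iso] * 8 + [paralog] * 200, 23)
        params = _params(k=23)
        r1 = ReadRecord("f/1", low_iso[0:70])
        r2 = ReadRecord("f/2", reverse_complement(low_iso[60:90]))
        return table, params, r1, r2

    def test_pair_threshold_preserves_private_kmers(self):
        table, params, r1, r2 = self._two_isoform_fixture()
        h1 = read_threshold(r1, table, params)
        h2 = read_threshold(r2, table, params)
        assert h1 < h2
        # mate 2's own (higher) threshold would overwrite mate 1's
        # genuine count-8 k-mers with the high-count paralog
        naive = correct_read(r1, table, params, h_override=h2)
        assert naive.status == "corrected"
        assert naive.corrected_sequence != r1.sequence
        # the pair-common (smaller) threshold keeps them
        res1, res2 = correct_pair(r1, r2, table, params)
        assert res1.status == "clean"
        assert res1.corrected_sequence == r1.sequence
        assert res2.status == "clean"

    def test_identical_mates_identical_results(self, rng):
        base = _random_seq(rng, 80)
        table = build_table([base] * 100, k=9)
        read = list(base)
        read[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[40]]
        r = ReadRecord("m", "".join(read))
        res1, res2 = correct_pair(r, r, table, _params(k=9))
        assert res1.corrected_sequence == res2.corrected_sequence
        assert res1.corrections == res2.corrections


# --- exhaustive-enumeration oracle -------------------------------------------

def oracle_min_corrections(seq, anchor, table, h_value, params):
    """Minimum corrections over ALL admissible read-length paths, by
    exhaustive enumeration with memoization (independent of the DFS,
    pruning, restart, and selection logic under test). Returns (right
    minimum, left minimum), each None when no admissible path reaches
    the respective read end."""
    k = params.k
    alpha = params.alpha
    mask = local_solid_mask(seq, table, h_value, params)

    def side_min(wseq, last_kpos, wmask):
        L = len(wseq)
        bsolid = solid_bases(wmask, k)

        @lru_cache(maxsize=None)
        def rec(p, tail):
            if p == L:
                return 0
            if bsolid[p]:
                return rec(p + 1, (tail + wseq[p])[1:])
            best = None
            for c in "ACGT":
                m = table.multiplicity(tail + c)
                if m == 0:
                    continue
                sc = max(table.multiplicity(tail + b) for b in "ACGT")
                f = min(kmer_level_threshold(sc, alpha), h_value)
                if m <= f:
                    continue
                sub = rec(p + 1, (tail + c)[1:])
                if sub is None:
                    continue
                cost = (c != wseq[p]) + sub
                if best is None or cost < best:
                    best = cost
            return best

        start = last_kpos + k
        if start >= L:
            return 0
        return rec(start, wseq[last_kpos + 1:last_kpos + k])

    a, b = anchor
    L = len(seq)
    right = side_min(seq, b - 1, list(mask))
    left = side_min(reverse_complement(seq), L - k - a, list(mask)[::-1])
    return right, left


def anchor_covers(anchor, direction, read, k):
    a, b = anchor
    return (b - 1 + k >= len(read)) if direction == "5to3" else (a == 0)


def compare_against_oracle(n_instances, seed):
    """Generate random (read, table) instances and check that the DFS +
    selection finds exactly the exhaustive-enumeration minimum in both
    directions. Returns the number of anchored instances exercised."""
    rng = np.random.default_rng(seed)
    k = 5
    params = _params(k=k, max_corrections_read=12,
                     max_corrections_window=12, max_paths=10**6,
                     polya_fraction=None)
    checked = 0
    attempts = 0
    while checked < n_instances and attempts < 20 * n_instances:
        attempts += 1
        base = _random_seq(rng, 45)
        variant = list(base)
        for p in rng.choice(45, size=3, replace=False):
            variant[p] = "ACGT"[int(rng.integers(0, 4))]
        table = build_table(
            [base] * int(rng.integers(2, 40)) +
            ["".join(variant)] * int(rng.integers(0, 12)), k=k)
        if not table.counts:
            continue
        read = list(base[5:35])
        for p in rng.choice(30, size=int(rng.integers(0, 3)),
                            replace=False):
            read[p] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(read)
        h = read_threshold(read, table, params)
        mask = local_solid_mask(read, table, h, params)
        anchor = find_anchor(mask)
        if anchor is None:
            continue
        oracle_r, oracle_l = oracle_min_corrections(
            read, anchor, table, h, params)
        for direction, oracle in (("5to3", oracle_r), ("3to5", oracle_l)):
            cands = search_paths(read, anchor, direction, table, h,
                                 params, mask=mask)
            best = select_path(cands, read)
            if oracle is None:
                assert best is None or anchor_covers(anchor, direction,
                                                     read, params.k)
            else:
                assert best is not None
                assert len(best.corrections) == oracle
        checked += 1
    return checked


class TestOracleEquivalence:
    def test_small_instances_match_exhaustive_minimum(self):
        """DFS + selection finds the true minimum-change path."""
        assert compare_against_oracle(60, seed=7) >= 60
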