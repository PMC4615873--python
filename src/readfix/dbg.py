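"""Canonical k-mer counting: the De Bruijn graph backing the corrector.

The graph is implicit: nodes are the stored k-mers, edges are (k-1)-base
overlaps queried through :func:`successor_counts`. Only k-mers seen at
least ``min_count`` times (default 2) are kept, so sequencing errors --
which are overwhelmingly singletons -- never enter the graph.

By default a k-mer and its reverse complement are pooled under the
lexicographically smaller of the two (the *canonical* form), which makes
the table usable on unstranded libraries; ``stranded=True`` disables
pooling.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Union

NUCLEOTIDES = ("A", "C", "G", "T")
_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_acgt(kmer: str) -> None:
    if not _ACGT.issuperset(kmer):
        for i, c in enumerate(kmer):
            if c not in _ACGT:
                raise ValueError(
                    f"non-ACGT character {c!r} at position {i} in k-mer {kmer!r}"
                )


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement.

    Idempotent; raises ``ValueError`` naming the first offending position
    if the k-mer contains a character outside {A, C, G, T}.
    """
    _check_acgt(kmer)
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerTable:
    """Multiplicity table of (canonical) k-mers.

    ``counts`` maps each stored key to its total occurrence count across
    the read set, both strands pooled unless ``stranded``.
    """

    k: int
    counts: Dict[str, int] = field(default_factory=dict)
    stranded: bool = False
    min_count: int = 2

    def __len__(self) -> int:
        return len(self.counts)

    def _key(self, kmer: str) -> str:
        return kmer if self.stranded else canonical(kmer)

    def multiplicity(self, kmer: str) -> int:
        """M(u): stored count of ``kmer`` (canonicalized), 0 if absent.

        Singletons and never-seen k-mers are indistinguishable: both 0.
        K-mers containing non-ACGT characters report 0.
        """
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != table k {self.k}")
        if not _ACGT.issuperset(kmer):
            return 0
        return self.counts.get(self._key(kmer), 0)

    def successor_counts(self, kmer: str) -> Dict[str, int]:
        """Multiplicity of each successor S(u, c) = u[1:] + c, c in ACGT.

        The 3'->5' analogue is obtained by calling this on the reverse
        complement; extension code never needs a predecessor query.
        """
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != table k {self.k}")
        suffix = kmer[1:]
        return {c: self.multiplicity(suffix + c) for c in NUCLEOTIDES}


def _sequence_of(read) -> str:
    return read if isinstance(read, str) else read.sequence


def count_kmers(reads: Iterable[Union[str, "object"]], k: int,
                stranded: bool = False) -> Dict[str, int]:
    """Exact count of every (canonical) k-mer; windows with non-ACGT skipped."""
    counts: Dict[str, int] = {}
    get = counts.get
    for read in reads:
        seq = _sequence_of(read).upper()
        n = len(seq) - k + 1
        if n <= 0:
            continue
        clean = _ACGT.issuperset(seq)
        if stranded:
            for i in range(n):
                kmer = seq[i:i + k]
                if clean or _ACGT.issuperset(kmer):
                    counts[kmer] = get(kmer, 0) + 1
        else:
            rcseq = seq.translate(_COMPLEMENT)[::-1]
            ln = len(seq)
            for i in range(n):
                kmer = seq[i:i + k]
                if not clean and not _ACGT.issuperset(kmer):
                    continue
                rk = rcseq[ln - i - k:ln - i]
                key = kmer if kmer <= rk else rk
                counts[key] = get(key, 0) + 1
    return counts


def build_table(reads, k: int, min_count: int = 2,
                stranded: bool = False) -> KmerTable:
    """Two-pass table build: count everything, then drop counts < min_count.

    Reads may be plain strings or any object with a ``sequence`` attribute.
    Emits a warning (and returns an empty table) when k exceeds every read
    length.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    reads = list(reads)
    if not reads:
        raise ValueError("read set is empty")
    counts = count_kmers(reads, k, stranded=stranded)
    if not counts and all(len(_sequence_of(r)) < k for r in reads):
        warnings.warn(f"k={k} exceeds every read length; table is empty",
                      stacklevel=2)
    kept = {kmer: c for kmer, c in counts.items() if c >= min_count}
    return KmerTable(k=k, counts=kept, stranded=stranded, min_count=min_count)


# Thin functional aliases over the table methods.

def multiplicity(table: KmerTable, kmer: str) -> int:
    return table.multiplicity(kmer)


def successor_counts(table: KmerTable, kmer: str) -> Dict[str, int]:
    return table.successor_counts(kmer)


def dump_table(table: KmerTable, path) -> None:
    """Write the table as a 2-column TSV (kmer<TAB>count); .gz accepted."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for kmer in sorted(table.counts):
            fh.write(f"{kmer}\t{table.counts[kmer]}\n")


def load_table(path, stranded: bool = False, min_count: int = 2) -> KmerTable:
    """Load a table written by :func:`dump_table`."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    counts: Dict[str, int] = {}
    k = None
    with opener(path, "rt") as fh:
        for line in fh:
            kmer, _, cnt = line.rstrip("\n").partition("\t")
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise ValueError(f"inconsistent k-mer length in {path}")
            counts[kmer] = int(cnt)
    if k is None:
        raise ValueError(f"empty k-mer table file {path}")
    return KmerTable(k=k, counts=counts, stranded=stranded, min_count=min_count)
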