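"""Synthetic transcriptomes, expression-weighted reads, and ground truth.

The generator emulates the structure of an RNA-seq experiment at desk
scale: random transcripts assigned to low/medium/high expression tiers,
optional paralog pairs (a near-copy at lower abundance), optional polyA
tails, reads drawn proportional to abundance times effective length, and
independent per-base substitution errors recorded as ground truth so that
corrections can be scored per base.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corrector import CorrectionParams
from .dbg import KmerTable, canonical, reverse_complement
from .io_fastx import ReadRecord
from .thresholds import ThresholdConfig

TIERS = ("low", "medium", "high")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the package's reference benchmark: 20 transcripts of
    500-1,500 bp on expression tiers weighted 1:20:400, 20,000 single-end
    100 bp reads, 0.5% flat substitution error rate.
    """

    n_transcripts: int = 20
    length_range: Tuple[int, int] = (500, 1500)
    tier_weights: Tuple[float, float, float] = (1.0, 20.0, 400.0)
    paralog_pairs: int = 0
    paralog_divergence: int = 5
    paralog_abundance_ratio: float = 0.1
    polya_len: int = 0
    read_length: int = 100
    n_reads: int = 20_000
    paired: bool = False
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    error_rate: float = 0.005
    error_ramp: bool = False  # linearly 0 -> 2*error_rate toward the 3' end
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        for name in ("n_transcripts", "paralog_pairs", "polya_len",
                     "read_length", "n_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Transcript:
    transcript_id: str
    sequence: str
    tier: str
    abundance: float


@dataclass
class ReadOrigin:
    transcript_id: str
    tier: str
    strand: str  # '+' or '-'
    offset: int  # 0-based start on the transcript (of the fragment/read)


@dataclass
class ErrorTruth:
    """Injected substitutions for one read (ground truth for scoring)."""

    read_id: str
    positions: List[int]
    original_bases: List[str]
    transcript_id: str = ""
    tier: str = ""

    def __post_init__(self):
        if len(self.positions) != len(self.original_bases):
            raise ValueError("positions and original_bases differ in length")
        if any(b >= a for a, b in zip(self.positions[1:], self.positions)):
            raise ValueError("positions must be strictly increasing")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def make_transcriptome(config: SimConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> List[Transcript]:
    """Random transcripts with tiers, paralog pairs, and optional polyA tails.

    Tiers are assigned round-robin so every tier is populated; each of the
    first ``paralog_pairs`` transcripts gains a paralog: an exact copy with
    ``paralog_divergence`` substitutions at distinct positions, at
    ``paralog_abundance_ratio`` times the abundance, appended after the
    base transcripts. PolyA tails (all A) are appended last, after the
    divergence is planted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    transcripts: List[Transcript] = []
    for i in range(config.n_transcripts):
        tier = TIERS[i % 3]
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        abundance = config.tier_weights[TIERS.index(tier)]
        transcripts.append(Transcript(f"tx{i}", seq, tier, abundance))
    paralogs: List[Transcript] = []
    for p in range(min(config.paralog_pairs, len(transcripts))):
        base = transcripts[p]
        chars = list(base.sequence)
        d = min(config.paralog_divergence, len(chars))
        sites = rng.choice(len(chars), size=d, replace=False)
        for s in sites:
            old = chars[s]
            alts = [b for b in "ACGT" if b != old]
            chars[s] = alts[int(rng.integers(0, 3))]
        paralogs.append(Transcript(
            f"{base.transcript_id}p", "".join(chars), "low",
            base.abundance * config.paralog_abundance_ratio))
    transcripts.extend(paralogs)
    if config.polya_len:
        tail = "A" * config.polya_len
        transcripts = [replace(t, sequence=t.sequence + tail)
                       for t in transcripts]
    return transcripts


def sample_reads(transcripts: Sequence[Transcript], config: SimConfig,
                 rng: Optional[np.random.Generator] = None
                 ) -> Tuple[List[ReadRecord], List[ReadOrigin]]:
    """Draw reads proportional to abundance x effective length.

    Single-end mode draws a uniform start and a uniform strand (minus-
    strand reads are reverse complemented). Paired mode draws a fragment
    of normally distributed length and emits the two fragment ends as a
    forward mate-1 and reverse-complement mate-2, interleaved in the
    output list (`/1` then `/2`). Transcripts shorter than the read length
    are excluded with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    usable = [t for t in transcripts if len(t.sequence) >= rl]
    dropped = [t.transcript_id for t in transcripts if len(t.sequence) < rl]
    if dropped:
        warnings.warn(f"transcripts shorter than read length excluded: "
                      f"{', '.join(dropped)}", stacklevel=2)
    if not usable:
        raise ValueError("no transcript is at least one read length long")
    weights = np.array([t.abundance * (len(t.sequence) - rl + 1)
                        for t in usable], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(usable), size=config.n_reads, p=weights)

    reads: List[ReadRecord] = []
    origins: List[ReadOrigin] = []
    for i, ti in enumerate(picks):
        t = usable[ti]
        tlen = len(t.sequence)
        if config.paired:
            flen = int(round(rng.normal(config.fragment_mean,
                                        config.fragment_sd)))
            flen = max(rl, min(flen, tlen))
            start = int(rng.integers(0, tlen - flen + 1))
            frag = t.sequence[start:start + flen]
            r1 = frag[:rl]
            r2 = reverse_complement(frag)[:rl]
            reads.append(ReadRecord(f"read{i}/1", r1))
            reads.append(ReadRecord(f"read{i}/2", r2))
            origins.append(ReadOrigin(t.transcript_id, t.tier, "+", start))
            origins.append(ReadOrigin(t.transcript_id, t.tier, "-", start))
        else:
            start = int(rng.integers(0, tlen - rl + 1))
            seq = t.sequence[start:start + rl]
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            if strand == "-":
                seq = reverse_complement(seq)
            reads.append(ReadRecord(f"read{i}", seq))
            origins.append(ReadOrigin(t.transcript_id, t.tier, strand, start))
    return reads, origins


def inject_errors(reads: Sequence[ReadRecord], error_rate: float, seed: int,
                  ramp: bool = False,
                  origins: Optional[Sequence[ReadOrigin]] = None
                  ) -> Tuple[List[ReadRecord], List[ErrorTruth]]:
    """Substitute each base independently; record the ground truth.

    With ``ramp`` the per-base rate rises linearly from 0 at the 5' end to
    2x ``error_rate`` at the 3' end (mean preserved). The substituted base
    is uniform over the three alternatives. Only reads that received at
    least one error get a truth record.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    mutated: List[ReadRecord] = []
    truths: List[ErrorTruth] = []
    for idx, read in enumerate(reads):
        seq = read.sequence
        L = len(seq)
        if error_rate == 0 or L == 0:
            mutated.append(read)
            continue
        if ramp:
            rates = np.linspace(0.0, 2.0 * error_rate, num=L)
        else:
            rates = np.full(L, error_rate)
        hits = np.nonzero(rng.random(L) < rates)[0]
        if hits.size == 0:
            mutated.append(read)
            continue
        chars = list(seq)
        originals = []
        for p in hits:
            old = chars[p]
            alts = [b for b in "ACGT" if b != old]
            chars[p] = alts[int(rng.integers(0, 3))]
            originals.append(old)
        mutated.append(ReadRecord(read.read_id, "".join(chars),
                                  read.qualities))
        origin = origins[idx] if origins is not None else None
        truths.append(ErrorTruth(
            read.read_id, [int(p) for p in hits], originals,
            transcript_id=origin.transcript_id if origin else "",
            tier=origin.tier if origin else ""))
    return mutated, truths


def simulate_dataset(config: SimConfig):
    """Full pipeline: transcriptome -> reads -> errors.

    Returns (transcripts, clean reads, mutated reads, truths, origins).
    In paired mode each fragment's origin is duplicated for its two mates.
    """
    rng = np.random.default_rng(config.seed)
    transcripts = make_transcriptome(config, rng)
    reads, origins = sample_reads(transcripts, config, rng)
    mutated, truths = inject_errors(reads, config.error_rate,
                                    seed=config.seed + 2,
                                    ramp=config.error_ramp, origins=origins)
    return transcripts, reads, mutated, truths, origins


def write_truth_tsv(truths: Sequence[ErrorTruth], path) -> None:
    """One row per injected error: read_id, pos, orig_base, transcript, tier."""
    with open(path, "wt") as fh:
        fh.write("read_id\tpos\torig_base\ttranscript\ttier\n")
        for t in truths:
            for p, b in zip(t.positions, t.original_bases):
                fh.write(f"{t.read_id}\t{p}\t{b}\t{t.transcript_id}\t{t.tier}\n")


def load_truth_tsv(path) -> Dict[str, ErrorTruth]:
    """Truth records keyed by read id (reads without errors are absent)."""
    rows: Dict[str, ErrorTruth] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing truth TSV header")
        for line in fh:
            read_id, pos, base, tx, tier = line.rstrip("\n").split("\t")
            if read_id not in rows:
                rows[read_id] = ErrorTruth(read_id, [], [], tx, tier)
            rows[read_id].positions.append(int(pos))
            rows[read_id].original_bases.append(base)
    return rows


# --- the worked-example graph -------------------------------------------------

_FIG1_COUNTS = {
    # the read's own path: two strong anchor k-mers, then a weak vertex
    "AAGT": 520, "AGTC": 500, "GTCA": 4, "GTCT": 1,
    # four-correction branch (strongest successor of AGTC)
    "GTCC": 494, "TCCG": 490, "CCGT": 485, "CGTC": 480,
    # two-correction branch: the eventual winner
    "GTCG": 450, "TCGT": 440, "CGTT": 430, "GTTA": 420,
}


def fig1_fixture() -> Tuple[KmerTable, ReadRecord, CorrectionParams]:
    """The worked path-extension example: a k=4 graph around read AAGTCATAA.

    Four continuations exist at k-mer AGTC: the read's own (count 4,
    below threshold), a strong branch requiring four corrections, a
    strong branch requiring two (the winner), and a count-1 vertex that
    is pruned outright. alpha is fixed at 0.05. Counts the example does
    not pin down are set high enough that both surviving branches are
    admissible.
    """
    counts: Dict[str, int] = {}
    for kmer, c in _FIG1_COUNTS.items():
        counts[canonical(kmer)] = c
    table = KmerTable(k=4, counts=counts, min_count=1)
    read = ReadRecord("fig1", "AAGTCATAA")
    params = CorrectionParams(
        k=4, alpha=0.05,
        threshold_config=ThresholdConfig(alpha=0.05))
    return table, read, params
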