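"""FASTA/FASTQ input and output, plain or gzipped, single- or paired-end.

Parsing goes through Biopython's streaming iterators
(``FastqGeneralIterator`` / ``SimpleFastaParser``). Output headers are
annotated with the correction status (`` cor`` / `` unfixable_error``),
a convention downstream filters already understand; ``tag=False``
disables it.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Tuple, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PathLike = Union[str, Path]

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class ReadRecord:
    """One sequencing read: id (full header text), bases, optional qualities."""

    read_id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self):
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"quality string length {len(self.qualities)} != sequence "
                f"length {len(self.sequence)} for read {self.read_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: PathLike) -> IO[str]:
    """Open for reading, decompressing transparently on gzip magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _open_write(path: PathLike) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "wt")


def detect_format(path: PathLike) -> str:
    """'fasta' or 'fastq', from the first character of the (decompressed) file."""
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(
        f"{path}: cannot detect format (first character {first!r}, "
        "expected '>' for FASTA or '@' for FASTQ)")


def read_fastx(path: PathLike) -> Iterator[ReadRecord]:
    """Stream records from a FASTA or FASTQ file (gzip transparent)."""
    fmt = detect_format(path)
    with _open_text(path) as fh:
        if fmt == "fastq":
            n_seen = 0
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    n_seen += 1
                    yield ReadRecord(title, seq, qual)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ near line {4 * n_seen + 1}: {exc}"
                ) from exc
        else:
            for title, seq in SimpleFastaParser(fh):
                yield ReadRecord(title, seq)


def _mate_key(read_id: str) -> str:
    """Pairing key: first header token, trailing /1 /2 or .1 .2 stripped."""
    token = read_id.split()[0] if read_id else ""
    if len(token) > 2 and token[-2] in "/." and token[-1] in "12":
        token = token[:-2]
    return token


def read_pairs(path1: PathLike, path2: PathLike
               ) -> Iterator[Tuple[ReadRecord, ReadRecord]]:
    """Stream synchronized mate pairs; fail fast on desynchronization."""
    it1, it2 = read_fastx(path1), read_fastx(path2)
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        index += 1
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = path1 if r1 is None else path2
            raise ValueError(
                f"paired files desynchronized: {short} ends at pair index {index}")
        if _mate_key(r1.read_id) != _mate_key(r2.read_id):
            raise ValueError(
                f"mate id mismatch at pair index {index}: "
                f"{r1.read_id!r} vs {r2.read_id!r}")
        yield r1, r2


_STATUS_SUFFIX = {"clean": "", "corrected": " cor", "unfixable": " unfixable_error"}


def _annotated_header(read: ReadRecord, status: Optional[str], tag: bool) -> str:
    suffix = _STATUS_SUFFIX[status] if (tag and status) else ""
    return read.read_id + suffix


def _write_record(fh: IO[str], fmt: str, header: str, seq: str,
                  qual: Optional[str]) -> None:
    if fmt == "fastq":
        fh.write(f"@{header}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")
    else:
        fh.write(f">{header}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")


def write_fastx(records: Iterable[ReadRecord], path: PathLike,
                fmt: Optional[str] = None) -> int:
    """Write plain records; format from extension unless given. Returns count."""
    if fmt is None:
        stem = str(path)[:-3] if str(path).endswith(".gz") else str(path)
        fmt = "fasta" if stem.endswith((".fa", ".fasta")) else "fastq"
    n = 0
    with _open_write(path) as fh:
        for rec in records:
            _write_record(fh, fmt, rec.read_id, rec.sequence, rec.qualities)
            n += 1
    return n


def write_corrected(stream, out_path: PathLike, fmt: str,
                    tag: bool = True) -> int:
    """Write (ReadRecord, CorrectionResult) pairs in input order.

    The corrected sequence replaces the original; qualities pass through
    unchanged (substitutions preserve length). Headers gain `` cor`` or
    `` unfixable_error`` suffixes unless ``tag`` is off. Returns the
    number of records written.
    """
    n = 0
    with _open_write(out_path) as fh:
        for read, result in stream:
            header = _annotated_header(read, result.status, tag)
            _write_record(fh, fmt, header, result.corrected_sequence,
                          read.qualities)
            n += 1
    return n


def corrected_output_path(in_path: PathLike, out_dir: PathLike) -> Path:
    """`<stem>.cor.<ext>` in ``out_dir``, mirroring the input extension."""
    name = Path(in_path).name
    gz = name.endswith(".gz")
    if gz:
        name = name[:-3]
    stem, dot, ext = name.rpartition(".")
    if not dot:
        stem, ext = name, "fq"
    return Path(out_dir) / f"{stem}.cor.{ext}"
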