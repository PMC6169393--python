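"""Sequence records and FASTA/FASTQ input/output.

Residues are stored uppercase over the IUPAC nucleotide alphabet
(``ACGT``, ``N`` and the ambiguity letters ``RYSWKMBDHV``).  FASTQ
qualities are Phred+33 integers.  The per-read quality score is the
Phred transform of the *mean per-base error probability*, which is the
convention long-read base callers use when they bin reads into pass and
fail at a score threshold (≥7 by default downstream); an arithmetic
mean of Phred scores would overweight good bases and is deliberately
not used.

Parsing is implemented directly (rather than through a generic parser)
so that malformed input can be reported with the offending line number,
and so that illegal residue letters fail loudly instead of being
silently masked.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "SequenceRecord",
    "ReadRecord",
    "FastaParseError",
    "FastqParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "mean_read_quality",
    "reverse_complement",
    "VALID_RESIDUES",
]

#: IUPAC nucleotide letters accepted on input (after uppercasing).
VALID_RESIDUES = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the file and line number."""


class FastqParseError(ValueError):
    """Malformed FASTQ input; message names the file and line number."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (scaffold, contig, transcript, gene...)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.residues), self.description)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base Phred qualities.

    ``mean_q`` is derived once from the qualities (see
    :func:`mean_read_quality`) and cached.
    """

    id: str
    residues: str
    qualities: tuple[int, ...]
    description: str = ""
    mean_q: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read record id must be non-empty")
        if len(self.qualities) != len(self.residues):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )
        for q in self.qualities:
            if not 0 <= q <= 93:
                raise ValueError(f"read {self.id!r}: Phred score {q} outside [0, 93]")
        mq = mean_read_quality(self) if self.residues else float("nan")
        object.__setattr__(self, "mean_q", mq)

    def __len__(self) -> int:
        return len(self.residues)

    def passes_filter(self, threshold: float = 7.0) -> bool:
        """Pass/fail at a quality threshold; the threshold is inclusive.

        A small epsilon guards the boundary: a read whose per-base
        scores all equal the threshold must pass even though the
        log/antilog round trip can land a hair below it.
        """
        return len(self) > 0 and self.mean_q >= threshold - 1e-9


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def mean_read_quality(read: "ReadRecord | Sequence[int]") -> float:
    """Phred score of the mean per-base error probability.

    Computes ``-10 * log10(mean_i 10**(-q_i / 10))``.  Invariant under
    permutation of the bases and bounded by the min and max per-base
    score.  Raises ``ValueError`` for an empty read, whose quality is
    undefined.
    """
    quals = read.qualities if isinstance(read, ReadRecord) else read
    if len(quals) == 0:
        raise ValueError("mean quality of a zero-length read is undefined")
    mean_err = sum(10.0 ** (-q / 10.0) for q in quals) / len(quals)
    return -10.0 * math.log10(mean_err)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing ``.gz`` paths."""
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b"))  # type: ignore[arg-type]
    return open(path, mode)


def _validate_residues(raw: str, path: Path, lineno: int, exc: type[ValueError]) -> str:
    seq = raw.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise exc(
            f"{path}:{lineno}: illegal residue character(s) "
            f"{''.join(sorted(bad))!r}"
        )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) FASTA file.

    Residues are uppercased; record order is preserved; duplicate ids
    and illegal residue letters raise :class:`FastaParseError` with the
    line number.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: tuple[str, str] | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rec_id, desc = header
        records.append(SequenceRecord(rec_id, "".join(chunks), desc))
        chunks.clear()

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                body = line[1:].strip()
                if not body:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                parts = body.split(None, 1)
                rec_id = parts[0]
                if rec_id in seen:
                    raise FastaParseError(f"{path}:{lineno}: duplicate record id {rec_id!r}")
                seen.add(rec_id)
                header = (rec_id, parts[1] if len(parts) > 1 else "")
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(_validate_residues(line.replace(" ", ""), path, lineno, FastaParseError))
        flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA with ``width``-column wrapped sequence lines."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
            if not rec.residues:
                continue


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse 4-line (possibly gzipped) FASTQ with Phred+33 qualities."""
    path = Path(path)
    reads: list[ReadRecord] = []
    with _open_text(path) as fh:
        lines = iter(enumerate(fh, start=1))
        while True:
            try:
                lineno, head = next(lines)
            except StopIteration:
                break
            head = head.rstrip()
            if not head:
                continue
            if not head.startswith("@"):
                raise FastqParseError(f"{path}:{lineno}: expected '@' header, got {head[:20]!r}")
            body = head[1:].strip()
            if not body:
                raise FastqParseError(f"{path}:{lineno}: empty FASTQ header")
            parts = body.split(None, 1)
            try:
                seq_no, seq = next(lines)
                plus_no, plus = next(lines)
                qual_no, qual = next(lines)
            except StopIteration as err:
                raise FastqParseError(f"{path}:{lineno}: truncated FASTQ record") from err
            seq = _validate_residues(seq.strip(), path, seq_no, FastqParseError)
            if not plus.startswith("+"):
                raise FastqParseError(f"{path}:{plus_no}: expected '+' separator")
            qual = qual.rstrip("\n").rstrip("\r")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"{path}:{qual_no}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            quals = tuple(ord(c) - 33 for c in qual)
            for q in quals:
                if not 0 <= q <= 93:
                    raise FastqParseError(f"{path}:{qual_no}: quality character outside Phred+33 range")
            reads.append(ReadRecord(parts[0], seq, quals, parts[1] if len(parts) > 1 else ""))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for read in reads:
            desc = f" {read.description}" if read.description else ""
            fh.write(f"@{read.id}{desc}\n{read.residues}\n+\n")
            fh.write("".join(chr(q + 33) for q in read.qualities) + "\n")
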