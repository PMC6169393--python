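"""Contiguity and read-set statistics.

N50 is the classic contiguity statistic: sort contig lengths in
descending order and report the first length at which the cumulative
sum reaches half the assembly total.  NG50 substitutes an independently
estimated genome size for the assembly total, so an undersized assembly
can legitimately have NG50 = 0 (reported as n/a in tables).  Size-class
counts (">100 kb", ">1 Mb", ">1 kb", ">10 kb") are strict inequalities.

Read sets are partitioned at a mean-quality threshold (inclusive ≥,
default 7 — the conventional long-read pass/fail cut) and each
partition is summarized separately; depth of coverage is total bases
over genome size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seq_io import ReadRecord, SequenceRecord

__all__ = ["AssemblyStats", "ReadSetStats", "nxx", "assembly_summary", "summarize_reads"]


@dataclass(frozen=True)
class AssemblyStats:
    total_size: int
    n_contigs: int
    n50: int
    ng50: Optional[int]       # None when no expected genome size was given
    n_gt_100kb: int
    n_gt_1mb: int
    longest: int
    expected_genome_size: Optional[int] = None

    @property
    def ng50_display(self) -> str:
        """NG50 for tables: 'n/a' when absent or unreachable."""
        return str(self.ng50) if self.ng50 else "n/a"


@dataclass(frozen=True)
class ReadSetStats:
    n_reads: int
    total_bases: int
    mean_length: float
    longest: int
    n_gt_1kb: int
    n_gt_10kb: int
    mean_length_gt_1kb: float
    mean_length_gt_10kb: float
    depth: float


def nxx(
    lengths: Sequence[int], x: float = 50.0, total_override: Optional[int] = None
) -> int:
    """Nxx / NGxx of a length list.

    With ``total_override`` (an expected genome size) the threshold is
    taken against that value instead of the summed lengths; if the
    cumulative sum never reaches it, returns 0.
    """
    if len(lengths) == 0:
        raise ValueError("Nxx of an empty length list is undefined")
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    total = total_override if total_override is not None else sum(lengths)
    threshold = (x / 100.0) * total
    cum = 0
    for length in sorted(lengths, reverse=True):
        cum += length
        if cum >= threshold:
            return length
    return 0


def assembly_summary(
    contigs: Sequence[SequenceRecord], expected_genome_size: Optional[int] = None
) -> AssemblyStats:
    """Summarize an assembly; raises on an empty contig set."""
    if len(contigs) == 0:
        raise ValueError("cannot summarize an empty assembly")
    lengths = [len(c) for c in contigs]
    return AssemblyStats(
        total_size=sum(lengths),
        n_contigs=len(lengths),
        n50=nxx(lengths, 50),
        ng50=nxx(lengths, 50, expected_genome_size) if expected_genome_size else None,
        n_gt_100kb=sum(1 for n in lengths if n > 100_000),
        n_gt_1mb=sum(1 for n in lengths if n > 1_000_000),
        longest=max(lengths),
        expected_genome_size=expected_genome_size,
    )


def _read_stats(reads: Sequence[ReadRecord], genome_size: int) -> ReadSetStats:
    lengths = [len(r) for r in reads]
    total = sum(lengths)
    gt1 = [n for n in lengths if n > 1_000]
    gt10 = [n for n in lengths if n > 10_000]
    return ReadSetStats(
        n_reads=len(lengths),
        total_bases=total,
        mean_length=total / len(lengths) if lengths else 0.0,
        longest=max(lengths, default=0),
        n_gt_1kb=len(gt1),
        n_gt_10kb=len(gt10),
        mean_length_gt_1kb=sum(gt1) / len(gt1) if gt1 else 0.0,
        mean_length_gt_10kb=sum(gt10) / len(gt10) if gt10 else 0.0,
        depth=total / genome_size,
    )


def summarize_reads(
    reads: Iterable[ReadRecord], genome_size: int, q_threshold: float = 7.0
) -> tuple[ReadSetStats, ReadSetStats]:
    """(pass, fail) statistics at an inclusive mean-quality threshold."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    passed: list[ReadRecord] = []
    failed: list[ReadRecord] = []
    for r in reads:
        (passed if r.passes_filter(q_threshold) else failed).append(r)
    return _read_stats(passed, genome_size), _read_stats(failed, genome_size)
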