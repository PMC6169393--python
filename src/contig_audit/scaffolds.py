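"""Decompose scaffolds into N-free contigs and N-run gaps.

A scaffold is split at every position holding the letter ``N``: maximal
N-free runs become reference contigs, maximal N-runs become gaps.  Only
``N`` splits — other IUPAC ambiguity letters stay inside contigs.  A
gap in the accounting sense must have two flanking contigs, so leading
and trailing N-runs are kept (for lossless reconstruction) but recorded
separately as terminal gaps.

All coordinates are 0-based half-open on the scaffold, so BED export is
a direct dump of the gap records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seq_io import SequenceRecord

__all__ = [
    "ReferenceContig",
    "GapRecord",
    "Scaffold",
    "GapInventory",
    "decompose_scaffold",
    "gap_inventory",
    "gaps_to_bed",
]

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class ReferenceContig:
    """A maximal N-free run of a scaffold."""

    scaffold_id: str
    index: int          # 0-based ordinal along the scaffold
    start: int          # scaffold coordinate, half-open
    end: int
    residues: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.residues):
            raise ValueError("contig span does not match residue length")
        if "N" in self.residues:
            raise ValueError("reference contig contains N")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def name(self) -> str:
        """Emitted contig id, ``scaffoldID.contigIndex``."""
        return f"{self.scaffold_id}.{self.index}"


@dataclass(frozen=True)
class GapRecord:
    """A maximal N-run; internal gap ``i`` sits between contigs ``i`` and ``i+1``."""

    scaffold_id: str
    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Scaffold:
    id: str
    length: int
    contigs: tuple[ReferenceContig, ...]
    internal_gaps: tuple[GapRecord, ...]
    terminal_gaps: tuple[GapRecord, ...]

    @property
    def is_singleton(self) -> bool:
        """True for a gap-free scaffold made of exactly one contig."""
        return len(self.contigs) == 1 and not self.internal_gaps and not self.terminal_gaps

    def reconstruct(self) -> str:
        """Rebuild the original residues from contigs and gaps."""
        pieces = sorted(
            [(c.start, c.residues) for c in self.contigs]
            + [(g.start, "N" * g.length) for g in self.internal_gaps + self.terminal_gaps]
        )
        return "".join(p for _, p in pieces)


@dataclass(frozen=True)
class GapInventory:
    """Table-style gap accounting over a scaffold collection."""

    n_scaffolds: int
    n_multi_contig_scaffolds: int
    n_contigs_in_multi: int
    n_internal_gaps: int
    n_singleton_contigs: int

    def __add__(self, other: "GapInventory") -> "GapInventory":
        return GapInventory(
            self.n_scaffolds + other.n_scaffolds,
            self.n_multi_contig_scaffolds + other.n_multi_contig_scaffolds,
            self.n_contigs_in_multi + other.n_contigs_in_multi,
            self.n_internal_gaps + other.n_internal_gaps,
            self.n_singleton_contigs + other.n_singleton_contigs,
        )


def decompose_scaffold(record: SequenceRecord) -> Scaffold:
    """Split a scaffold at N-runs.

    All-N and empty scaffolds are legal and yield zero contigs.  The
    decomposition is lossless: ``Scaffold.reconstruct()`` returns the
    original residues.
    """
    seq = record.residues
    gap_spans = [(m.start(), m.end()) for m in _N_RUN.finditer(seq)]

    contigs: list[ReferenceContig] = []
    pos = 0
    for g_start, g_end in gap_spans + [(len(seq), len(seq))]:
        if g_start > pos:
            contigs.append(
                ReferenceContig(record.id, len(contigs), pos, g_start, seq[pos:g_start])
            )
        pos = g_end

    internal: list[GapRecord] = []
    terminal: list[GapRecord] = []
    for g_start, g_end in gap_spans:
        flanked = g_start > 0 and g_end < len(seq) and contigs and any(
            c.end == g_start for c in contigs
        ) and any(c.start == g_end for c in contigs)
        if flanked:
            internal.append(GapRecord(record.id, len(internal), g_start, g_end))
        else:
            terminal.append(GapRecord(record.id, len(terminal), g_start, g_end))

    return Scaffold(record.id, len(seq), tuple(contigs), tuple(internal), tuple(terminal))


def gap_inventory(scaffolds: Iterable[Scaffold]) -> GapInventory:
    """Count multi-contig scaffolds, their contigs, internal gaps and singletons.

    For every scaffold with k ≥ 2 contigs the internal gap count is
    exactly k − 1, so ``n_internal_gaps == n_contigs_in_multi −
    n_multi_contig_scaffolds`` always holds.
    """
    n_scaffolds = n_multi = n_contigs_multi = n_gaps = n_singletons = 0
    for sc in scaffolds:
        n_scaffolds += 1
        if len(sc.contigs) >= 2:
            n_multi += 1
            n_contigs_multi += len(sc.contigs)
            n_gaps += len(sc.internal_gaps)
        elif sc.is_singleton:
            n_singletons += 1
    return GapInventory(n_scaffolds, n_multi, n_contigs_multi, n_gaps, n_singletons)


def gaps_to_bed(scaffolds: Sequence[Scaffold], include_terminal: bool = False) -> str:
    """BED3+ text for gap records: scaffold, start, end, gap_index, length."""
    lines = []
    for sc in scaffolds:
        gaps = sc.internal_gaps + (sc.terminal_gaps if include_terminal else ())
        for g in sorted(gaps, key=lambda g: g.start):
            lines.append(f"{g.scaffold_id}\t{g.start}\t{g.end}\t{g.index}\t{g.length}")
    return "\n".join(lines) + ("\n" if lines else "")
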