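"""Gap-closure and singleton accounting against a new assembly.

Given a reference assembly decomposed into scaffolds/contigs/gaps and a
new (contig-only) assembly, this module answers two questions:

* how many gap-free singleton reference scaffolds above a length floor
  can be placed on the new assembly at high identity, and
* how many reference gaps are *potentially closed*, i.e. evidenced to
  be spanned by a single contig of the new assembly.

Two closure rules are provided.  The ``loose`` rule declares a gap
closed when both of its flanking reference contigs place on one common
assembly contig — the literal "two contigs on the same assembled
contig" bookkeeping.  The ``strict`` rule additionally requires the two
placements to agree in strand, to occur in scaffold order along the
target, and to sit no farther apart than the gap length plus a
tolerance; it guards against coincidental co-placement on repeat-rich
targets.  Strict closures are a subset of loose closures by
construction.

Reference scaffolds are processed one at a time: placements of one
scaffold's contigs never influence another scaffold's verdicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .mapper import Placement, TargetIndex, detect_containment, place_on_each_target
from .scaffolds import Scaffold
from .seq_io import SequenceRecord

__all__ = [
    "SingletonReport",
    "GapVerdict",
    "GapClosureReport",
    "evaluate_singletons",
    "evaluate_gap_closure",
    "closure_percentage",
    "genome_fraction",
]

DEFAULT_MIN_IDENTITY = 0.99
DEFAULT_SINGLETON_MIN_LEN = 10_000
DEFAULT_MIN_FLANK_LEN = 500
DEFAULT_STRICT_TOLERANCE = 1_000
DEFAULT_MIN_QUERY_COV = 0.9


def _well_placed(placements, min_query_cov: float):
    """Placements that align at least ``min_query_cov`` of their query.

    An identity filter alone would accept a fragment of a query placed
    perfectly (e.g. a reference contig truncated by an assembly break),
    which is not evidence that the whole contig lies on that target.
    """
    return [
        p for p in placements if (p.q_end - p.q_start) >= min_query_cov * p.query_length
    ]


@dataclass(frozen=True)
class SingletonReport:
    """Placement tally for gap-free single-contig reference scaffolds."""

    n_singletons_total: int
    n_singletons_ge_min_len: int
    n_placed: int
    min_len: int
    min_identity: float

    @property
    def fraction_placed(self) -> float:
        if self.n_singletons_ge_min_len == 0:
            return 0.0
        return self.n_placed / self.n_singletons_ge_min_len


@dataclass(frozen=True)
class GapVerdict:
    """Per-gap outcome; ``status`` is closed / open / indeterminate."""

    scaffold_id: str
    gap_index: int
    gap_length: int
    left: Optional[Placement]
    right: Optional[Placement]
    closed: bool
    status: str
    closing_target_id: Optional[str] = None


@dataclass(frozen=True)
class GapClosureReport:
    mode: str
    rows: tuple[GapVerdict, ...]
    n_gaps: int
    n_closed: int
    n_indeterminate: int
    n_contained_placements: int
    contained: tuple[Placement, ...] = field(default=(), repr=False)

    @property
    def percent_closed(self) -> int:
        return closure_percentage(self.n_closed, self.n_gaps)


def closure_percentage(n_closed: int, n_gaps: int) -> int:
    """Integer percent of gaps closed, rounded half away from zero."""
    if n_gaps <= 0:
        raise ValueError("percentage undefined for zero gaps")
    if n_closed < 0 or n_closed > n_gaps:
        raise ValueError("n_closed must lie in [0, n_gaps]")
    return int(math.floor(100.0 * n_closed / n_gaps + 0.5))


def evaluate_singletons(
    reference: Iterable[Scaffold],
    assembly: "Iterable[SequenceRecord] | TargetIndex",
    min_len: int = DEFAULT_SINGLETON_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
) -> SingletonReport:
    """Count singleton reference scaffolds placeable on the assembly.

    Only scaffolds consisting of exactly one contig and no N at all
    enter the tally; the length filter is strict (``> min_len``).
    """
    index = assembly if isinstance(assembly, TargetIndex) else TargetIndex(assembly)
    n_total = n_eligible = n_placed = 0
    for sc in reference:
        if not sc.is_singleton:
            continue
        n_total += 1
        if sc.length <= min_len:
            continue
        n_eligible += 1
        query = SequenceRecord(sc.id, sc.contigs[0].residues)
        if _well_placed(place_on_each_target(query, index, min_identity), min_query_cov):
            n_placed += 1
    return SingletonReport(n_total, n_eligible, n_placed, min_len, min_identity)


def _strict_compatible(
    left: Placement, right: Placement, gap_length: int, tolerance: int
) -> bool:
    if left.strand != right.strand:
        return False
    if left.strand == "+":
        distance = right.t_start - left.t_end
    else:
        distance = left.t_start - right.t_end
    # flank alignments may run a little into each other across the gap
    return -tolerance <= distance <= gap_length + tolerance


def evaluate_gap_closure(
    reference: Iterable[Scaffold],
    assembly: "Iterable[SequenceRecord] | TargetIndex",
    mode: str = "loose",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_flank_len: int = DEFAULT_MIN_FLANK_LEN,
    strict_tolerance: int = DEFAULT_STRICT_TOLERANCE,
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
) -> GapClosureReport:
    """Decide, per reference gap, whether the assembly closes it.

    Flanking contigs shorter than ``min_flank_len`` are treated as
    unplaceable and their gaps reported ``indeterminate`` (counted as
    open): placements of very short queries are unreliable and would
    otherwise manufacture closures.
    """
    if mode not in ("loose", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    index = assembly if isinstance(assembly, TargetIndex) else TargetIndex(assembly)

    rows: list[GapVerdict] = []
    contained_all: list[Placement] = []
    n_closed = n_gaps = n_indet = 0
    for sc in reference:
        if len(sc.contigs) < 2:
            continue
        placements: dict[int, list[Placement]] = {}
        for contig in sc.contigs:
            if len(contig) < min_flank_len:
                continue
            query = SequenceRecord(contig.name, contig.residues)
            placements[contig.index] = _well_placed(
                place_on_each_target(query, index, min_identity), min_query_cov
            )

        flat = [p for pls in placements.values() for p in pls]
        contained_all.extend(p for p in detect_containment(flat) if p.contained_in)

        for gap in sc.internal_gaps:
            n_gaps += 1
            left_list = placements.get(gap.index, [])
            right_list = placements.get(gap.index + 1, [])
            left_ok = gap.index in placements
            right_ok = (gap.index + 1) in placements
            best_pair: Optional[tuple[Placement, Placement]] = None
            for lp in left_list:
                for rp in right_list:
                    if lp.target_id != rp.target_id:
                        continue
                    if mode == "strict" and not _strict_compatible(
                        lp, rp, gap.length, strict_tolerance
                    ):
                        continue
                    if best_pair is None or lp.score + rp.score > (
                        best_pair[0].score + best_pair[1].score
                    ):
                        best_pair = (lp, rp)
            if best_pair is not None:
                n_closed += 1
                rows.append(
                    GapVerdict(
                        sc.id, gap.index, gap.length,
                        best_pair[0], best_pair[1], True, "closed",
                        best_pair[0].target_id,
                    )
                )
            else:
                status = "open" if (left_ok and right_ok) else "indeterminate"
                if status == "indeterminate":
                    n_indet += 1
                rows.append(
                    GapVerdict(
                        sc.id, gap.index, gap.length,
                        left_list[0] if left_list else None,
                        right_list[0] if right_list else None,
                        False, status,
                    )
                )
    return GapClosureReport(
        mode=mode,
        rows=tuple(rows),
        n_gaps=n_gaps,
        n_closed=n_closed,
        n_indeterminate=n_indet,
        n_contained_placements=len(contained_all),
        contained=tuple(contained_all),
    )


def genome_fraction(placements: Sequence[Placement], genome_size: int) -> float:
    """Aligned fraction of a genome: union of target intervals / size.

    Overlapping placements are merged per target before summing, so no
    base is counted twice.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    by_target: dict[str, list[tuple[int, int]]] = {}
    for p in placements:
        if p.t_end > p.t_start:
            by_target.setdefault(p.target_id, []).append((p.t_start, p.t_end))
    covered = 0
    for spans in by_target.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return covered / genome_size
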