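"""Transcript representation scoring against an assembly.

A transcript counts as *properly represented* when at least
``min_cov`` (default 90%) of its length aligns to a single assembly
contig at a weighted identity of at least ``min_identity`` (default
95%).  Split placements on one contig — the genomic alignment of a
multi-exon transcript breaks at introns — are unioned on the
transcript; placements on different contigs are never pooled, which is
stricter than HSP pooling across subjects but avoids crediting
assemblies that scatter a gene over several contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .mapper import TargetIndex, collect_placements, place_on_each_target
from .seq_io import SequenceRecord

__all__ = ["TranscriptVerdict", "TranscriptAlignmentSummary", "evaluate_transcripts"]

# floor for gathering candidate placements; well below any sensible
# min_identity so borderline segments still contribute to coverage
_CANDIDATE_FLOOR = 0.5

# chains may not jump farther than this on the target: an intron-sized
# gap must split a transcript into separate (exon-like) placements
# rather than be absorbed, as alignment columns, into one placement
_TRANSCRIPT_MAX_GAP = 1_000


@dataclass(frozen=True)
class TranscriptVerdict:
    id: str
    target_id: str | None
    covered_fraction: float
    weighted_identity: float
    proper: bool


@dataclass(frozen=True)
class TranscriptAlignmentSummary:
    n_transcripts: int
    n_proper: int
    rows: tuple[TranscriptVerdict, ...]

    @property
    def fraction_proper(self) -> float:
        return self.n_proper / self.n_transcripts if self.n_transcripts else 0.0


def _union_len(spans: Sequence[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(spans):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def evaluate_transcripts(
    transcripts: Iterable[SequenceRecord],
    genome: "Iterable[SequenceRecord] | TargetIndex",
    min_cov: float = 0.90,
    min_identity: float = 0.95,
) -> TranscriptAlignmentSummary:
    """Score each transcript on its single best assembly contig.

    Both thresholds are inclusive (≥).  ``covered_fraction`` is the
    unioned query span over the transcript length; ``weighted_identity``
    is the matches-weighted mean identity over the retained placements.
    """
    index = genome if isinstance(genome, TargetIndex) else TargetIndex(genome)
    rows: list[TranscriptVerdict] = []
    n_proper = 0
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("empty transcript set")
    for tr in transcripts:
        candidates = place_on_each_target(
            tr, index, _CANDIDATE_FLOOR, max_gap=_TRANSCRIPT_MAX_GAP
        )
        if not candidates:
            rows.append(TranscriptVerdict(tr.id, None, 0.0, 0.0, False))
            continue
        best_target = candidates[0].target_id
        pls = collect_placements(
            tr, index, best_target, _CANDIDATE_FLOOR, max_gap=_TRANSCRIPT_MAX_GAP
        )
        if not pls:
            rows.append(TranscriptVerdict(tr.id, best_target, 0.0, 0.0, False))
            continue
        covered = _union_len([(p.q_start, p.q_end) for p in pls]) / len(tr)
        total_matches = sum(p.matches for p in pls)
        wid = (
            sum(p.identity * p.matches for p in pls) / total_matches
            if total_matches
            else 0.0
        )
        proper = covered >= min_cov and wid >= min_identity
        n_proper += proper
        rows.append(TranscriptVerdict(tr.id, best_target, covered, wid, proper))
    return TranscriptAlignmentSummary(len(rows), n_proper, tuple(rows))
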