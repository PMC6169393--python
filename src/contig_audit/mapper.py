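"""Seed-chain-align placement of query sequences onto target contigs.

The pipeline is the standard long-read mapping recipe at desk scale:

1. *minimizer seeding* — canonical k-mers, smallest (by a mixed integer
   hash) in each w-window, indexed once per target set;
2. *colinear chaining* — dynamic programming over anchors shared by a
   query and a target, strictly increasing in query and (strand
   adjusted) target coordinates, scored by covered query bases minus a
   gap-difference penalty;
3. *base-level alignment* — the chain pins its terminal anchors as
   exact matches, the spanned region is aligned with bounded edit
   distance (edlib) and the chain's ragged ends are extended outward
   when the extension scores positively.

Identity is reported BLAST-style as identical columns over alignment
columns, indels included, so a ">99% identity" placement filter has the
meaning users of alignment tables expect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from intervaltree import IntervalTree

from .seq_io import SequenceRecord, reverse_complement

__all__ = [
    "Anchor",
    "Placement",
    "TargetIndex",
    "index_and_anchor",
    "chain_anchors",
    "place_contig",
    "place_on_each_target",
    "collect_placements",
    "detect_containment",
    "placements_to_paf",
]

DEFAULT_K = 15
DEFAULT_W = 10
DEFAULT_MAX_GAP = 10_000
_CHAIN_LOOKBACK = 64      # minimap2-style bounded predecessor search
_EXTENSION_MIN_IDENTITY = 0.70
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i


@dataclass(frozen=True)
class Anchor:
    """An exact k-mer match between query and target.

    ``strand`` is '+' when the query k-mer matches the target forward
    strand, '-' when it matches the reverse complement.  For '-'
    anchors ``target_pos`` is given on the reverse-complemented target
    so that chains increase in both coordinates on either strand.
    """

    query_pos: int
    target_pos: int
    span: int
    strand: str
    target_id: str


@dataclass(frozen=True)
class Placement:
    """One query located on one target, with a base-level identity."""

    query_id: str
    target_id: str
    strand: str
    q_start: int
    q_end: int
    t_start: int            # forward-strand target coordinates, half-open
    t_end: int
    matches: int
    aln_len: int
    query_length: int
    target_length: int
    contained_in: Optional[str] = None
    primary: bool = True

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len if self.aln_len else 0.0

    @property
    def score(self) -> float:
        """Ranking score: identity × aligned query bases."""
        return self.identity * (self.q_end - self.q_start)


def _mix64(x: np.ndarray) -> np.ndarray:
    """Invertible integer mix (splitmix64 finalizer) for minimizer ordering."""
    x = x.astype(np.uint64)
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes and strand flags for every position.

    Returns ``(codes, strands)`` of length ``len(seq) - k + 1``;
    positions whose window holds a non-ACGT letter get code −1.
    ``strands`` is ``True`` where the forward k-mer is canonical.
    """
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    base = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = base >= 0
    b = np.where(valid, base, 0)
    windows = np.lib.stride_tricks.sliding_window_view(b, k)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = windows @ pow4
    rc_windows = 3 - windows[:, ::-1]
    rev = rc_windows @ pow4
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    canon = np.minimum(fwd, rev)
    strands = fwd <= rev
    canon[~ok] = -1
    return canon, strands


def _minimizers(seq: str, k: int, w: int) -> list[tuple[int, int, bool]]:
    """(pos, canonical code, forward-is-canonical) minimizers of a sequence."""
    codes, strands = _kmer_codes(seq, k)
    n = len(codes)
    if n == 0:
        return []
    order = _mix64(np.where(codes >= 0, codes, 0))
    order[codes < 0] = np.iinfo(np.uint64).max  # never pick invalid k-mers
    if n <= w:
        idx = np.array([int(order.argmin())])
    else:
        wins = np.lib.stride_tricks.sliding_window_view(order, w)
        idx = np.unique(wins.argmin(axis=1) + np.arange(wins.shape[0]))
    out = []
    for i in idx:
        if codes[i] >= 0:
            out.append((int(i), int(codes[i]), bool(strands[i])))
    return out


class TargetIndex:
    """Minimizer index over a target set, built once and reused per query."""

    def __init__(self, targets: Iterable[SequenceRecord], k: int = DEFAULT_K, w: int = DEFAULT_W):
        if k < 11:
            raise ValueError("k must be >= 11")
        if w < 1:
            raise ValueError("w must be >= 1")
        self.k = k
        self.w = w
        self.targets: dict[str, SequenceRecord] = {}
        self._table: dict[int, list[tuple[str, int, bool]]] = {}
        for rec in targets:
            if rec.id in self.targets:
                raise ValueError(f"duplicate target id {rec.id!r}")
            self.targets[rec.id] = rec
            for pos, code, fwd in _minimizers(rec.residues, k, w):
                self._table.setdefault(code, []).append((rec.id, pos, fwd))

    def anchors(self, query: SequenceRecord) -> list[Anchor]:
        """Verified exact-match anchors of a query against the index."""
        k = self.k
        out: list[Anchor] = []
        for q_pos, code, q_fwd in _minimizers(query.residues, k, self.w):
            for t_id, t_pos, t_fwd in self._table.get(code, ()):
                strand = "+" if q_fwd == t_fwd else "-"
                t_len = len(self.targets[t_id])
                q_kmer = query.residues[q_pos : q_pos + k]
                if strand == "+":
                    t_kmer = self.targets[t_id].residues[t_pos : t_pos + k]
                    adj = t_pos
                else:
                    t_kmer = reverse_complement(
                        self.targets[t_id].residues[t_pos : t_pos + k]
                    )
                    adj = t_len - k - t_pos
                if q_kmer == t_kmer:  # guards against hash-level coincidences / ambiguity codes
                    out.append(Anchor(q_pos, adj, k, strand, t_id))
        return out


def index_and_anchor(
    query: SequenceRecord,
    targets: "Iterable[SequenceRecord] | TargetIndex",
    k: int = DEFAULT_K,
    w: int = DEFAULT_W,
) -> list[Anchor]:
    """Anchor a single query; accepts a prebuilt :class:`TargetIndex`."""
    index = targets if isinstance(targets, TargetIndex) else TargetIndex(targets, k, w)
    return index.anchors(query)


def _chain_score(anchors: Sequence[Anchor], max_gap: int) -> tuple[float, list[Anchor]]:
    """Best colinear chain among anchors of one (target, strand) group.

    DP over anchors sorted by (query_pos, target_pos); predecessor
    search is bounded to a fixed lookback window, which is exact on all
    but adversarial inputs and keeps chaining linear-time.
    """
    anchors = sorted(anchors, key=lambda a: (a.query_pos, a.target_pos))
    n = len(anchors)
    if n == 0:
        return 0.0, []
    k = anchors[0].span
    score = [float(k)] * n
    parent = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(max(0, i - _CHAIN_LOOKBACK), i):
            aj = anchors[j]
            dq = ai.query_pos - aj.query_pos
            dt = ai.target_pos - aj.target_pos
            if dq <= 0 or dt <= 0:
                continue
            if dq > max_gap or dt > max_gap:
                continue
            gain = min(k, dq) - 0.01 * abs(dq - dt)
            if score[j] + gain > score[i]:
                score[i] = score[j] + gain
                parent[i] = j
    best = max(range(n), key=lambda i: (score[i], -anchors[i].query_pos, -anchors[i].target_pos))
    chain: list[Anchor] = []
    i = best
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    chain.reverse()
    return score[best], chain


def chain_anchors(
    anchors: Iterable[Anchor], max_gap: int = DEFAULT_MAX_GAP
) -> list[Anchor]:
    """Best colinear chain over all (target, strand) groups of one query.

    Ties break deterministically: higher score, then lexicographically
    smaller target id, then '+' before '-', then smaller target start.
    """
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.target_id, a.strand), []).append(a)
    best_chain: list[Anchor] = []
    best_key: tuple = ()
    for (t_id, strand), group in groups.items():
        sc, chain = _chain_score(group, max_gap)
        if not chain:
            continue
        key = (-sc, t_id, strand, chain[0].target_pos)
        if not best_chain or key < best_key:
            best_chain, best_key = chain, key
    return best_chain


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(alignment columns, edit operations) from an edlib extended cigar."""
    cols = edits = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch != "=":
                edits += n
    return cols, edits


def _aligned_counts(query: str, target: str, mode: str) -> tuple[int, int, int, int]:
    """matches, columns, target-span, query-span for an edlib alignment."""
    if not query and not target:
        return 0, 0, 0, 0
    if not query:
        return (0, len(target), len(target), 0) if mode == "NW" else (0, 0, 0, 0)
    if not target:
        return 0, len(query), 0, len(query)
    res = edlib.align(query, target, task="path", mode=mode)
    cols, edits = _cigar_stats(res["cigar"])
    loc = res["locations"][0]
    t_span = (loc[1] - (loc[0] or 0) + 1) if loc[1] is not None else len(target)
    return cols - edits, cols, t_span, len(query)


@dataclass(frozen=True)
class _AlignedChain:
    """A chain fleshed out to a base-level alignment on one target/strand."""

    target_id: str
    strand: str
    q_start: int
    q_end: int
    ta_start: int           # coordinates on the strand-adjusted target
    ta_end: int
    matches: int
    aln_len: int


def _align_chain(
    query: SequenceRecord,
    target: SequenceRecord,
    chain: Sequence[Anchor],
    extend_ends: bool = True,
) -> Optional[_AlignedChain]:
    """Align the chain-spanned region and extend the ragged ends.

    The first and last chain anchors are exact matches, so the core is
    a global (NW) alignment between the pinned coordinates.  Each
    unanchored query flank is aligned against a proportional target
    window and kept only if the extension's own identity clears a
    floor; random sequence aligns at ~50% identity under unit edit
    costs, true homologous flanks at long-read error rates stay above
    ~80%, so the floor cleanly clips extensions into unrelated
    sequence.
    """
    if not chain:
        return None
    strand = chain[0].strand
    k = chain[0].span
    tseq = target.residues if strand == "+" else reverse_complement(target.residues)
    qs, qe = chain[0].query_pos, chain[-1].query_pos + k
    ts, te = chain[0].target_pos, chain[-1].target_pos + k
    core_m, core_cols, _, _ = _aligned_counts(query.residues[qs:qe], tseq[ts:te], "NW")

    matches, cols = core_m, core_cols
    q_lo, q_hi, t_lo, t_hi = qs, qe, ts, te
    if extend_ends:
        left = query.residues[:qs]
        if left:
            w_lo = max(0, ts - int(len(left) * 1.5) - 32)
            lw = tseq[w_lo:ts]
            m, c, t_span, _ = _aligned_counts(left[::-1], lw[::-1], "SHW")
            if m > _EXTENSION_MIN_IDENTITY * c:
                matches += m
                cols += c
                q_lo = 0
                t_lo = ts - t_span
        right = query.residues[qe:]
        if right:
            w_hi = min(len(tseq), te + int(len(right) * 1.5) + 32)
            rw = tseq[te:w_hi]
            m, c, t_span, _ = _aligned_counts(right, rw, "SHW")
            if m > _EXTENSION_MIN_IDENTITY * c:
                matches += m
                cols += c
                q_hi = len(query.residues)
                t_hi = te + t_span
    return _AlignedChain(target.id, strand, q_lo, q_hi, t_lo, t_hi, matches, cols)


def _to_placement(query: SequenceRecord, target: SequenceRecord, ac: _AlignedChain) -> Placement:
    t_len = len(target)
    if ac.strand == "+":
        t_start, t_end = ac.ta_start, ac.ta_end
    else:
        t_start, t_end = t_len - ac.ta_end, t_len - ac.ta_start
    return Placement(
        query_id=query.id,
        target_id=target.id,
        strand=ac.strand,
        q_start=ac.q_start,
        q_end=ac.q_end,
        t_start=t_start,
        t_end=t_end,
        matches=ac.matches,
        aln_len=ac.aln_len,
        query_length=len(query),
        target_length=t_len,
    )


def place_on_each_target(
    query: SequenceRecord,
    index: TargetIndex,
    min_identity: float = 0.0,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Placement]:
    """Best placement of the query on every target it anchors to.

    One placement per (target, strand) chain, filtered by
    ``min_identity``; within one target only the best strand is kept.
    Sorted best-first with deterministic tie-breaking; the first entry
    is flagged primary.
    """
    anchors = index.anchors(query)
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.target_id, a.strand), []).append(a)
    per_target: dict[str, Placement] = {}
    for (t_id, strand), group in sorted(groups.items()):
        _, chain = _chain_score(group, max_gap)
        ac = _align_chain(query, index.targets[t_id], chain)
        if ac is None:
            continue
        pl = _to_placement(query, index.targets[t_id], ac)
        if pl.identity < min_identity or pl.aln_len == 0:
            continue
        prev = per_target.get(t_id)
        if prev is None or (pl.score, pl.strand == "+") > (prev.score, prev.strand == "+"):
            per_target[t_id] = pl
    ranked = sorted(
        per_target.values(), key=lambda p: (-p.score, p.target_id, p.t_start)
    )
    return [replace(p, primary=(i == 0)) for i, p in enumerate(ranked)]


def place_contig(
    query: SequenceRecord,
    targets: "Iterable[SequenceRecord] | TargetIndex",
    min_identity: float = 0.99,
    k: int = DEFAULT_K,
    w: int = DEFAULT_W,
    max_gap: int = DEFAULT_MAX_GAP,
) -> Optional[Placement]:
    """Single best placement of a query, or None below ``min_identity``.

    Ranking is identity × aligned query bases, then smallest target id,
    then smallest target start (reproducible tie-breaking).
    """
    index = targets if isinstance(targets, TargetIndex) else TargetIndex(targets, k, w)
    placements = place_on_each_target(query, index, min_identity, max_gap)
    return placements[0] if placements else None


def collect_placements(
    query: SequenceRecord,
    index: TargetIndex,
    target_id: str,
    min_identity: float = 0.0,
    max_gap: int = DEFAULT_MAX_GAP,
    max_chains: int = 16,
) -> list[Placement]:
    """All disjoint chained placements of a query on one target.

    Chains are peeled off best-first, removing each chain's anchors, so
    split (exon-like) placements of one query on one target are all
    recovered.  Used by transcript evaluation.
    """
    target = index.targets[target_id]
    remaining = [a for a in index.anchors(query) if a.target_id == target_id]
    out: list[Placement] = []
    for _ in range(max_chains):
        chain = chain_anchors(remaining, max_gap)
        if not chain:
            break
        ac = _align_chain(query, target, chain)
        if ac is not None:
            pl = _to_placement(query, target, ac)
            if pl.identity >= min_identity and pl.aln_len > 0:
                out.append(pl)
        covered = {(a.query_pos, a.target_pos, a.strand) for a in chain}
        span_lo = min(a.query_pos for a in chain)
        span_hi = max(a.query_pos for a in chain) + chain[0].span
        remaining = [
            a
            for a in remaining
            if (a.query_pos, a.target_pos, a.strand) not in covered
            and not (span_lo <= a.query_pos < span_hi)
        ]
    return sorted(out, key=lambda p: (-p.score, p.q_start))


def detect_containment(placements: Sequence[Placement]) -> list[Placement]:
    """Flag placements whose target interval nests inside another's.

    B is contained in A iff they share a target, A ≠ B, and
    ``[t_start_B, t_end_B) ⊆ [t_start_A, t_end_A)``.  Ties resolve
    toward the largest enclosing interval.  Returns new Placement
    objects in the input order with ``contained_in`` set.
    """
    by_target: dict[str, IntervalTree] = {}
    for i, p in enumerate(placements):
        if p.t_end > p.t_start:
            by_target.setdefault(p.target_id, IntervalTree()).addi(p.t_start, p.t_end, i)
    out = []
    for i, p in enumerate(placements):
        parent = None
        best_span = -1
        tree = by_target.get(p.target_id)
        if tree is not None:
            for iv in tree.overlap(p.t_start, p.t_end):
                j = iv.data
                if j == i:
                    continue
                q = placements[j]
                if q.t_start <= p.t_start and p.t_end <= q.t_end:
                    span = q.t_end - q.t_start
                    if span == p.t_end - p.t_start and q.t_start == p.t_start:
                        # identical intervals: contain the later one in the earlier
                        if j > i:
                            continue
                    if span > best_span or (
                        span == best_span and (parent is None or q.query_id < parent)
                    ):
                        parent, best_span = q.query_id, span
        out.append(replace(p, contained_in=parent))
    return out


def placements_to_paf(placements: Iterable[Placement]) -> str:
    """Render placements as PAF lines with an ``id:f`` identity tag."""
    lines = []
    for p in placements:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    p.query_id, p.query_length, p.q_start, p.q_end, p.strand,
                    p.target_id, p.target_length, p.t_start, p.t_end,
                    p.matches, p.aln_len, 255,
                )
            )
            + f"\tid:f:{p.identity:.6f}"
            + ("\ttp:A:P" if p.primary else "\ttp:A:S")
        )
    return "\n".join(lines) + ("\n" if lines else "")
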