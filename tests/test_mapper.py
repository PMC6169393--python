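import itertools

import edlib
import numpy as np
import pytest
from Bio import Align

from contig_audit.mapper import (
    Anchor,
    Placement,
    TargetIndex,
    chain_anchors,
    detect_containment,
    index_and_anchor,
    place_contig,
    place_on_each_target,
    placements_to_paf,
)
from contig_audit.polish import CorruptionSpec, corrupt_sequence
from contig_audit.seq_io import SequenceRecord, reverse_complement


def _mutate(rng, seq, n_subs):
    out = list(seq)
    for i in rng.choice(len(seq), n_subs, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(11)
    return "".join(rng.choice(list("ACGT"), 40_000))


@pytest.fixture(scope="module")
def index(genome):
    return TargetIndex([SequenceRecord("t1", genome)])


class TestAnchoring:
    def test_identical_query_tiles_forward(self, genome, index):
        q = SequenceRecord("q", genome[5_000:7_000])
        anchors = index.anchors(q)
        assert anchors and all(a.strand == "+" for a in anchors)
        # minimizers appear at least once per window of w+k bases
        positions = sorted(a.query_pos for a in anchors)
        gaps = np.diff(positions)
        assert gaps.max() <= index.w + index.k

    def test_reverse_complement_query_anchors_minus(self, genome, index):
        q = SequenceRecord("q", reverse_complement(genome[5_000:7_000]))
        anchors = index.anchors(q)
        assert anchors and all(a.strand == "-" for a in anchors)

    def test_anchors_subset_of_brute_force_kmer_matches(self, rng, random_seq):
        target = random_seq(rng, 2_000)
        query = target[300:900] + random_seq(rng, 200)
        k = 11
        anchors = index_and_anchor(
            SequenceRecord("q", query), [SequenceRecord("t", target)], k=k, w=5
        )
        exact = set()
        kmers = {}
        for i in range(len(target) - k + 1):
            kmers.setdefault(target[i : i + k], []).append(i)
        for j in range(len(query) - k + 1):
            kq = query[j : j + k]
            for i in kmers.get(kq, []):
                exact.add((j, i, "+"))
            rc = reverse_complement(kq)
            for i in kmers.get(rc, []):
                exact.add((j, len(target) - k - i, "-"))
        got = {(a.query_pos, a.target_pos, a.strand) for a in anchors}
        assert got and got <= exact

    def test_kmers_containing_n_never_anchor(self):
        target = SequenceRecord("t", "ACGTACGTACGTACGTACGT" * 5)
        query = SequenceRecord("q", "ACGTACGTNACGTACGTACG")
        anchors = index_and_anchor(query, [target], k=11, w=1)
        for a in anchors:
            assert "N" not in query.residues[a.query_pos : a.query_pos + 11]

    def test_k_longer_than_query_gives_no_anchors(self, index):
        assert index.anchors(SequenceRecord("q", "ACGT")) == []


def _oracle_best_chain_score(anchors, max_gap, k):
    """Exhaustive enumeration of every colinear chain (n <= 12)."""
    best = 0.0
    idx = sorted(range(len(anchors)), key=lambda i: (anchors[i].query_pos, anchors[i].target_pos))
    for r in range(1, len(idx) + 1):
        for combo in itertools.combinations(idx, r):
            chain = [anchors[i] for i in combo]
            score = float(k)
            ok = True
            for a, b in zip(chain, chain[1:]):
                dq = b.query_pos - a.query_pos
                dt = b.target_pos - a.target_pos
                if dq <= 0 or dt <= 0 or dq > max_gap or dt > max_gap:
                    ok = False
                    break
                score += min(k, dq) - 0.01 * abs(dq - dt)
            if ok:
                best = max(best, score)
    return best


class TestChaining:
    def _score(self, chain, k):
        score = float(k)
        for a, b in zip(chain, chain[1:]):
            score += min(k, b.query_pos - a.query_pos) - 0.01 * abs(
                (b.query_pos - a.query_pos) - (b.target_pos - a.target_pos)
            )
        return score

    def test_exact_substring_chain_covers_it(self, genome, index):
        q = SequenceRecord("q", genome[10_000:11_000])
        chain = chain_anchors(index.anchors(q))
        assert chain[0].query_pos < index.k + index.w
        assert chain[-1].query_pos > 1_000 - 2 * (index.k + index.w)

    def test_matches_exhaustive_enumeration(self, rng):
        k = 15
        for _ in range(30):
            n = int(rng.integers(2, 13))
            anchors = [
                Anchor(int(rng.integers(0, 400)), int(rng.integers(0, 400)), k, "+", "t")
                for _ in range(n)
            ]
            got = chain_anchors(anchors, max_gap=200)
            assert self._score(got, k) == pytest.approx(
                _oracle_best_chain_score(anchors, 200, k)
            )

    def test_longer_run_wins_across_max_gap(self):
        short = [Anchor(q, q, 15, "+", "t") for q in (0, 20)]
        long = [Anchor(q, q + 50_000, 15, "+", "t") for q in (40_000, 40_020, 40_040)]
        chain = chain_anchors(short + long, max_gap=1_000)
        assert [a.query_pos for a in chain] == [40_000, 40_020, 40_040]

    def test_empty_anchor_set_gives_empty_chain(self):
        assert chain_anchors([]) == []


class TestPlacement:
    def test_exact_substring_identity_one(self, genome, index):
        q = SequenceRecord("q", genome[12_000:13_000])
        p = place_contig(q, index)
        assert p.identity == 1.0 and p.strand == "+"
        assert (p.t_start, p.t_end) == (12_000, 13_000)
        assert (p.q_start, p.q_end) == (0, 1_000)

    def test_single_mismatch_matches_full_dp(self, genome, index):
        rng = np.random.default_rng(2)
        q = SequenceRecord("q", _mutate(rng, genome[20_000:20_100], 1))
        p = place_contig(q, index, min_identity=0.9)
        assert p.matches == 99 and p.aln_len == 100
        assert p.identity == pytest.approx(0.99)

    def test_unrelated_query_rejected(self, index, rng, random_seq):
        q = SequenceRecord("q", random_seq(rng, 1_000))
        assert place_contig(q, index, min_identity=0.99) is None

    def test_self_placement_spans_full_length(self, rng, random_seq):
        t = SequenceRecord("t", random_seq(rng, 3_000))
        p = place_contig(t, [t])
        assert p.identity == 1.0
        assert (p.q_start, p.q_end) == (0, 3_000)
        assert (p.t_start, p.t_end) == (0, 3_000)

    def test_strand_symmetry(self, genome, index):
        fwd = place_contig(SequenceRecord("q", genome[15_000:16_500]), index)
        rev = place_contig(
            SequenceRecord("q", reverse_complement(genome[15_000:16_500])), index
        )
        assert (fwd.strand, rev.strand) == ("+", "-")
        assert fwd.identity == rev.identity == 1.0
        assert (fwd.t_start, fwd.t_end) == (rev.t_start, rev.t_end)

    def test_deterministic(self, genome, index):
        rng = np.random.default_rng(7)
        q = SequenceRecord("q", _mutate(rng, genome[25_000:27_000], 30))
        assert place_contig(q, index) == place_contig(q, index)

    def test_identity_tracks_independent_dp_aligner(self, rng, random_seq):
        """Dual route: seed-chain-align vs biopython's exhaustive DP."""
        aligner = Align.PairwiseAligner(
            mode="global", match_score=1, mismatch_score=-1,
            open_gap_score=-1, extend_gap_score=-1,
        )
        for trial in range(10):
            t = random_seq(rng, 300)
            q, _ = corrupt_sequence(
                SequenceRecord("q", t),
                CorruptionSpec.from_total(0.04, seed=trial),
            )
            p = place_contig(q, [SequenceRecord("t", t)], min_identity=0.0, k=11, w=3)
            aln = aligner.align(q.residues, t)[0]
            counts = aln.counts()
            dp_identity = counts.identities / (
                counts.identities + counts.mismatches + counts.gaps
            )
            assert p is not None
            assert abs(p.identity - dp_identity) < 0.005

    def test_secondary_placements_flagged(self, rng, random_seq):
        seg = random_seq(rng, 1_500)
        targets = [SequenceRecord("a", seg), SequenceRecord("b", seg)]
        pls = place_on_each_target(SequenceRecord("q", seg), TargetIndex(targets))
        assert [p.primary for p in pls] == [True, False]
        assert {p.target_id for p in pls} == {"a", "b"}


def _placement(qid, t_start, t_end, tid="utg1"):
    return Placement(
        query_id=qid, target_id=tid, strand="+", q_start=0,
        q_end=t_end - t_start, t_start=t_start, t_end=t_end,
        matches=t_end - t_start, aln_len=t_end - t_start,
        query_length=t_end - t_start, target_length=10_000_000,
    )


class TestContainment:
    def test_nested_interval_is_contained(self):
        # interval sizes from the fly-scaffold narrative: a 79 kb contig
        # placed in the middle of a 339 kb contig
        a = _placement("contig52", 0, 339_371)
        b = _placement("contig53", 150_000, 229_102)
        out = detect_containment([a, b])
        assert out[0].contained_in is None
        assert out[1].contained_in == "contig52"

    def test_disjoint_intervals_not_contained(self):
        out = detect_containment([_placement("a", 0, 100), _placement("b", 200, 300)])
        assert all(p.contained_in is None for p in out)

    def test_different_targets_never_contain(self):
        out = detect_containment(
            [_placement("a", 0, 1_000, "t1"), _placement("b", 10, 20, "t2")]
        )
        assert all(p.contained_in is None for p in out)

    def test_ties_resolve_to_largest_enclosure(self):
        out = detect_containment(
            [
                _placement("outer", 0, 1_000),
                _placement("mid", 100, 800),
                _placement("inner", 200, 300),
            ]
        )
        assert out[2].contained_in == "outer"

    def test_matches_quadratic_oracle(self, rng):
        placements = []
        for i in range(60):
            s = int(rng.integers(0, 5_000))
            e = s + int(rng.integers(1, 2_000))
            placements.append(_placement(f"q{i}", s, e, f"t{int(rng.integers(3))}"))
        got = detect_containment(placements)
        for i, p in enumerate(placements):
            enclosing = [
                q
                for j, q in enumerate(placements)
                if j != i
                and q.target_id == p.target_id
                and q.t_start <= p.t_start
                and p.t_end <= q.t_end
                and not (
                    (q.t_start, q.t_end) == (p.t_start, p.t_end) and j > i
                )
            ]
            if enclosing:
                want = sorted(
                    enclosing, key=lambda q: (-(q.t_end - q.t_start), q.query_id)
                )[0].query_id
                assert got[i].contained_in == want
            else:
                assert got[i].contained_in is None


def test_paf_output_has_twelve_mandatory_columns(genome, index):
    p = place_contig(SequenceRecord("q", genome[1_000:2_000]), index)
    fields = placements_to_paf([p]).strip().split("\t")
    assert len(fields) >= 12
    assert fields[4] == "+" and int(fields[9]) == 1_000 and int(fields[10]) == 1_000
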