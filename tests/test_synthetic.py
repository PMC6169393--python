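import numpy as np
import pytest

from contig_audit.gap_closure import evaluate_gap_closure
from contig_audit.polish import CorruptionSpec
from contig_audit.scaffolds import decompose_scaffold
from contig_audit.seq_io import SequenceRecord, reverse_complement
from contig_audit.synthetic import (
    GeometricLengths,
    UniformLengths,
    fragment_into_reference,
    make_assembly_surrogate,
    simulate_genome,
    simulate_reads,
)

_STOPS = {"TAA", "TAG", "TGA"}


class TestSimulateGenome:
    def test_gc_within_binomial_bounds(self):
        n = 100_000
        genome, _ = simulate_genome(n, gc=0.5, seed=1)
        gc = sum(genome.residues.count(b) for b in "GC")
        sigma = (n * 0.25) ** 0.5
        assert abs(gc - n * 0.5) < 3 * sigma

    def test_planted_genes_are_valid_single_copy_orfs(self):
        genome, truth = simulate_genome(80_000, n_genes=10, seed=2)
        assert len(truth.genes) == 10
        for g in truth.genes:
            assert genome.residues[g.start : g.end] == g.residues
            assert g.residues.startswith("ATG")
            assert g.residues[-3:] in _STOPS
            codons = [g.residues[i : i + 3] for i in range(3, len(g.residues) - 3, 3)]
            assert not any(c in _STOPS for c in codons)
            assert genome.residues.count(g.residues) == 1

    def test_genes_do_not_overlap(self):
        _, truth = simulate_genome(60_000, n_genes=20, seed=3)
        spans = sorted((g.start, g.end) for g in truth.genes)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_deterministic_given_seed(self):
        a, _ = simulate_genome(30_000, n_genes=5, repeat_fraction=0.1, seed=4)
        b, _ = simulate_genome(30_000, n_genes=5, repeat_fraction=0.1, seed=4)
        assert a.residues == b.residues

    def test_different_seeds_differ(self):
        a, _ = simulate_genome(30_000, seed=5)
        b, _ = simulate_genome(30_000, seed=6)
        assert a.residues != b.residues

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_genome(10_000, n_genes=11, gene_length=900, seed=1)

    def test_repeats_fill_requested_fraction(self):
        genome, _ = simulate_genome(100_000, repeat_fraction=0.2, seed=7)
        assert len(genome.residues) == 100_000


class TestFragmentIntoReference:
    def test_single_contig_reference_equals_genome(self):
        genome, _ = simulate_genome(20_000, seed=8)
        refs, truth = fragment_into_reference(
            genome, 1, contig_lengths=UniformLengths(20_000, 20_000), seed=8
        )
        assert refs[0].residues == genome.residues
        assert truth[0].gaps == ()

    def test_decomposition_recovers_truth_coordinates(self):
        genome, _ = simulate_genome(60_000, seed=9)
        refs, truth = fragment_into_reference(genome, 6, seed=9)
        for rec, sc in zip(refs, truth):
            d = decompose_scaffold(rec)
            off = sc.genome_start
            assert [(c.start + off, c.end + off) for c in d.contigs] == list(sc.contigs)
            assert [(g.start + off, g.end + off) for g in d.internal_gaps] == list(sc.gaps)
            # contig sequence comes from the genome; gap sequence is hidden
            for c in d.contigs:
                assert c.residues == genome.residues[c.start + off : c.end + off]

    def test_gap_total_is_contig_total_minus_scaffolds(self):
        genome, _ = simulate_genome(60_000, seed=10)
        _, truth = fragment_into_reference(genome, 6, seed=10)
        n_contigs = sum(len(sc.contigs) for sc in truth)
        n_gaps = sum(len(sc.gaps) for sc in truth)
        assert n_gaps == n_contigs - len(truth)

    def test_scaffold_lengths_tile_the_genome(self):
        genome, _ = simulate_genome(45_000, seed=11)
        refs, truth = fragment_into_reference(genome, 4, seed=11)
        assert sum(len(r.residues) for r in refs) == 45_000
        for rec, sc in zip(refs, truth):
            assert len(rec.residues) == sc.genome_end - sc.genome_start


class TestSimulateReads:
    def test_error_free_reads_are_genome_substrings(self):
        genome, _ = simulate_genome(30_000, seed=12)
        reads = simulate_reads(genome, depth=2, length_mean=1_500,
                               length_sd_log=0.4, seed=12)
        for r in reads[:20]:
            assert (
                r.residues in genome.residues
                or reverse_complement(r.residues) in genome.residues
            )

    def test_total_bases_hit_requested_depth(self):
        genome, _ = simulate_genome(100_000, seed=13)
        reads = simulate_reads(genome, depth=20, seed=13)
        total = sum(len(r) for r in reads)
        assert abs(total - 2_000_000) / 2_000_000 < 0.05

    def test_mean_length_near_default_target(self):
        genome, _ = simulate_genome(100_000, seed=14)
        reads = simulate_reads(genome, depth=20, seed=14)
        mean = np.mean([len(r) for r in reads])
        assert abs(mean - 5_894) / 5_894 < 0.10

    def test_qualities_reflect_error_rate(self):
        genome, _ = simulate_genome(30_000, seed=15)
        noisy = simulate_reads(genome, depth=1, error_spec=CorruptionSpec.from_total(0.1),
                               seed=15)
        clean = simulate_reads(genome, depth=1, seed=15)
        assert np.mean([r.mean_q for r in noisy]) < np.mean([r.mean_q for r in clean])
        assert all(r.mean_q >= 59.9 for r in clean)

    def test_deterministic_given_seed(self):
        genome, _ = simulate_genome(30_000, seed=16)
        a = simulate_reads(genome, depth=1, seed=17)
        b = simulate_reads(genome, depth=1, seed=17)
        assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]

    def test_depth_must_be_positive(self):
        genome, _ = simulate_genome(30_000, seed=18)
        with pytest.raises(ValueError):
            simulate_reads(genome, depth=0)


class TestAssemblySurrogate:
    def test_no_breakpoints_single_contig_all_closed(self):
        genome, _ = simulate_genome(40_000, seed=19)
        _, truth = fragment_into_reference(genome, 4, seed=19)
        records, expected = make_assembly_surrogate(genome, [], truth)
        assert len(records) == 1
        assert records[0].residues == genome.residues
        assert expected and all(expected.values())

    def test_breakpoint_inside_gap_opens_only_that_gap(self):
        genome, _ = simulate_genome(40_000, seed=20)
        _, truth = fragment_into_reference(genome, 4, seed=20)
        target_sc = next(sc for sc in truth if sc.gaps)
        gi = len(target_sc.gaps) // 2
        s, e = target_sc.gaps[gi]
        _, expected = make_assembly_surrogate(genome, [(s + e) // 2], truth)
        open_gaps = {k for k, v in expected.items() if not v}
        assert open_gaps == {(target_sc.scaffold_id, gi)}

    def test_expected_table_matches_evaluator_on_clean_surrogate(self):
        for seed in range(3):
            genome, _ = simulate_genome(50_000, seed=30 + seed)
            refs, truth = fragment_into_reference(
                genome, 5,
                contig_lengths=UniformLengths(900, 2_200),
                gap_lengths=GeometricLengths(150, minimum=30),
                seed=30 + seed,
            )
            rng = np.random.default_rng(seed)
            all_gaps = [(sc, gi) for sc in truth for gi in range(len(sc.gaps))]
            pick = rng.choice(len(all_gaps), size=min(2, len(all_gaps)), replace=False)
            bps = []
            for c in pick:
                sc, gi = all_gaps[c]
                s, e = sc.gaps[gi]
                bps.append((s + e) // 2)
            assembly, expected = make_assembly_surrogate(genome, bps, truth)
            report = evaluate_gap_closure(
                [decompose_scaffold(r) for r in refs], assembly, mode="loose"
            )
            got = {(r.scaffold_id, r.gap_index): r.closed for r in report.rows}
            assert got == expected

    def test_breakpoints_outside_genome_rejected(self):
        genome, _ = simulate_genome(20_000, seed=21)
        with pytest.raises(ValueError):
            make_assembly_surrogate(genome, [25_000])
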