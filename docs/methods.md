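# Methods

`contig-audit` evaluates a new contig-only genome assembly against a
published, scaffolded reference, and emulates — at desk scale — the
polishing arc that turns a raw long-read draft into a usable genome.
This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Reference decomposition

A scaffold is split at **every position holding the letter N**: maximal
N-free runs become reference contigs, maximal N-runs become gaps.  Only
`N` splits; other IUPAC ambiguity letters stay inside contigs, because
they assert partial base information rather than an unresolved join.
Leading/trailing N-runs are retained for lossless reconstruction but
excluded from gap accounting: a gap in the bookkeeping sense needs two
flanking contigs.  Consequently, for a scaffold of *k* ≥ 2 contigs
there are exactly *k* − 1 internal gaps, and over any scaffold set

    n_internal_gaps = n_contigs_in_multi − n_multi_contig_scaffolds,

an identity the inventory reports and the tests verify.  All
coordinates are 0-based half-open, so BED export is a direct dump.

## Placement model

Queries (reference contigs, transcripts, genes, reads) are located on
target contigs by the standard long-read recipe:

1. **Minimizer seeding.** Canonical k-mers (k = 15), smallest by a
   splitmix64-mixed hash in each w = 10 window; k-mers containing
   non-ACGT letters never seed.  The target index is built once per
   target set.
2. **Colinear chaining.** Dynamic programming over shared anchors,
   strictly increasing in query and strand-adjusted target coordinates;
   chain score is covered query bases minus 0.01·|Δq − Δt| per join,
   with joins limited to `max_gap` (default 10 kb).  Predecessor search
   is bounded to a 64-anchor lookback (exact on everything except
   adversarial anchor clouds); ties break deterministically by target
   id, strand, then target start.
3. **Base-level alignment.** The chain's terminal anchors are exact
   matches, so the spanned region is aligned globally (edlib, unit edit
   costs) between pinned coordinates.  Unanchored query flanks are
   aligned semi-globally against a proportional target window and
   accepted only at ≥ 70% identity — random DNA aligns near 50% under
   unit costs, true homologous flanks at long-read error rates above
   ~80%, so the floor clips extension into unrelated sequence while
   keeping genuinely homologous ragged ends.

**Identity** is BLAST-style: identical columns / alignment columns,
indels counted against.  On random pairs up to 5 kb with up to 12%
simulated error, pipeline identity agrees with a single full global
alignment to well under 0.5 percentage points (acceptance suite); an
independent exhaustive DP aligner (Biopython) cross-checks the identity
bookkeeping on small instances.

A placement's ranking score is identity × aligned query bases; the best
placement per target is kept, the global best flagged primary.
Containment (one placement's target interval nested inside another's)
is flagged per target with an interval tree, ties resolved toward the
largest enclosing interval.

## Gap closure

Reference scaffolds are processed **one at a time**; each contig ≥ 500
bp is placed on the assembly (shorter flanks are unreliable to place
and mark their gaps *indeterminate*, counted open).  A placement counts
only if identity ≥ 0.99 **and** it covers ≥ 90% of the query.  The
coverage requirement is a deliberate strengthening of an
identity-only rule: a contig cut in half by an assembly break still
places its halves at 100% identity, which is not evidence the whole
contig lies on that target.  With it, the evaluator agrees exactly
with the interval-logic truth table of the synthetic surrogate
(a gap is truly spanned iff one assembly contig contains both flanking
contig territories).

Two closure rules are reported:

* **loose** (default): a gap is closed when its two flanking contigs
  both place on one common assembly contig — the literal
  two-contigs-on-one-target bookkeeping used for published
  gap-closure tables;
* **strict**: additionally same strand, scaffold order along the
  target, and flank separation ≤ gap length + 1 kb tolerance.

Strict closures are a subset of loose closures on every input
(property-tested).  Percentages round half away from zero; all 14
published per-species rows reproduce under this convention.
`genome_fraction` is the union of aligned target intervals divided by
the genome size — overlaps are never double-counted.

## Contiguity and read statistics

N50 is computed by descending cumulative sum with an inclusive
threshold; NG50 substitutes a user-supplied expected genome size and
legitimately returns 0 ("n/a") for undersized assemblies.  Size-class
counts (>100 kb, >1 Mb; reads >1 kb, >10 kb) are strict inequalities.
Per-read quality is the Phred transform of the **mean per-base error
probability** (−10·log₁₀ of the mean of 10^(−q/10))) — the base-caller
convention — not the arithmetic mean of Phred scores, which would
overweight good bases.  The pass/fail threshold (default 7) is
inclusive, with a 1e-9 epsilon so a read whose bases all sit exactly at
the threshold passes despite float round-trip.

## Transcript scoring

A transcript is *properly represented* when ≥ 90% of its length aligns
to a **single** assembly contig at ≥ 95% matches-weighted identity
(both thresholds inclusive).  Chaining uses `max_gap` = 1 kb so
intron-sized target gaps split the transcript into exon-like placements
that are unioned on the query; placements on different contigs are
never pooled — stricter than cross-subject HSP pooling, and
deliberately so: scattering a gene across contigs should not count.

## Polishing simulation

The simulation reproduces, with exact ground truth, the familiar
finding that raw long-read drafts are gene-dead and consensus polishing
revives them:

* **Corruption** applies i.i.d. per-base substitutions, insertions and
  deletions (a total rate *r* splits r/2, r/4, r/4).  The 10–15% total
  draft rate models an unpolished long-read consensus.
* **Pileup polishing** maps reads back to the draft, walks each
  alignment into per-column votes (base, deletion, or inserted string
  at a junction), and replaces each column by its strict majority with
  ties keeping the draft — a deterministic simplification of
  partial-order-alignment consensus.  Zero mapped reads return the
  draft unchanged.
* **Gene recovery** scores planted single-copy ORFs: a gene is intact
  iff it aligns at ≥ 95% identity with every indel a multiple of three
  and no internal stop codon in the aligned frame.  Planted genes with
  known truth replace an ortholog database: no download, exact ground
  truth, same qualitative readout.

The standard scenario is a 200 kb genome, 50 genes of 900 bp, 12%
draft error, 30× reads, 3 iterations.  At seed 1 it prints gene
recovery 0.00 → 0.58 → 0.76 → 0.76 with 8%-error reads and reaches
1.00 with 1%-error reads, echoing the unpolished-near-zero /
polished-near-reference pattern of real BUSCO trajectories.  Residual
errors concentrate at the genome's extreme ends, where uniform read
starts leave no coverage — the analogue of coverage decay at real
contig ends.

## Synthetic data: what it does and does not emulate

The generator produces i.i.d. background at a chosen GC (default
0.45), optionally salted with 3 repeat motifs of 2–5 kb copied at ~2%
divergence, plus non-overlapping forward-strand ORFs.  References are
built by hiding genome stretches behind N-runs of equal length
(contig lengths default Uniform(800, 3000), gap lengths geometric with
mean 500); assembly surrogates cut the genome at chosen breakpoints.
Read lengths are log-normal with arithmetic mean 5,894 bp and
log-sigma 0.9 (~15% of reads exceed 10 kb — no log-normal at that mean
can reach 20%), truncated to [100 bp, genome length]; per-base
qualities encode each read's realized error rate.

Not emulated: homopolymer-biased errors (real nanopore indels cluster
in homopolymers; polishing real data is accordingly harder),
heterozygosity (no diploid sampling), chimeric reads, transposon
biology of real repeats, GC skew, and base-level scaffold-gap-length
misestimates.  Passing tests therefore demonstrate the *accounting and
algorithms* are correct under realistic geometry, not that real-genome
closure rates would reproduce.

## Numerical choices

* Rounding: half away from zero everywhere tables are printed
  (banker's rounding would disagree on exact halves).
* Percent columns in Average rows are means of per-species
  percentages; the pooled Σclosed/Σgaps is also reported and labeled
  (61% vs 67% on the bundled closure table).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical inputs give identical outputs
  everywhere, including placement tie-breaks.
* Degenerate inputs: empty/all-N scaffolds decompose to zero contigs;
  empty anchor sets chain to empty; no-placement is a result, not an
  error; zero-gap references make percent-closed undefined (error).

## Problem sizes

Tests and the acceptance suite run on 20–200 kb genomes, 30× read
sets, and 100-seed closure sweeps — sizes chosen so the full suite
completes in minutes on one CPU while every code path (multi-scaffold
references, ~140-gap closure tables, 1,000-read pileups) is exercised
at realistic shape.

## Known limitations

* The chaining lookback bound (64) can in principle miss the optimal
  chain in adversarial repeat clouds; the exhaustive-enumeration oracle
  covers the exact regime (≤ 12 anchors) and the repeat stress in the
  generator stays well inside the bound.
* Split/chimeric placements across multiple targets are out of scope;
  a query placed half on each of two contigs is simply "not placed".
* Insertion consensus votes on whole inserted strings per junction;
  alignment ambiguity can split votes between adjacent junctions,
  which slows (but in practice does not prevent) convergence.
* The loose closure rule can over-count on repeat-heavy references
  (any co-placement of the two flanks counts); strict mode exists
  precisely to bound that effect, and both are reported.
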