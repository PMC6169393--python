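"""Synthetic genomes, gapped references, read sets and assembly surrogates.

Every generator returns full ground truth alongside the sequence, so
each analysis stage (decomposition, placement, gap closure, polishing,
gene recovery) can be tested against certainty instead of against an
external dataset.  What is emulated:

* a genome of i.i.d. background at a chosen GC, optionally salted with
  a small divergent repeat library (to stress the mapper) and planted
  single-copy ORFs (start codon, stop-free body, stop codon);
* a *reference assembly* built by partitioning the genome into scaffold
  territories and hiding stretches of sequence behind N-runs — the
  classic scaffolds-with-gaps structure, with the hidden sequence and
  all coordinates recorded;
* long reads with log-normal lengths and i.i.d. errors, the length
  scale anchored to a ~5.9 kb mean typical of early nanopore runs;
* an *assembly surrogate*: the true genome cut at chosen breakpoints,
  giving a contig set whose expected gap-closure table follows from
  pure interval logic.

All generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .polish import CorruptionSpec, corrupt_sequence
from .seq_io import ReadRecord, SequenceRecord, reverse_complement

__all__ = [
    "PlantedGene",
    "ScaffoldTruth",
    "SyntheticTruth",
    "GeometricLengths",
    "UniformLengths",
    "LogNormalLengths",
    "simulate_genome",
    "fragment_into_reference",
    "simulate_reads",
    "make_assembly_surrogate",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class PlantedGene:
    id: str
    start: int          # genome coordinates, half-open
    end: int
    strand: str
    residues: str


@dataclass(frozen=True)
class ScaffoldTruth:
    """Genome-coordinate map of one reference scaffold."""

    scaffold_id: str
    genome_start: int
    genome_end: int
    contigs: tuple[tuple[int, int], ...]   # genome coords of each contig
    gaps: tuple[tuple[int, int], ...]      # genome coords hidden behind N


@dataclass(frozen=True)
class SyntheticTruth:
    genome: SequenceRecord
    genes: tuple[PlantedGene, ...] = ()
    scaffolds: tuple[ScaffoldTruth, ...] = ()
    breakpoints: tuple[int, ...] = ()


# --- length distributions -------------------------------------------------

@dataclass(frozen=True)
class GeometricLengths:
    """Geometric lengths with the given mean, shifted to ``minimum``."""

    mean: float
    minimum: int = 1

    def __call__(self, rng: np.random.Generator) -> int:
        p = 1.0 / max(self.mean - self.minimum + 1, 1.0)
        return self.minimum + int(rng.geometric(p)) - 1


@dataclass(frozen=True)
class UniformLengths:
    lo: int
    hi: int

    def __call__(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.lo, self.hi + 1))


@dataclass(frozen=True)
class LogNormalLengths:
    """Log-normal lengths parameterized by the arithmetic mean."""

    mean: float
    sigma: float
    minimum: int = 1

    def __call__(self, rng: np.random.Generator) -> int:
        mu = math.log(self.mean) - self.sigma**2 / 2
        return max(self.minimum, int(rng.lognormal(mu, self.sigma)))


LengthSampler = Callable[[np.random.Generator], int]


# --- genome ---------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=n, p=probs)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """Start codon, stop-free codon body, stop codon; length must be %3 == 0."""
    if length % 3 != 0 or length < 9:
        raise ValueError("gene length must be a multiple of 3 and >= 9")
    n_body = length // 3 - 2
    body = "".join(rng.choice(_CODONS) for _ in range(n_body))
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    return "ATG" + body + stop


def simulate_genome(
    size: int,
    gc: float = 0.45,
    repeat_fraction: float = 0.0,
    n_genes: int = 0,
    gene_length: int = 900,
    seed: int = 0,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Generate a genome with registered repeats and planted ORFs.

    Repeats are 3 motifs of 2–5 kb copied at ~2% divergence until the
    requested fraction is reached; genes are planted last (single copy,
    forward strand, non-overlapping) so the registry always matches the
    emitted sequence exactly.
    """
    if size < 10_000:
        raise ValueError("genome size must be at least 10 kb")
    if not (0 <= gc < 1 and 0 <= repeat_fraction < 1):
        raise ValueError("fractions must lie in [0, 1)")
    if n_genes * gene_length + repeat_fraction * size > 0.9 * size:
        raise ValueError("requested genes and repeats do not fit in the genome")
    rng = np.random.default_rng(seed)
    seq = list(_random_bases(rng, size, gc))

    if repeat_fraction > 0:
        motifs = [
            _random_bases(rng, int(rng.integers(2_000, 5_001)), gc) for _ in range(3)
        ]
        placed = 0
        while placed < repeat_fraction * size:
            motif = motifs[int(rng.integers(3))]
            copy, _ = corrupt_sequence(
                SequenceRecord("m", motif),
                CorruptionSpec(0.01, 0.005, 0.005, seed=int(rng.integers(2**31))),
            )
            start = int(rng.integers(0, size - len(copy)))
            seq[start : start + len(copy)] = list(copy.residues)
            placed += len(copy)

    genes: list[PlantedGene] = []
    occupied: list[tuple[int, int]] = []
    for gi in range(n_genes):
        for _attempt in range(10_000):
            start = int(rng.integers(0, size - gene_length))
            end = start + gene_length
            if all(end <= s or start >= e for s, e in occupied):
                break
        else:
            raise ValueError("could not pack genes into the genome")
        orf = _random_orf(rng, gene_length)
        seq[start:end] = list(orf)
        occupied.append((start, end))
        genes.append(PlantedGene(f"gene_{gi:03d}", start, end, "+", orf))

    genome = SequenceRecord("genome", "".join(seq))
    return genome, SyntheticTruth(genome=genome, genes=tuple(sorted(genes, key=lambda g: g.start)))


# --- reference fragmentation ----------------------------------------------

def fragment_into_reference(
    genome: SequenceRecord,
    n_scaffolds: int,
    contig_lengths: LengthSampler = UniformLengths(800, 3_000),
    gap_lengths: LengthSampler = GeometricLengths(500, minimum=1),
    seed: int = 0,
) -> tuple[list[SequenceRecord], tuple[ScaffoldTruth, ...]]:
    """Hide stretches of a genome behind N-runs to emulate a gapped reference.

    The genome is split into ``n_scaffolds`` contiguous territories;
    inside each, contig and gap segments alternate with lengths drawn
    from the samplers.  The N-run replaces the true sequence at equal
    length, so scaffold and territory lengths coincide and every truth
    coordinate resolves on the genome.  Scaffolds always start and end
    with a contig.
    """
    rng = np.random.default_rng(seed)
    size = len(genome.residues)
    if n_scaffolds < 1 or n_scaffolds > size // 1_000:
        raise ValueError("unreasonable scaffold count for this genome size")
    bounds = [round(i * size / n_scaffolds) for i in range(n_scaffolds + 1)]
    records: list[SequenceRecord] = []
    truths: list[ScaffoldTruth] = []
    min_tail = 800  # a trailing contig shorter than this is merged leftward
    for si in range(n_scaffolds):
        a, b = bounds[si], bounds[si + 1]
        contigs: list[tuple[int, int]] = []
        gaps: list[tuple[int, int]] = []
        pos = a
        while pos < b:
            c = min(max(contig_lengths(rng), 1), b - pos)
            contigs.append((pos, pos + c))
            pos += c
            if pos >= b:
                break
            g = max(gap_lengths(rng), 1)
            if pos + g + min_tail > b:
                # no room for a gap plus trailing contig: extend last contig to the end
                contigs[-1] = (contigs[-1][0], b)
                pos = b
                break
            gaps.append((pos, pos + g))
            pos += g
        sid = f"scaffold_{si:04d}"
        pieces = []
        for (s, e) in sorted(contigs + gaps):
            if (s, e) in gaps:
                pieces.append("N" * (e - s))
            else:
                pieces.append(genome.residues[s:e])
        records.append(SequenceRecord(sid, "".join(pieces)))
        truths.append(ScaffoldTruth(sid, a, b, tuple(contigs), tuple(gaps)))
    return records, tuple(truths)


# --- reads ----------------------------------------------------------------

def simulate_reads(
    genome: SequenceRecord,
    depth: float,
    length_mean: float = 5_894.0,
    length_sd_log: float = 0.9,
    error_spec: Optional[CorruptionSpec] = None,
    seed: int = 0,
    min_length: int = 100,
) -> list[ReadRecord]:
    """Simulate long reads to a target depth of coverage.

    Lengths are log-normal with the given arithmetic mean, truncated to
    ``[min_length, genome length]``; starts are uniform; strands are
    random; errors follow ``error_spec`` (per-read seeds derived from
    ``seed``).  Per-base qualities encode the realized per-read error
    rate, so downstream quality filters see scores consistent with the
    simulated accuracy.  Total bases land within one read length of
    ``depth × genome size``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    glen = len(genome.residues)
    target = depth * glen
    mu = math.log(length_mean) - length_sd_log**2 / 2
    reads: list[ReadRecord] = []
    total = 0
    i = 0
    while total < target:
        length = int(np.clip(rng.lognormal(mu, length_sd_log), min_length, glen))
        start = int(rng.integers(0, glen - length + 1))
        fragment = genome.residues[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        n_errors = 0
        if error_spec is not None and error_spec.total > 0:
            corrupted, log = corrupt_sequence(
                SequenceRecord("f", fragment),
                replace(error_spec, seed=int(rng.integers(2**31))),
            )
            fragment = corrupted.residues
            n_errors = len(log)
        rate = n_errors / max(len(fragment), 1)
        q = 60 if rate <= 0 else int(np.clip(round(-10 * math.log10(rate)), 2, 60))
        reads.append(
            ReadRecord(
                f"read_{i:06d}",
                fragment,
                (q,) * len(fragment),
                description=f"start={start} end={start + length} strand={strand}",
            )
        )
        total += len(fragment)
        i += 1
    return reads


# --- assembly surrogate ---------------------------------------------------

def make_assembly_surrogate(
    genome: SequenceRecord,
    breakpoints: Sequence[int] = (),
    reference_truth: Sequence[ScaffoldTruth] = (),
    error_spec: Optional[CorruptionSpec] = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[tuple[str, int], bool]]:
    """Cut the true genome at breakpoints to fabricate an assembly.

    Returns the contig records and, when ``reference_truth`` is given,
    the expected closure table: reference gap ``(scaffold, index)`` is
    expected closed iff one assembly contig fully contains both
    flanking reference-contig territories.
    """
    glen = len(genome.residues)
    bps = sorted(set(int(b) for b in breakpoints))
    if bps and (bps[0] <= 0 or bps[-1] >= glen):
        raise ValueError("breakpoints must lie strictly inside the genome")
    bounds = [0] + bps + [glen]
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    segments: list[tuple[int, int]] = []
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1]
        seq = genome.residues[s:e]
        if error_spec is not None and error_spec.total > 0:
            corrupted, _ = corrupt_sequence(
                SequenceRecord("s", seq),
                replace(error_spec, seed=int(rng.integers(2**31))),
            )
            seq = corrupted.residues
        records.append(SequenceRecord(f"asm_{i:04d}", seq))
        segments.append((s, e))

    expected: dict[tuple[str, int], bool] = {}
    for sc in reference_truth:
        for gi in range(len(sc.gaps)):
            left = sc.contigs[gi]
            right = sc.contigs[gi + 1]
            expected[(sc.scaffold_id, gi)] = any(
                s <= left[0] and right[1] <= e for s, e in segments
            )
    return records, expected
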