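"""Synthetic study system: annotated genome, diverged diploid individuals,
and simulated capture reads with a known truth set.

The generator emulates the data a targeted exon-capture experiment
produces, at desk scale: a multi-chromosome reference with gene/exon
annotation, individuals diverged from the reference at configurable
homozygous-substitution and heterozygosity rates, and short single-end
reads (36 bp by default) drawn from the capture targets with per-quality
base-call errors, an off-target read fraction, and PCR duplicates.
Alignment is bypassed: each simulated read records its true origin, so
every downstream stage can be tested against exact truth.

All generators are fully deterministic for a fixed seed. Each stage draws
from its own child of the spec's seed (numpy SeedSequence spawning), so
adding a later stage never perturbs earlier draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dna import BASES, iupac_code, revcomp
from .read_processing import MappedRead
from .target_design import ExonTarget, GeneModel
from .util import apportion_largest_remainder

__all__ = [
    "GenomeSpec",
    "IndividualSpec",
    "ReadSimSpec",
    "ReferenceGenome",
    "Individual",
    "SizingError",
    "generate_reference",
    "derive_individual",
    "simulate_reads",
    "write_fastq",
    "write_truth_tsv",
    "read_truth_tsv",
]

_MIN_INTERGENIC = 50
_INTRON_RANGE = (100, 800)


class SizingError(ValueError):
    """A chromosome is too short to host the requested gene content."""


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the synthetic annotated reference genome."""

    chromosome_lengths: tuple[int, ...]
    n_genes: int = 30
    exons_per_gene_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (60, 400)
    gc_content: float = 0.42
    n_candidate_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths or any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("all chromosome lengths must be positive")
        for lo, hi in (self.exons_per_gene_range, self.exon_length_range):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0,1]")
        if self.n_genes < 0 or self.n_candidate_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_candidate_genes > self.n_genes:
            raise ValueError("n_candidate_genes cannot exceed n_genes")


@dataclass(frozen=True)
class IndividualSpec:
    """Divergence of one diploid individual from the reference.

    ``divergence_rate`` is the expected homozygous (fixed) substitutions per
    site; ``heterozygosity_rate`` the expected heterozygous sites per site.
    A site is never both.
    """

    divergence_rate: float
    heterozygosity_rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.divergence_rate, self.heterozygosity_rate):
            if not 0.0 <= r <= 0.05:
                raise ValueError("rates must lie in [0, 0.05]")
        if self.divergence_rate + self.heterozygosity_rate > 0.1:
            raise ValueError("divergence + heterozygosity rates exceed 0.1")


@dataclass(frozen=True)
class ReadSimSpec:
    """Parameters of the simulated post-enrichment read library."""

    read_length: int = 36
    mean_on_target_depth: float = 20.0
    off_target_fraction: float = 0.75
    per_quality_error: Mapping[int, float] = field(
        default_factory=lambda: {30: 0.001, 33: 0.0006, 35: 0.0003}
    )
    quality_weights: Mapping[int, float] | None = None
    duplicate_fraction: float = 0.1
    non_unique_fraction: float = 0.05  # reads emitted with MAPQ 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not self.per_quality_error:
            raise ValueError("per_quality_error must be non-empty")
        for q, e in self.per_quality_error.items():
            if not 0.0 < e < 0.5:
                raise ValueError(f"error rate for Q{q} must lie in (0, 0.5)")
        for name in ("off_target_fraction", "duplicate_fraction", "non_unique_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.mean_on_target_depth < 0:
            raise ValueError("mean_on_target_depth must be >= 0")
        if self.quality_weights is not None and set(self.quality_weights) != set(
            self.per_quality_error
        ):
            raise ValueError("quality_weights keys must match per_quality_error keys")


@dataclass
class ReferenceGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    candidate_ids: list[str]

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class Individual:
    """Two haplotype sequences per chromosome plus the edit truth set.

    ``truth`` has one row per edited site: chrom, pos (1-based), ref,
    genotype (IUPAC), cls ('fixed' | 'heterozygous').
    """

    haplotypes: dict[str, tuple[str, str]]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# reference generation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return codes.tobytes().decode("ascii")


def _gene_structure(
    rng: np.random.Generator, spec: GenomeSpec
) -> tuple[list[tuple[int, int]], int]:
    """Exon intervals relative to gene start, and total gene span."""
    n_ex = int(rng.integers(spec.exons_per_gene_range[0], spec.exons_per_gene_range[1] + 1))
    ex_lens = rng.integers(
        spec.exon_length_range[0], spec.exon_length_range[1] + 1, size=n_ex
    )
    introns = rng.integers(_INTRON_RANGE[0], _INTRON_RANGE[1] + 1, size=max(0, n_ex - 1))
    exons = []
    cursor = 0
    for i, l in enumerate(ex_lens):
        exons.append((cursor, cursor + int(l)))
        cursor += int(l)
        if i < n_ex - 1:
            cursor += int(introns[i])
    return exons, cursor


def generate_reference(spec: GenomeSpec) -> ReferenceGenome:
    """Build the annotated synthetic reference genome.

    Genes are apportioned to chromosomes proportionally to length (largest
    remainder), placed without overlap with random intergenic gaps; every
    gene's first exon in transcription order carries the 5' UTR flag.
    """
    ss = np.random.SeedSequence(spec.seed)
    seq_rng, struct_rng, place_rng, strand_rng, cand_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    chroms = [f"chr{i + 1}" for i in range(len(spec.chromosome_lengths))]
    sequences = {
        c: _random_sequence(seq_rng, l, spec.gc_content)
        for c, l in zip(chroms, spec.chromosome_lengths)
    }
    per_chrom = apportion_largest_remainder(spec.chromosome_lengths, spec.n_genes)

    genes: list[GeneModel] = []
    counter = 0
    for c, chrom_len, g in zip(chroms, spec.chromosome_lengths, per_chrom):
        if g == 0:
            continue
        structures = [_gene_structure(struct_rng, spec) for _ in range(g)]
        span_total = sum(span for _, span in structures)
        min_required = span_total + (g + 1) * _MIN_INTERGENIC
        if min_required > chrom_len:
            raise SizingError(
                f"{c}: {g} genes need >= {min_required} bp but chromosome "
                f"has {chrom_len} bp"
            )
        slack = chrom_len - min_required
        extra = place_rng.multinomial(slack, np.full(g + 1, 1.0 / (g + 1)))
        cursor = 0
        for i, (exons_rel, span) in enumerate(structures):
            cursor += _MIN_INTERGENIC + int(extra[i])
            exons = tuple((cursor + s, cursor + e) for s, e in exons_rel)
            strand = "+" if strand_rng.random() < 0.5 else "-"
            utr_idx = 0 if strand == "+" else len(exons) - 1
            counter += 1
            genes.append(GeneModel(f"g{counter:04d}", c, strand, exons, utr_idx))
            cursor += span

    all_ids = [g.gene_id for g in genes]
    cand = (
        sorted(cand_rng.choice(all_ids, size=spec.n_candidate_genes, replace=False))
        if spec.n_candidate_genes
        else []
    )
    return ReferenceGenome(sequences, genes, list(cand))


# ---------------------------------------------------------------------------
# diverged diploid individual


def derive_individual(reference: ReferenceGenome, spec: IndividualSpec) -> Individual:
    """Introduce fixed and heterozygous substitutions at disjoint sites.

    Fixed edits alter both haplotypes identically; each heterozygous edit
    puts the alternate allele on exactly one haplotype. The returned truth
    table records every edit.
    """
    ss = np.random.SeedSequence(spec.seed)
    rngs = {c: np.random.default_rng(s)
            for c, s in zip(reference.sequences, ss.spawn(len(reference.sequences)))}
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    code_index = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code_index[b] = i

    haplotypes: dict[str, tuple[str, str]] = {}
    rows: list[tuple] = []
    for chrom, seq in reference.sequences.items():
        rng = rngs[chrom]
        L = len(seq)
        n_fixed = rng.binomial(L, spec.divergence_rate)
        n_het = rng.binomial(L, spec.heterozygosity_rate)
        hap0 = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        hap1 = hap0.copy()
        if n_fixed + n_het == 0:
            haplotypes[chrom] = (seq, seq)
            continue
        # one draw of distinct positions keeps fixed/het sites disjoint
        positions = rng.choice(L, size=n_fixed + n_het, replace=False)
        offsets = rng.integers(1, 4, size=n_fixed + n_het)
        het_hap = rng.integers(0, 2, size=n_het)
        for k, (pos, off) in enumerate(zip(positions, offsets)):
            ref_b = seq[pos]
            alt_b = BASES[(code_index[ord(ref_b)] + off) % 4]
            if k < n_fixed:
                hap0[pos] = hap1[pos] = ord(alt_b)
                rows.append((chrom, int(pos) + 1, ref_b, alt_b, "fixed"))
            else:
                target = hap0 if het_hap[k - n_fixed] == 0 else hap1
                target[pos] = ord(alt_b)
                rows.append(
                    (chrom, int(pos) + 1, ref_b, iupac_code(ref_b, alt_b), "heterozygous")
                )
        haplotypes[chrom] = (
            hap0.tobytes().decode("ascii"),
            hap1.tobytes().decode("ascii"),
        )
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "genotype", "cls"])
    truth = truth.sort_values(["chrom", "pos"], ignore_index=True)
    return Individual(haplotypes, truth)


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    individual: Individual,
    targets: Sequence[ExonTarget],
    spec: ReadSimSpec,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> list[MappedRead]:
    """Simulate the filtered-capture read library with known truth placement.

    Reads are drawn from both haplotypes with equal probability; on-target
    read starts are uniform over each target's footprint extended by one
    read length, giving (in expectation) uniform ``mean_on_target_depth``
    coverage across the target. A further ``off_target_fraction`` of reads
    falls outside all targets, ``duplicate_fraction`` of the final library
    are PCR copies (identical position, strand and MAPQ; independent
    base-call errors), and ``non_unique_fraction`` of templates are flagged
    MAPQ 0 to exercise the uniqueness filter (others get MAPQ 60).
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    if chromosome_lengths is None:
        chromosome_lengths = {
            c: len(h[0]) for c, h in individual.haplotypes.items()
        }
    L = spec.read_length
    if spec.mean_on_target_depth == 0:
        warnings.warn("mean_on_target_depth is 0: no reads simulated")
        return []

    ss = np.random.SeedSequence(spec.seed)
    place_rng, off_rng, dup_rng, mapq_rng, qual_rng, err_rng = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    hap_bytes = {
        c: (h[0].encode("ascii"), h[1].encode("ascii"))
        for c, h in individual.haplotypes.items()
    }

    # template records: (chrom, start, strand, hap, mapq)
    records: list[tuple[str, int, str, int, int]] = []
    for t in sorted(targets, key=lambda t: (t.chromosome, t.start, t.end)):
        chrom_len = chromosome_lengths[t.chromosome]
        n_t = int(round(spec.mean_on_target_depth * (t.length + L - 1) / L))
        if n_t == 0:
            continue
        starts = place_rng.integers(t.start - (L - 1), t.end, size=n_t)
        starts = np.clip(starts, 0, max(0, chrom_len - L))
        haps = place_rng.integers(0, 2, size=n_t)
        strands = place_rng.integers(0, 2, size=n_t)
        for s, h, st in zip(starts, haps, strands):
            records.append((t.chromosome, int(s), "+-"[st], int(h), 60))

    n_on = len(records)
    f = spec.off_target_fraction
    n_off = int(round(n_on * f / (1.0 - f))) if f > 0 else 0
    if n_off:
        from intervaltree import IntervalTree

        trees: dict[str, IntervalTree] = {}
        for t in targets:
            trees.setdefault(t.chromosome, IntervalTree()).addi(t.start, t.end)
        chroms = list(chromosome_lengths)
        weights = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        made = 0
        attempts = 0
        while made < n_off and attempts < 50 * n_off:
            attempts += 1
            c = chroms[int(off_rng.choice(len(chroms), p=weights))]
            s = int(off_rng.integers(0, max(1, chromosome_lengths[c] - L)))
            tree = trees.get(c)
            if tree is not None and tree.overlap(s, s + L):
                continue
            records.append((c, s, "+-"[int(off_rng.integers(0, 2))],
                            int(off_rng.integers(0, 2)), 60))
            made += 1
        if made < n_off:
            warnings.warn("could not place all off-target reads (targets too dense)")

    # MAPQ-0 templates
    if spec.non_unique_fraction > 0:
        flags = mapq_rng.random(len(records)) < spec.non_unique_fraction
        records = [
            (c, s, st, h, 0 if fl else mq)
            for (c, s, st, h, mq), fl in zip(records, flags)
        ]

    # PCR duplicates: copies of existing templates (same position/strand/MAPQ)
    d = spec.duplicate_fraction
    n_dup = int(round(len(records) * d / (1.0 - d))) if d > 0 else 0
    if n_dup:
        src = dup_rng.integers(0, len(records), size=n_dup)
        records.extend(records[int(i)] for i in src)

    # vectorized quality and error draws over the whole library
    n = len(records)
    qs = np.array(sorted(spec.per_quality_error), dtype=np.uint8)
    if spec.quality_weights is None:
        w = np.full(len(qs), 1.0 / len(qs))
    else:
        w = np.array([spec.quality_weights[int(q)] for q in qs], dtype=float)
        w /= w.sum()
    quals = qual_rng.choice(qs, size=(n, L), p=w)
    err_lookup = np.zeros(64)
    for q, e in spec.per_quality_error.items():
        err_lookup[q] = e
    is_err = err_rng.random((n, L)) < err_lookup[quals]
    err_off = err_rng.integers(1, 4, size=(n, L), dtype=np.uint8)

    code_index = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_index[b] = i
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)

    reads: list[MappedRead] = []
    for i, (chrom, start, strand, hap, mapq) in enumerate(records):
        seq = np.frombuffer(hap_bytes[chrom][hap][start : start + L], dtype=np.uint8).copy()
        mask = is_err[i]
        if mask.any():
            seq[mask] = base_codes[(code_index[seq[mask]] + err_off[i][mask]) % 4]
        reads.append(
            MappedRead(
                read_id=f"r{i:08d}",
                chromosome=chrom,
                position=start,
                strand=strand,
                cigar=f"{L}M",
                bases=seq.tobytes().decode("ascii"),
                qualities=quals[i].astype(np.int64),
                mapping_quality=mapq,
            )
        )
    reads.sort(key=lambda r: (r.chromosome, r.position, r.read_id))
    return reads


# ---------------------------------------------------------------------------
# text outputs


def write_fastq(reads: Sequence[MappedRead], path) -> None:
    """Phred+33 FASTQ; reverse-strand reads are written read-oriented."""
    with open(path, "w") as fh:
        for r in reads:
            seq, qual = r.bases, r.qualities
            if r.strand == "-":
                seq, qual = revcomp(seq), qual[::-1]
            qstr = "".join(chr(int(q) + 33) for q in qual)
            fh.write(f"@{r.read_id}\n{seq}\n+\n{qstr}\n")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
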