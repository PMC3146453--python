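"""Selection of exon capture targets from an annotated reference genome.

The design strategy samples a small, genome-wide subset of the exome, to
keep the total captured sequence affordable while spreading markers across
every chromosome:

* A fixed list of *candidate* genes contributes all of its exons, uncapped.
* Genome-wide genes are then sampled by visiting chromosomes proportionally
  to their length (largest-remainder apportionment of visits) and, on each
  visit, taking the gene whose midpoint lies closest to the midpoint of the
  largest contiguous span of the chromosome not yet covered by a selected
  gene. This spreads picks evenly along each chromosome.
* Per non-candidate gene, the exon containing the 5' UTR is always taken
  (regulatory interest), then further exons are drawn uniformly at random
  until the per-gene total first exceeds ``per_gene_bp_cap`` (the crossing
  exon is kept). Exons shorter than ``min_exon_bp`` are never drawn. Genes
  whose every exon exceeds the cap contribute the two ends of the
  5'-terminal exon instead.
* A redundancy screen rejects any exon sharing a 40 bp ungapped window at
  more than 90% identity (>= 37/40 matches at defaults) with an exon
  already collected, on either strand, so near-duplicate sequence is
  captured only once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dna import revcomp
from .util import apportion_largest_remainder

__all__ = [
    "GeneModel",
    "DesignConfig",
    "ExonTarget",
    "AnnotationError",
    "BudgetError",
    "select_genes_genomewide",
    "select_exons_for_gene",
    "redundancy_filter",
    "design_targets",
    "write_bed6",
    "read_bed6",
]


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation."""


class BudgetError(ValueError):
    """The base-pair budget cannot accommodate the mandatory targets."""


@dataclass(frozen=True)
class GeneModel:
    """One gene with its exon structure (coordinates 0-based, half-open).

    ``exons`` are stored sorted by genomic coordinate; ``utr5_exon`` indexes
    the exon carrying the 5' UTR in that list (for a '-' strand gene this is
    normally the highest-coordinate exon).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    utr5_exon: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene without exons")
        prev_end = -1
        for s, e in self.exons:
            if s < 0 or e <= s:
                raise AnnotationError(f"{self.gene_id}: bad exon interval ({s},{e})")
            if s < prev_end:
                raise AnnotationError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e
        if not 0 <= self.utr5_exon < len(self.exons):
            raise AnnotationError(f"{self.gene_id}: 5' UTR exon index out of range")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def tx_order(self) -> list[int]:
        """Exon indices in transcription (5'->3') order."""
        idx = list(range(len(self.exons)))
        return idx if self.strand == "+" else idx[::-1]


@dataclass(frozen=True)
class DesignConfig:
    per_gene_bp_cap: int = 1500
    min_exon_bp: int = 40
    long_first_exon_end_bp: int = 750
    redundancy_window_bp: int = 40
    redundancy_identity: float = 0.90  # strict: reject only if identity > this
    n_genomewide_genes: int = 2367
    total_bp_budget: int = 3_000_000
    candidate_gene_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.per_gene_bp_cap < self.min_exon_bp:
            raise ValueError("per_gene_bp_cap must be >= min_exon_bp")
        if not 0.0 < self.redundancy_identity < 1.0:
            raise ValueError("redundancy_identity must be in (0,1)")
        for name in ("min_exon_bp", "long_first_exon_end_bp",
                     "redundancy_window_bp", "total_bp_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genomewide_genes < 0:
            raise ValueError("n_genomewide_genes must be >= 0")


@dataclass(frozen=True)
class ExonTarget:
    """A genomic interval selected for capture."""

    chromosome: str
    start: int  # 0-based
    end: int  # half-open
    gene_id: str
    exon_ordinal: int  # position of the source exon in transcription order
    role: str  # utr5 | sampled | candidate_gene | long_first_exon_end
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.gene_id}|{self.exon_ordinal}|{self.role}"


# ---------------------------------------------------------------------------
# genome-wide gene sampling


def _largest_unsampled_span(
    footprints: list[tuple[int, int]], chrom_len: int
) -> tuple[int, int]:
    """Largest contiguous interval containing no selected-gene footprint.

    Ties are broken toward the lower-coordinate span.
    """
    best = (0, chrom_len)
    if not footprints:
        return best
    merged: list[tuple[int, int]] = []
    for s, e in sorted(footprints):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    spans: list[tuple[int, int]] = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            spans.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < chrom_len:
        spans.append((cursor, chrom_len))
    if not spans:  # whole chromosome covered; degenerate but defined
        return (0, 0)
    best_len = -1
    best_span = spans[0]
    for s, e in spans:
        if e - s > best_len:
            best_len, best_span = e - s, (s, e)
    return best_span


def select_genes_genomewide(
    genes: Iterable[GeneModel],
    chromosome_lengths: Mapping[str, int],
    n_genes: int,
    already_selected: frozenset[str] | set[str] = frozenset(),
) -> list[GeneModel]:
    """Pick ``n_genes`` genes spread along and across chromosomes.

    Chromosomes are visited round-robin with per-chromosome visit counts
    apportioned to their lengths (largest remainder). On each visit the gene
    whose midpoint is nearest the midpoint of the currently largest
    unsampled span is taken; ties go to the lower genomic coordinate.
    Footprints of ``already_selected`` genes count as sampled spans.
    """
    genes = list(genes)
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in chromosome_lengths}
    footprints: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosome_lengths}
    for g in genes:
        if g.chromosome not in chromosome_lengths:
            raise AnnotationError(
                f"gene {g.gene_id} on chromosome {g.chromosome} with unknown length"
            )
        if g.gene_id in already_selected:
            footprints[g.chromosome].append((g.start, g.end))
        else:
            by_chrom[g.chromosome].append(g)
    n_available = sum(len(v) for v in by_chrom.values())
    if n_genes > n_available:
        raise ValueError(f"requested {n_genes} genes but only {n_available} available")
    for c in by_chrom:
        by_chrom[c].sort(key=lambda g: (g.midpoint, g.start, g.gene_id))

    chroms = list(chromosome_lengths)
    lengths = [chromosome_lengths[c] for c in chroms]
    visits = dict(zip(chroms, apportion_largest_remainder(lengths, n_genes)))

    picked: list[GeneModel] = []
    while len(picked) < n_genes:
        progress = False
        for c in chroms:
            if len(picked) == n_genes:
                break
            if visits.get(c, 0) <= 0:
                continue
            pool = by_chrom[c]
            if not pool:
                continue
            span = _largest_unsampled_span(footprints[c], chromosome_lengths[c])
            span_mid = (span[0] + span[1]) // 2
            best = min(pool, key=lambda g: (abs(g.midpoint - span_mid), g.midpoint))
            pool.remove(best)
            footprints[c].append((best.start, best.end))
            picked.append(best)
            visits[c] -= 1
            progress = True
        if not progress:
            # some chromosomes exhausted their genes: redistribute leftover
            # visits over chromosomes that still have genes, by length
            avail = [c for c in chroms if by_chrom[c]]
            leftover = n_genes - len(picked)
            if not avail:
                raise ValueError("gene annotation exhausted before n_genes reached")
            warnings.warn(
                "chromosome gene pool exhausted; redistributing "
                f"{leftover} visits across {len(avail)} chromosomes"
            )
            redo = apportion_largest_remainder(
                [chromosome_lengths[c] for c in avail], leftover
            )
            visits = dict(zip(avail, redo))
            chroms = avail
    return picked


# ---------------------------------------------------------------------------
# per-gene exon selection


def select_exons_for_gene(
    gene: GeneModel, config: DesignConfig, rng: np.random.Generator
) -> list[ExonTarget]:
    """Apply the per-gene target rules; see module docstring for the policy."""

    def target(exon_idx: int, role: str, start=None, end=None) -> ExonTarget:
        s, e = gene.exons[exon_idx]
        return ExonTarget(
            chromosome=gene.chromosome,
            start=s if start is None else start,
            end=e if end is None else end,
            gene_id=gene.gene_id,
            exon_ordinal=gene.tx_order().index(exon_idx),
            role=role,
            strand=gene.strand,
        )

    if gene.gene_id in config.candidate_gene_ids:
        return [target(i, "candidate_gene") for i in gene.tx_order()]

    lengths = [e - s for s, e in gene.exons]
    if all(l > config.per_gene_bp_cap for l in lengths):
        # only over-cap exons: take both ends of the 5'-terminal exon
        first = gene.tx_order()[0]
        s, e = gene.exons[first]
        w = config.long_first_exon_end_bp
        return [
            target(first, "long_first_exon_end", start=s, end=s + w),
            target(first, "long_first_exon_end", start=e - w, end=e),
        ]

    out = [target(gene.utr5_exon, "utr5")]
    total = lengths[gene.utr5_exon]
    pool = [
        i
        for i in gene.tx_order()
        if i != gene.utr5_exon and lengths[i] >= config.min_exon_bp
    ]
    order = rng.permutation(len(pool)) if pool else []
    for k in order:
        if total > config.per_gene_bp_cap:
            break
        i = pool[int(k)]
        out.append(target(i, "sampled"))
        total += lengths[i]
    return out


# ---------------------------------------------------------------------------
# redundancy screen


def _similarity_params(window: int, identity: float) -> tuple[int, int]:
    """(matches needed for rejection, seed k guaranteeing detection)."""
    needed = math.floor(identity * window) + 1  # strictly greater than identity
    max_mm = window - needed
    k = max(1, math.ceil((window - max_mm) / (max_mm + 1)))
    return needed, k


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_ACGT_CODES = frozenset(b"ACGT")


def _has_similar_window(a: np.ndarray, b: np.ndarray, window: int, needed: int, k: int) -> bool:
    """True iff some length-`window` ungapped alignment of a against b has
    >= `needed` matching ACGT bases. Exact via exhaustive diagonal scan of
    k-mer-seeded diagonals (the seed length guarantees every qualifying
    window contains an exact k-mer match)."""
    na, nb = len(a), len(b)
    if na < window or nb < window:
        return False
    index: dict[bytes, list[int]] = {}
    bb = b.tobytes()
    for j in range(nb - k + 1):
        kmer = bb[j : j + k]
        if any(c not in _ACGT_CODES for c in kmer):
            continue
        index.setdefault(kmer, []).append(j)
    aa = a.tobytes()
    diagonals: set[int] = set()
    for i in range(na - k + 1):
        hits = index.get(aa[i : i + k])
        if hits:
            for j in hits:
                diagonals.add(i - j)
    acgt = np.zeros(256, dtype=bool)
    for c in b"ACGT":
        acgt[c] = True
    for d in diagonals:
        s = max(0, d)
        e = min(na, nb + d)
        if e - s < window:
            continue
        av = a[s:e]
        bv = b[s - d : e - d]
        match = (av == bv) & acgt[av]
        csum = np.concatenate(([0], np.cumsum(match)))
        wins = csum[window:] - csum[:-window]
        if wins.size and wins.max() >= needed:
            return True
    return False


def redundancy_filter(
    candidate_sequence: str,
    collected_sequences: Sequence[str],
    window: int = 40,
    identity: float = 0.90,
) -> bool:
    """Accept (True) or reject (False) a candidate exon sequence.

    Rejected iff some ungapped window of exactly `window` bp aligned against
    any already-collected exon (either strand) has identity strictly greater
    than `identity`; N never counts as a match. Sequences shorter than the
    window can never be rejected.
    """
    if len(candidate_sequence) < window:
        return True
    needed, k = _similarity_params(window, identity)
    if needed > window:
        return True
    cand = _seq_array(candidate_sequence)
    for coll in collected_sequences:
        if len(coll) < window:
            continue
        fwd = _seq_array(coll)
        if _has_similar_window(cand, fwd, window, needed, k):
            return False
        rev = _seq_array(revcomp(coll))
        if _has_similar_window(cand, rev, window, needed, k):
            return False
    return True


# ---------------------------------------------------------------------------
# whole-design driver


def design_targets(
    genes: Iterable[GeneModel],
    genome: Mapping[str, object],
    config: DesignConfig,
    seed: int,
) -> tuple[list[ExonTarget], pd.DataFrame]:
    """Run the full capture design: candidates first, then genome-wide
    sampling until ``n_genomewide_genes`` genes are taken or the base-pair
    budget is reached, screening every emitted exon for redundancy in
    emission order.

    ``genome`` maps chromosome name to a sliceable sequence (dict of str or
    a pyfaidx.Fasta). Returns the accepted targets and a per-gene report.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    # .keys() works for both plain dicts and pyfaidx.Fasta
    chrom_lengths = {c: len(genome[c]) for c in genome.keys()}

    def seq_of(t: ExonTarget) -> str:
        return str(genome[t.chromosome][t.start : t.end]).upper()

    targets: list[ExonTarget] = []
    collected: list[str] = []
    total_bp = 0
    report_rows: list[dict] = []

    def emit_gene(gene: GeneModel) -> None:
        nonlocal total_bp
        kept: list[ExonTarget] = []
        for t in select_exons_for_gene(gene, config, rng):
            s = seq_of(t)
            if redundancy_filter(
                s, collected, config.redundancy_window_bp, config.redundancy_identity
            ):
                targets.append(t)
                collected.append(s)
                kept.append(t)
                total_bp += t.length
        report_rows.append(
            {
                "gene_id": gene.gene_id,
                "n_exons_selected": len(kept),
                "total_bp": sum(t.length for t in kept),
                "roles": ",".join(sorted({t.role for t in kept})),
            }
        )

    candidates = sorted(
        (g for g in genes if g.gene_id in config.candidate_gene_ids),
        key=lambda g: (g.chromosome, g.start, g.gene_id),
    )
    for g in candidates:
        emit_gene(g)
    if total_bp > config.total_bp_budget:
        raise BudgetError(
            f"candidate genes alone occupy {total_bp} bp, over the "
            f"{config.total_bp_budget} bp budget"
        )

    n_avail = sum(1 for g in genes if g.gene_id not in config.candidate_gene_ids)
    n_wanted = min(config.n_genomewide_genes, n_avail)
    if n_wanted > 0:
        order = select_genes_genomewide(
            genes, chrom_lengths, n_wanted, frozenset(config.candidate_gene_ids)
        )
        for g in order:
            if total_bp >= config.total_bp_budget:
                break
            emit_gene(g)

    targets.sort(key=lambda t: (t.chromosome, t.start, t.end))
    report = pd.DataFrame(
        report_rows, columns=["gene_id", "n_exons_selected", "total_bp", "roles"]
    )
    return targets, report


# ---------------------------------------------------------------------------
# BED6 I/O


def write_bed6(targets: Iterable[ExonTarget], path) -> None:
    with open(path, "w") as fh:
        for t in sorted(targets, key=lambda t: (t.chromosome, t.start, t.end)):
            fh.write(
                f"{t.chromosome}\t{t.start}\t{t.end}\t{t.name}\t0\t{t.strand}\n"
            )


def read_bed6(path) -> list[ExonTarget]:
    out: list[ExonTarget] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "target|0|sampled"
            strand = f[5] if len(f) > 5 else "+"
            parts = name.split("|")
            gene_id = parts[0]
            ordinal = int(parts[1]) if len(parts) > 1 and parts[1].isdigit() else 0
            role = parts[2] if len(parts) > 2 else "sampled"
            out.append(
                ExonTarget(chrom, start, end, gene_id, ordinal, role, strand)
            )
    return out
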