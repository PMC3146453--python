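"""Diploid consensus genotyping from pileups of filtered reads.

Model
-----
At each targeted position covered by at least one surviving read, the
caller evaluates the posterior over the 10 unordered diploid genotypes
{x,y} on alleles {A,C,G,T}. Base calls are treated as independent draws:

    P(b | {x,y}) = 1/2 [ p(b|x) + p(b|y) ],
    p(b|x) = 1 - e   if b == x,   else e/3,     e = 10**(-q/10)

with q the (recalibrated) base quality. The prior puts mass
1 - theta_het - theta_hom on the reference homozygote, theta_het/3 on
each heterozygote carrying the reference allele, and spreads theta_hom
equally over the six genotypes without the reference allele. theta_het
mirrors the conventional per-site variant-rate parameter (default 0.001);
theta_hom defaults to half of it. The call is the posterior mode
(ties broken toward genotypes containing the reference allele) and its
Phred-like consensus quality is round(-10*log10(1 - posterior)), capped
at 99.

High-confidence calls additionally require a minimum depth (default 8)
and minimum consensus quality (default 30); the number of retained
targeted positions is the "callable bases" denominator of the variant
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from .dna import BASES, iupac_code, round_half_up
from .read_processing import MappedRead, TargetIndex

__all__ = [
    "PileupColumn",
    "ConsensusCall",
    "CallFilterConfig",
    "GENOTYPES",
    "genotype_priors",
    "build_pileup",
    "call_consensus",
    "call_pileup",
    "filter_calls",
]

# the 10 unordered diploid genotypes as allele-index pairs (x <= y)
GENOTYPES: tuple[tuple[int, int], ...] = tuple(
    (x, y) for x in range(4) for y in range(x, 4)
)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PileupColumn:
    chromosome: str
    position: int  # 0-based
    reference_base: str
    bases: np.ndarray  # allele indices 0..3
    qualities: np.ndarray
    strands: np.ndarray  # carried but unused by the model

    @property
    def depth(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ConsensusCall:
    chromosome: str
    position: int  # 0-based
    reference_base: str
    genotype: str  # IUPAC code
    quality: int
    depth: int

    @property
    def is_heterozygous(self) -> bool:
        return self.genotype not in BASES


@dataclass(frozen=True)
class CallFilterConfig:
    min_depth: int = 8
    min_quality: int = 30

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_quality < 0:
            raise ValueError("thresholds must be non-negative")


def genotype_priors(ref_base: str, theta_het: float, theta_hom: float) -> np.ndarray:
    """Prior over the 10 genotypes given the reference base."""
    if not 0 < theta_het + theta_hom < 1:
        raise ValueError("theta_het + theta_hom must lie in (0,1)")
    r = _BASE_INDEX[ref_base]
    pri = np.empty(len(GENOTYPES))
    for g, (x, y) in enumerate(GENOTYPES):
        if x == y == r:
            pri[g] = 1.0 - theta_het - theta_hom
        elif x == r or y == r:
            pri[g] = theta_het / 3.0
        else:
            pri[g] = theta_hom / 6.0
    return pri


def build_pileup(
    reads: Iterable[MappedRead],
    targets: TargetIndex,
    reference: Mapping[str, object],
) -> Iterator[PileupColumn]:
    """One column per targeted position covered by >= 1 read.

    Reads are assumed to have passed filtering and duplicate removal; reads
    with non-match CIGARs are skipped with a warning. Columns are yielded
    in (chromosome, position) order; reference-N positions are skipped.
    """
    per_chrom: dict[str, dict[int, tuple[list, list, list]]] = {}
    targeted_masks: dict[str, np.ndarray] = {}

    def mask_for(chrom: str, length: int) -> np.ndarray:
        m = targeted_masks.get(chrom)
        if m is None:
            m = np.zeros(length, dtype=bool)
            for s, e in targets.merged_intervals(chrom):
                m[s:e] = True
            targeted_masks[chrom] = m
        return m

    for r in reads:
        if not r.is_all_match():
            warnings.warn(f"{r.read_id}: non-match CIGAR {r.cigar!r} skipped in pileup")
            continue
        refseq = reference[r.chromosome]
        m = mask_for(r.chromosome, len(refseq))
        cols = per_chrom.setdefault(r.chromosome, {})
        for i in range(r.length):
            pos = r.position + i
            if pos >= len(m) or not m[pos]:
                continue
            b = r.bases[i]
            if b not in _BASE_INDEX:
                continue
            col = cols.get(pos)
            if col is None:
                col = ([], [], [])
                cols[pos] = col
            col[0].append(_BASE_INDEX[b])
            col[1].append(int(r.qualities[i]))
            col[2].append(0 if r.strand == "+" else 1)

    for chrom in sorted(per_chrom):
        refseq = str(reference[chrom][:]).upper()
        for pos in sorted(per_chrom[chrom]):
            ref_b = refseq[pos]
            if ref_b not in _BASE_INDEX:
                continue
            bases, quals, strands = per_chrom[chrom][pos]
            yield PileupColumn(
                chromosome=chrom,
                position=pos,
                reference_base=ref_b,
                bases=np.array(bases, dtype=np.int64),
                qualities=np.array(quals, dtype=np.int64),
                strands=np.array(strands, dtype=np.int64),
            )


def _posteriors(column: PileupColumn, theta_het: float, theta_hom: float) -> np.ndarray:
    e = np.power(10.0, -column.qualities / 10.0)
    # p[a, i] = P(observed base_i | true allele a)
    p = np.tile(e / 3.0, (4, 1))
    p[column.bases, np.arange(column.depth)] = 1.0 - e
    loglik = np.array(
        [np.log(0.5 * (p[x] + p[y])).sum() for x, y in GENOTYPES]
    )
    logpost = loglik + np.log(genotype_priors(column.reference_base, theta_het, theta_hom))
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def call_consensus(
    column: PileupColumn,
    theta_het: float = 0.001,
    theta_hom: float | None = None,
) -> ConsensusCall:
    """Posterior-mode diploid genotype for one pileup column."""
    if column.depth == 0:
        raise ValueError("cannot call a genotype on an empty column")
    if theta_hom is None:
        theta_hom = theta_het / 2.0
    post = _posteriors(column, theta_het, theta_hom)
    r = _BASE_INDEX[column.reference_base]
    # ties broken toward genotypes containing the reference allele
    order = sorted(
        range(len(GENOTYPES)),
        key=lambda g: (-post[g], 0 if r in GENOTYPES[g] else 1, g),
    )
    best = order[0]
    err = max(1.0 - float(post[best]), 1e-10)
    quality = min(99, round_half_up(-10.0 * np.log10(err)))
    x, y = GENOTYPES[best]
    return ConsensusCall(
        chromosome=column.chromosome,
        position=column.position,
        reference_base=column.reference_base,
        genotype=iupac_code(BASES[x], BASES[y]),
        quality=quality,
        depth=column.depth,
    )


def call_pileup(
    columns: Iterable[PileupColumn],
    theta_het: float = 0.001,
    theta_hom: float | None = None,
) -> list[ConsensusCall]:
    return [call_consensus(c, theta_het, theta_hom) for c in columns]


def filter_calls(
    calls: Iterable[ConsensusCall], config: CallFilterConfig = CallFilterConfig()
) -> tuple[list[ConsensusCall], int]:
    """High-confidence calls and the callable-base count (their number)."""
    kept = [
        c
        for c in calls
        if c.depth >= config.min_depth and c.quality >= config.min_quality
    ]
    return kept, len(kept)
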