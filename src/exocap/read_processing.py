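"""Mapped-read filtering ahead of genotyping.

Three criteria, applied in order to a position-sorted stream:

1. reads not uniquely mapped are discarded (operationalised as a mapping
   quality below a configurable floor, default MAPQ >= 1);
2. reads with no aligned base overlapping a capture target are discarded;
3. PCR duplicates are removed: within each group of reads mapped at
   identical (chromosome, position, strand), only the read with the
   highest sum of base qualities is kept (ties broken by lowest read id).

Reads whose CIGAR contains anything but aligned matches are rejected with
a warning; indel handling is out of scope.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .target_design import ExonTarget

__all__ = [
    "MappedRead",
    "TargetIndex",
    "FilterStats",
    "DuplicateStats",
    "SortOrderError",
    "filter_reads",
    "remove_pcr_duplicates",
    "read_sam",
    "write_sam",
]

_CIGAR_ALL_M = re.compile(r"^(\d+)M$")


class SortOrderError(ValueError):
    """Input reads are not sorted by (chromosome, position)."""


@dataclass(frozen=True)
class MappedRead:
    """A single-end aligned read (position 0-based, match-only CIGAR)."""

    read_id: str
    chromosome: str
    position: int
    strand: str
    cigar: str
    bases: str
    qualities: np.ndarray  # integer Phred scores, one per base
    mapping_quality: int

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"{self.read_id}: |bases| != |qualities|")

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        return self.position + self.length

    @property
    def quality_sum(self) -> int:
        return int(np.sum(self.qualities))

    def is_all_match(self) -> bool:
        return bool(_CIGAR_ALL_M.match(self.cigar))


class TargetIndex:
    """Per-chromosome interval index over capture targets."""

    def __init__(self, targets: Iterable[ExonTarget]):
        self._trees: dict[str, IntervalTree] = {}
        self._targets = list(targets)
        for t in self._targets:
            self._trees.setdefault(t.chromosome, IntervalTree()).addi(t.start, t.end, t)

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        tree = self._trees.get(chromosome)
        return bool(tree is not None and tree.overlap(start, end))

    def containing(self, chromosome: str, position: int) -> list[ExonTarget]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(position)]

    def merged_intervals(self, chromosome: str) -> list[tuple[int, int]]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        merged = IntervalTree(tree)
        merged.merge_overlaps()
        return sorted((iv.begin, iv.end) for iv in merged)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    @property
    def total_bp(self) -> int:
        return sum(
            e - s for c in self._trees for s, e in self.merged_intervals(c)
        )

    def __iter__(self) -> Iterator[ExonTarget]:
        return iter(self._targets)


@dataclass
class FilterStats:
    n_input: int = 0
    n_non_unique: int = 0
    n_off_target: int = 0
    n_bad_cigar: int = 0
    n_passed: int = 0

    @property
    def on_target_fraction(self) -> float:
        """On-target fraction among uniquely mapped, well-formed reads."""
        unique = self.n_input - self.n_non_unique - self.n_bad_cigar
        return self.n_passed / unique if unique else 0.0


@dataclass
class DuplicateStats:
    n_input: int = 0
    n_removed: int = 0

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def _check_sorted(reads: Iterable[MappedRead]) -> Iterator[MappedRead]:
    seen_chroms: set[str] = set()
    cur_chrom: str | None = None
    cur_pos = -1
    for r in reads:
        if r.chromosome != cur_chrom:
            if r.chromosome in seen_chroms:
                raise SortOrderError(
                    f"reads not grouped by chromosome (revisited {r.chromosome})"
                )
            seen_chroms.add(r.chromosome)
            cur_chrom, cur_pos = r.chromosome, -1
        if r.position < cur_pos:
            raise SortOrderError(
                f"reads not position-sorted on {r.chromosome} "
                f"({r.position} after {cur_pos})"
            )
        cur_pos = r.position
        yield r


def filter_reads(
    reads: Iterable[MappedRead],
    targets: TargetIndex,
    min_mapq: int = 1,
) -> tuple[list[MappedRead], FilterStats]:
    """Keep uniquely mapped reads with at least one aligned base on target."""
    stats = FilterStats()
    out: list[MappedRead] = []
    for r in _check_sorted(reads):
        stats.n_input += 1
        if not r.is_all_match():
            stats.n_bad_cigar += 1
            warnings.warn(f"{r.read_id}: non-match CIGAR {r.cigar!r}, read rejected")
            continue
        if r.mapping_quality < min_mapq:
            stats.n_non_unique += 1
            continue
        if not targets.overlaps(r.chromosome, r.position, r.end):
            stats.n_off_target += 1
            continue
        out.append(r)
        stats.n_passed += 1
    return out, stats


def remove_pcr_duplicates(
    reads: Iterable[MappedRead],
) -> tuple[list[MappedRead], DuplicateStats]:
    """Collapse (chromosome, position, strand) groups to the best read.

    The survivor maximises the sum of base qualities; ties go to the
    lexicographically smallest read id, making the result independent of
    input order within a group.
    """
    stats = DuplicateStats()
    out: list[MappedRead] = []
    group: dict[str, MappedRead] = {}
    group_key: tuple[str, int] | None = None

    def flush() -> None:
        for strand in sorted(group):
            out.append(group[strand])

    for r in _check_sorted(reads):
        stats.n_input += 1
        key = (r.chromosome, r.position)
        if key != group_key:
            flush()
            group = {}
            group_key = key
        best = group.get(r.strand)
        if best is None:
            group[r.strand] = r
        else:
            stats.n_removed += 1
            if (-r.quality_sum, r.read_id) < (-best.quality_sum, best.read_id):
                group[r.strand] = r
    flush()
    return out, stats


# ---------------------------------------------------------------------------
# SAM I/O (via pysam; headers preserved where present)


def write_sam(
    reads: Sequence[MappedRead],
    chromosome_lengths: Mapping[str, int],
    path,
) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chromosome_lengths.items()],
    }
    ref_ids = {c: i for i, c in enumerate(chromosome_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.query_sequence = r.bases
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = ref_ids[r.chromosome]
            a.reference_start = r.position
            a.mapping_quality = r.mapping_quality
            a.cigarstring = r.cigar
            a.query_qualities = [int(q) for q in r.qualities]
            fh.write(a)


def read_sam(path) -> Iterator[MappedRead]:
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            yield MappedRead(
                read_id=a.query_name,
                chromosome=a.reference_name,
                position=a.reference_start,
                strand="-" if a.is_reverse else "+",
                cigar=a.cigarstring or "",
                bases=a.query_sequence or "",
                qualities=np.asarray(a.query_qualities, dtype=np.int64),
                mapping_quality=a.mapping_quality,
            )
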