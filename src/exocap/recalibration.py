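"""Empirical base-quality recalibration.

Sequencer-reported base qualities can be mis-calibrated (the motivating
case is an older instrument whose software lacked the vendor's on-board
correction). The procedure: after filtering and duplicate removal, treat
every mismatch between an aligned base and the reference as sequencer
error, bin aligned bases by their reported quality, and compute an
empirical error rate per bin as the ratio of mismatches to matches
(m/M, per the original formulation; the m/(m+M) proportion is available
as an option — the two differ only at O(e^2)). Reported qualities are then
replaced by the Phred score of the empirical rate.

For an individual highly diverged from the reference, real differences
masquerade as errors and deflate qualities severely; the remedy is to
average the per-bin error rates measured on closer relatives and
recalibrate the divergent sample with the averaged table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dna import phred_from_error
from .read_processing import MappedRead

__all__ = [
    "RecalibrationTable",
    "build_recalibration_table",
    "average_tables",
    "apply_recalibration",
]

QUALITY_FLOOR = 2
QUALITY_CEIL = 41


@dataclass(frozen=True)
class RecalibrationTable:
    """Per original quality: match/mismatch counts, error rate, replacement.

    ``error_rates`` may be averaged across samples, in which case it is not
    the ratio of the (summed) counts; the rates are therefore stored
    explicitly. Replacement qualities are Phred(-10*log10 e), rounded
    half-up and clamped to [2, 41]; a bin with no observed mismatches maps
    to the ceiling.
    """

    matches: dict[int, int]
    mismatches: dict[int, int]
    error_rates: dict[int, float]
    replacements: dict[int, int]

    @classmethod
    def from_counts(
        cls,
        matches: Mapping[int, int],
        mismatches: Mapping[int, int],
        rate_mode: str = "mismatch_over_match",
    ) -> "RecalibrationTable":
        if rate_mode not in ("mismatch_over_match", "mismatch_over_total"):
            raise ValueError(f"unknown rate_mode {rate_mode!r}")
        qs = sorted(set(matches) | set(mismatches))
        if not qs:
            raise ValueError("cannot build a recalibration table from zero aligned bases")
        rates: dict[int, float] = {}
        for q in qs:
            m = mismatches.get(q, 0)
            mm = matches.get(q, 0)
            if rate_mode == "mismatch_over_match":
                rates[q] = m / mm if mm > 0 else float("inf")
            else:
                rates[q] = m / (m + mm) if (m + mm) > 0 else float("inf")
        return cls(
            matches={q: matches.get(q, 0) for q in qs},
            mismatches={q: mismatches.get(q, 0) for q in qs},
            error_rates=rates,
            replacements={
                q: phred_from_error(rates[q], QUALITY_FLOOR, QUALITY_CEIL) for q in qs
            },
        )

    @property
    def qualities(self) -> list[int]:
        return sorted(self.error_rates)

    def replacement_for(self, q: int) -> int:
        """Replacement quality; unseen bins map to the nearest observed bin
        (ties toward the lower quality)."""
        if q in self.replacements:
            return self.replacements[q]
        nearest = min(self.qualities, key=lambda qq: (abs(qq - q), qq))
        return self.replacements[nearest]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quality": self.qualities,
                "matches": [self.matches.get(q, 0) for q in self.qualities],
                "mismatches": [self.mismatches.get(q, 0) for q in self.qualities],
                "error_rate": [self.error_rates[q] for q in self.qualities],
                "new_quality": [self.replacements[q] for q in self.qualities],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RecalibrationTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            matches=dict(zip(df["quality"], df["matches"])),
            mismatches=dict(zip(df["quality"], df["mismatches"])),
            error_rates=dict(zip(df["quality"], df["error_rate"])),
            replacements=dict(zip(df["quality"], df["new_quality"])),
        )


def build_recalibration_table(
    reads: Iterable[MappedRead],
    reference: Mapping[str, object],
    rate_mode: str = "mismatch_over_match",
    mask=None,
) -> RecalibrationTable:
    """Count per-quality matches/mismatches of aligned bases vs reference.

    Expects reads that already passed filtering and duplicate removal.
    Reference N positions are skipped, as are non-ACGT read bases. An
    optional ``mask`` (TargetIndex-like with ``overlaps``) excludes
    positions, e.g. known-variant sites.
    """
    is_acgt = np.zeros(256, dtype=bool)
    for c in b"ACGT":
        is_acgt[c] = True
    match_counts = np.zeros(94, dtype=np.int64)
    mismatch_counts = np.zeros(94, dtype=np.int64)
    ref_cache: dict[str, np.ndarray] = {}
    n_bases = 0
    for r in reads:
        refarr = ref_cache.get(r.chromosome)
        if refarr is None:
            refarr = np.frombuffer(
                str(reference[r.chromosome][:]).upper().encode("ascii"), dtype=np.uint8
            )
            ref_cache[r.chromosome] = refarr
        ref_slice = refarr[r.position : r.end]
        bases = np.frombuffer(r.bases.encode("ascii"), dtype=np.uint8)
        valid = is_acgt[ref_slice] & is_acgt[bases]
        if mask is not None:
            keep = np.array(
                [
                    not mask.overlaps(r.chromosome, p, p + 1)
                    for p in range(r.position, r.end)
                ]
            )
            valid &= keep
        qs = r.qualities
        is_match = bases == ref_slice
        np.add.at(match_counts, qs[valid & is_match], 1)
        np.add.at(mismatch_counts, qs[valid & ~is_match], 1)
        n_bases += int(valid.sum())
    if n_bases == 0:
        raise ValueError("zero aligned bases: cannot recalibrate")
    matches = {int(q): int(c) for q, c in enumerate(match_counts) if c}
    mismatches = {int(q): int(c) for q, c in enumerate(mismatch_counts) if c}
    return RecalibrationTable.from_counts(matches, mismatches, rate_mode)


def average_tables(tables: Sequence[RecalibrationTable]) -> RecalibrationTable:
    """Arithmetic mean of per-bin error rates over tables observing the bin.

    A bin counts as observed in a table when it has at least one match
    (a finite error rate). Counts are summed for bookkeeping; replacement
    qualities are recomputed from the averaged rates.
    """
    if not tables:
        raise ValueError("need at least one table to average")
    qs = sorted({q for t in tables for q in t.error_rates})
    rates: dict[int, float] = {}
    for q in qs:
        observed = [
            t.error_rates[q]
            for t in tables
            if q in t.error_rates and t.matches.get(q, 0) > 0
        ]
        if not observed:  # bin seen only as mismatches: keep the infinite rate
            observed = [t.error_rates[q] for t in tables if q in t.error_rates]
        rates[q] = float(np.mean(observed))
    return RecalibrationTable(
        matches={q: sum(t.matches.get(q, 0) for t in tables) for q in qs},
        mismatches={q: sum(t.mismatches.get(q, 0) for t in tables) for q in qs},
        error_rates=rates,
        replacements={
            q: phred_from_error(rates[q], QUALITY_FLOOR, QUALITY_CEIL) for q in qs
        },
    )


def apply_recalibration(
    reads: Iterable[MappedRead], table: RecalibrationTable
) -> list[MappedRead]:
    """Replace every base quality with the table's replacement quality."""
    lut = np.array([table.replacement_for(q) for q in range(94)], dtype=np.int64)
    return [replace(r, qualities=lut[r.qualities]) for r in reads]
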