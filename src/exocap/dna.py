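"""Small DNA utilities shared across the pipeline.

IUPAC ambiguity codes are used throughout to report diploid genotypes:
a homozygous genotype is written as the single base, a heterozygote as
the two-allele ambiguity code (R, Y, M, K, W, S).
"""

from __future__ import annotations

import math

BASES = "ACGT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# two-allele ambiguity codes; single bases map to themselves
IUPAC_TO_ALLELES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
}

ALLELES_TO_IUPAC: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_TO_ALLELES.items()
}

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def iupac_code(allele_a: str, allele_b: str) -> str:
    """IUPAC code for an unordered diploid genotype over {A,C,G,T}."""
    try:
        return ALLELES_TO_IUPAC[frozenset((allele_a, allele_b))]
    except KeyError:
        raise ValueError(f"not a diploid ACGT genotype: {allele_a}/{allele_b}")


def alleles_of(code: str) -> frozenset[str]:
    try:
        return IUPAC_TO_ALLELES[code.upper()]
    except KeyError:
        raise ValueError(f"unsupported IUPAC genotype code: {code!r}")


def is_heterozygous(code: str) -> bool:
    return len(alleles_of(code)) == 2


def is_transition(ref: str, alt: str) -> bool:
    return frozenset((ref, alt)) in TRANSITIONS


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (Phred convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def phred_from_error(e: float, lo: int = 2, hi: int = 41) -> int:
    """Phred score for an error probability, clamped to [lo, hi]."""
    if e <= 0.0:
        return hi
    if math.isinf(e) or e >= 1.0:
        return lo
    return max(lo, min(hi, round_half_up(-10.0 * math.log10(e))))
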