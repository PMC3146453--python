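"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence


def apportion_largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Split `total` integer units across items proportionally to `weights`.

    Hamilton / largest-remainder apportionment: each item gets the floor of
    its exact quota, and the leftover units go to the largest fractional
    remainders. Ties are broken by input order, making the result fully
    deterministic.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    quotas = [total * w / wsum for w in weights]
    counts = [int(q) for q in quotas]
    leftover = total - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100*n/d rounded half-up to `decimals` places (report convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        Decimal(100.0 * numerator / denominator).quantize(q, rounding=ROUND_HALF_UP)
    )
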