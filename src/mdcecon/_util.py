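"""Shared numeric helpers: monetary rounding and integer apportionment."""

from __future__ import annotations

import math
from collections.abc import Sequence


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; monetary reporting
    here follows the commercial convention (0.5 CAD rounds up).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    """Apportion ``n`` units over categories by the largest-remainder method.

    Quotas n*p_i are floored; leftover units go to the categories with the
    largest fractional parts (ties broken by category order, earliest first),
    so the result is deterministic and sums to ``n`` exactly.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    quotas = [n * p for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(proportions)),
        key=lambda i: (-(quotas[i] - counts[i]), i),
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


def spread_total(total: int, k: int, minimum: int = 0, maximum: int | None = None) -> list[int]:
    """Split integer ``total`` into ``k`` parts, each in [minimum, maximum].

    Parts differ by at most one (an even spread), front-loaded
    deterministically. Raises if the bounds make the total infeasible.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if total < k * minimum:
        raise ValueError(f"total {total} below the feasible minimum {k * minimum}")
    if maximum is not None and total > k * maximum:
        raise ValueError(f"total {total} above the feasible maximum {k * maximum}")
    base, extra = divmod(total, k)
    return [base + 1 if i < extra else base for i in range(k)]
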