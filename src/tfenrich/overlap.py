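"""Two-set overlap statistics on a shared gene universe, and Venn partitions.

Given a universe of ``N`` genes and two subsets of sizes ``nA`` and ``nB``
with observed overlap ``k``, the expected overlap by chance is ``nA*nB/N``.
The "fold" statistic reports over-representation as ``k/expected`` when the
observed overlap meets or exceeds expectation, and under-representation as
the reciprocal form ``expected/k`` otherwise (an overlap of zero is flagged
as infinitely under-represented). The accompanying p-value is the one-sided
hypergeometric tail in the direction of the deviation: ``P(X >= k)`` for
over-representation, ``P(X <= k)`` for under-representation, with
``X ~ Hypergeometric(N, K, n)``.

Tails are accumulated in log space from log-gamma terms, so probabilities
remain accurate to well over ten significant digits down to the smallest
normal doubles (~1e-300).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import GeneSet

__all__ = [
    "OverlapRecord",
    "expected_overlap",
    "fold_representation",
    "hypergeom_tail",
    "overlap_table",
    "bonferroni_threshold",
    "venn_partition",
]


def expected_overlap(n_total: int, n_a: int, n_b: int) -> float:
    """Expected overlap of two random subsets of sizes nA, nB in a universe
    of N genes: ``nA * nB / N``."""
    if n_total < 1:
        raise ValueError("universe size must be >= 1")
    if not (0 <= n_a <= n_total) or not (0 <= n_b <= n_total):
        raise ValueError(
            f"set sizes ({n_a}, {n_b}) must lie in [0, {n_total}]"
        )
    return n_a * n_b / n_total


def fold_representation(
    k: int, n_total: int, n_a: int, n_b: int
) -> tuple[str, float]:
    """Over/under-representation of the observed overlap relative to chance.

    Returns ``("over", k/expected)`` when ``k >= expected`` (a tie counts as
    over-representation with fold 1.0), ``("under", expected/k)`` when the
    overlap falls short, and ``("under", inf)`` for an overlap of zero.
    """
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError(f"overlap k={k} must lie in [0, min(nA, nB)]")
    e = expected_overlap(n_total, n_a, n_b)
    if e == 0:
        # degenerate: one set is empty; nothing can overlap
        return ("over", 1.0) if k == 0 else ("over", math.inf)
    if k >= e:
        return ("over", k / e)
    if k == 0:
        return ("under", math.inf)
    return ("under", e / k)


def _log_pmf(N: int, K: int, n: int, i: np.ndarray) -> np.ndarray:
    # log C(K,i) + log C(N-K, n-i) - log C(N,n), via log-gamma
    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(K, i) + logc(N - K, n - i) - logc(N, n)


def hypergeom_tail(
    n_total: int, n_success: int, n_draw: int, k: int, direction: str = "over"
) -> float:
    """One-sided hypergeometric tail probability.

    ``direction="over"`` gives ``P(X >= k)``; ``direction="under"`` gives
    ``P(X <= k)`` for ``X ~ Hypergeometric(N=n_total, K=n_success,
    n=n_draw)``. The support is ``[max(0, n+K-N), min(K, n)]``; a ``k``
    outside it on the inclusive side yields exactly 1.0.
    """
    N, K, n = int(n_total), int(n_success), int(n_draw)
    if N < 1 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K, n)={min(K, n)}]")
    lo = max(0, n + K - N)
    hi = min(K, n)
    if direction == "over":
        if k <= lo:
            return 1.0
        i = np.arange(k, hi + 1)
    elif direction == "under":
        if k >= hi:
            return 1.0
        i = np.arange(lo, k + 1)
    else:
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    return float(min(1.0, math.exp(logsumexp(_log_pmf(N, K, n, i)))))


@dataclass(frozen=True)
class OverlapRecord:
    """One two-set comparison: sizes, observed and expected overlap, the
    over/under fold, and the directional hypergeometric tail."""

    label: str
    n_total: int
    n_a: int
    n_b: int
    k: int
    expected: float
    direction: str
    fold: float
    p_hyper: float


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def overlap_table(
    rows: Iterable[tuple[str, int, int, int, int]], alpha: float = 0.05
) -> tuple[list[OverlapRecord], float]:
    """Compute OverlapRecords for ``(label, N, nA, nB, k)`` rows plus the
    Bonferroni family-wise threshold ``alpha/m`` for the m rows supplied."""
    records = []
    for label, n_total, n_a, n_b, k in rows:
        direction, fold = fold_representation(k, n_total, n_a, n_b)
        records.append(
            OverlapRecord(
                label=label,
                n_total=n_total,
                n_a=n_a,
                n_b=n_b,
                k=k,
                expected=expected_overlap(n_total, n_a, n_b),
                direction=direction,
                fold=fold,
                p_hyper=hypergeom_tail(n_total, n_b, n_a, k, direction),
            )
        )
    if not records:
        raise ValueError("overlap_table needs at least one row")
    return records, bonferroni_threshold(len(records), alpha)


def overlap_from_sets(
    label: str, set_a: GeneSet, set_b: GeneSet, universe_size: int
) -> tuple[str, int, int, int, int]:
    """Build an overlap_table row directly from two gene sets."""
    k = len(set_a.member_set & set_b.member_set)
    return (label, universe_size, len(set_a), len(set_b), k)


def venn_partition(
    sets: Sequence[GeneSet] | Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], int]:
    """Counts for every non-empty region of a 2-4 set Venn diagram.

    Returns a mapping from the tuple of set names an element belongs to (in
    input order) to the number of elements with exactly that membership
    pattern; all ``2**s - 1`` patterns are present and the counts sum to the
    size of the union.
    """
    if isinstance(sets, Mapping):
        named = [(name, frozenset(members)) for name, members in sets.items()]
    else:
        named = [(gs.name, gs.member_set) for gs in sets]
    s = len(named)
    if not (2 <= s <= 4):
        raise ValueError(f"venn_partition supports 2-4 sets, got {s}")
    names = [n for n, _ in named]
    if len(set(names)) != s:
        raise ValueError("set names must be distinct")
    union = frozenset().union(*(m for _, m in named))
    counts: dict[tuple[str, ...], int] = {}
    # all non-empty membership patterns, in binary order over input position
    for mask in range(1, 2**s):
        pattern = tuple(names[i] for i in range(s) if mask >> i & 1)
        counts[pattern] = 0
    for g in union:
        pattern = tuple(n for n, m in named if g in m)
        counts[pattern] += 1
    return counts
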