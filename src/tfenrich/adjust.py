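"""Bonferroni and Benjamini-Hochberg multiple-testing corrections.

Both corrections take an explicit family size ``m`` that may exceed the
number of supplied p-values. That partial-family mode covers the common
reporting situation where only the top-ranked hits of a larger screen are in
hand (e.g. the smallest score p-values of a 445-TF screen): the supplied
values are treated as ranks ``1..len(raw)`` of the full family, and the
unobserved p-values are assumed large enough not to lower any step-up
minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AdjustedPValues", "bonferroni", "bh_adjust", "adjust_pvalues"]


def _validate(raw, m: int | None) -> tuple[np.ndarray, int]:
    p = np.asarray(raw, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("raw p-values must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("raw p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    m = int(m)
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of p-values {p.size}")
    return p, m


def bonferroni(raw, m: int | None = None) -> np.ndarray:
    """Family-wise correction: ``min(1, p * m)`` elementwise."""
    p, m = _validate(raw, m)
    return np.minimum(1.0, p * m)


def bh_adjust(raw, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    With the p-values sorted ascending and assigned ranks ``1..n`` (of a
    family of ``m >= n``), the adjusted value at rank ``j`` is
    ``min_{j' >= j} min(1, p_(j') * m / j')``, mapped back to input order.
    Ties share the larger rank's divisor before the suffix minimum, the
    standard step-up treatment. Rejecting ``adjusted <= alpha`` reproduces
    the classical step-up rejection set at level ``alpha``.
    """
    p, m = _validate(raw, m)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1, dtype=np.float64)
    scaled = np.minimum(1.0, p[order] * m / ranks)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n, dtype=np.float64)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class AdjustedPValues:
    """A raw -> adjusted p-value vector under a named correction."""

    raw: np.ndarray
    method: str  # "bonferroni" | "bh"
    m: int
    adjusted: np.ndarray


def adjust_pvalues(raw, method: str, m: int | None = None) -> AdjustedPValues:
    if method == "bonferroni":
        adj = bonferroni(raw, m)
    elif method == "bh":
        adj = bh_adjust(raw, m)
    else:
        raise ValueError(f"unknown correction method {method!r}; use 'bonferroni' or 'bh'")
    p, m_eff = _validate(raw, m)
    return AdjustedPValues(raw=p, method=method, m=m_eff, adjusted=adj)
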