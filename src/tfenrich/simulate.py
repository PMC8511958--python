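"""Synthetic universes, TF target tables, and query sets with known truth.

The generator emulates the input shapes of a larval-fly ChIP-seq TF-target
compendium screened against differential-expression gene lists: a fixed gene
universe, hundreds of TFs whose target-set sizes span roughly 500-9,000
genes, positive right-skewed (log-normal) peak scores, and query sets of a
few dozen to a hundred genes. A query can carry a planted signal: a chosen
fraction of its members is drawn from one TF's targets, optionally biased
toward high-scoring targets so that score enrichment and count enrichment
can be separated. Everything is a pure function of its arguments and the
seed.

The dataclass defaults are a small fixture profile (universe 5,000, 50 TFs)
sized so the statistical checks run in seconds; ``SyntheticSpec.full_scale``
gives the full-size profile (universe 13,964, 445 TFs, target range
500-9,000).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import GeneSet, GeneUniverse, TFTargetTable

__all__ = [
    "SyntheticSpec",
    "make_universe",
    "make_tf_table",
    "make_query_with_planted",
    "make_overlapping_sets",
]

# fixed per-operation stream keys so the generators draw from independent
# substreams of one seed
_STREAM_TABLE = 1
_STREAM_QUERY = 2
_STREAM_SETS = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of a synthetic benchmark instance."""

    n_bg: int = 5_000
    n_tfs: int = 50
    target_count_range: tuple[int, int] = (500, 2_500)
    score_log_mean: float = 0.0
    score_log_sd: float = 1.0
    planted_tfs: tuple[str, ...] = ()
    enrichment_fraction: float = 0.0
    high_score_bias: float = 0.0
    query_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.target_count_range
        if not (1 <= lo <= hi <= self.n_bg):
            raise ValueError(
                f"target_count_range {self.target_count_range} outside [1, {self.n_bg}]"
            )
        if not (0 <= self.enrichment_fraction <= 1):
            raise ValueError("enrichment_fraction must lie in [0, 1]")
        if self.high_score_bias < 0:
            raise ValueError("high_score_bias must be >= 0")
        if not (1 <= self.query_size <= self.n_bg):
            raise ValueError("query_size must lie in [1, n_bg]")
        if self.n_tfs < 1:
            raise ValueError("need at least one TF")

    @classmethod
    def full_scale(cls, **overrides) -> "SyntheticSpec":
        """Full-size profile: 13,964-gene universe, 445 TFs with 500-9,000
        targets each, 45-gene queries."""
        base = cls(
            n_bg=13_964,
            n_tfs=445,
            target_count_range=(500, 9_000),
            query_size=45,
        )
        return replace(base, **overrides) if overrides else base


def make_universe(n_bg: int, seed: int = 0) -> GeneUniverse:
    """A universe of ``n_bg`` unique synthetic identifiers (deterministic)."""
    if n_bg < 1:
        raise ValueError("universe size must be >= 1")
    width = len(str(n_bg))
    return GeneUniverse(tuple(f"g{i:0{width}d}" for i in range(1, n_bg + 1)))


def _tf_ids(n_tfs: int) -> tuple[str, ...]:
    width = len(str(n_tfs))
    return tuple(f"tf{i:0{width}d}" for i in range(1, n_tfs + 1))


def make_tf_table(spec: SyntheticSpec, universe: GeneUniverse) -> TFTargetTable:
    """TF target table: per-TF target count uniform on the configured range,
    targets sampled without replacement, i.i.d. log-normal peak scores."""
    lo, hi = spec.target_count_range
    if hi > universe.size:
        raise ValueError("target_count_range exceeds universe size")
    rng = np.random.default_rng([spec.seed, _STREAM_TABLE])
    targets: dict[str, dict[str, float]] = {}
    genes = universe.genes
    for tf in _tf_ids(spec.n_tfs):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(universe.size, size=size, replace=False)
        scores = rng.lognormal(spec.score_log_mean, spec.score_log_sd, size=size)
        targets[tf] = {genes[i]: float(s) for i, s in zip(idx, scores)}
    return TFTargetTable(universe, targets)


def make_query_with_planted(
    spec: SyntheticSpec, table: TFTargetTable, universe: GeneUniverse
) -> tuple[GeneSet, dict]:
    """A query gene set with a planted fraction of one TF's targets.

    ``round(enrichment_fraction * query_size)`` members are sampled from the
    planted TF's targets with weight proportional to ``score**high_score_bias``
    (``bias = 0`` is uniform over targets); the remainder is uniform over the
    rest of the universe. Returns the set and a ground-truth record with the
    planted TF and realized composition. With no planted TF (or fraction 0)
    the query is uniform over the universe.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_QUERY])
    genes = universe.genes
    n_plant = 0
    planted_tf = None
    planted_idx = np.empty(0, dtype=np.int64)
    if spec.planted_tfs and spec.enrichment_fraction > 0:
        if len(spec.planted_tfs) != 1:
            raise ValueError("exactly one planted TF is supported per query")
        planted_tf = spec.planted_tfs[0]
        if planted_tf not in table.tf_ids:
            raise ValueError(f"planted TF {planted_tf!r} not in table")
        n_plant = round(spec.enrichment_fraction * spec.query_size)
        tgt_idx = table.target_indices(planted_tf)
        if n_plant > tgt_idx.size:
            raise ValueError(
                f"cannot plant {n_plant} genes from {tgt_idx.size} targets"
            )
        w = table.target_scores(planted_tf) ** spec.high_score_bias
        w = w / w.sum()
        planted_idx = rng.choice(tgt_idx, size=n_plant, replace=False, p=w)
    n_rest = spec.query_size - n_plant
    pool = np.setdiff1d(
        np.arange(universe.size, dtype=np.int64), planted_idx, assume_unique=False
    )
    rest_idx = rng.choice(pool, size=n_rest, replace=False)
    members = tuple(genes[i] for i in np.sort(np.concatenate([planted_idx, rest_idx])))
    query = GeneSet("synthetic_query", "synthetic query with planted signal", members)
    truth = {
        "planted_tf": planted_tf,
        "n_planted": int(n_plant),
        "enrichment_fraction": spec.enrichment_fraction,
        "high_score_bias": spec.high_score_bias,
        "query_size": spec.query_size,
        "seed": spec.seed,
    }
    return query, truth


def make_overlapping_sets(
    n_total: int, n_a: int, n_b: int, k: int, seed: int = 0
) -> tuple[GeneSet, GeneSet, GeneUniverse]:
    """Two gene sets over a size-N universe with |A|=nA, |B|=nB, |A∩B|=k
    exactly (errors when the pigeonhole makes that infeasible)."""
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError(f"overlap {k} exceeds min(nA, nB)")
    if n_a + n_b - k > n_total:
        raise ValueError(
            f"infeasible: |A ∪ B| = {n_a + n_b - k} exceeds universe size {n_total}"
        )
    if min(n_a, n_b) < 1:
        raise ValueError("both sets must be non-empty")
    universe = make_universe(n_total, seed)
    rng = np.random.default_rng([seed, _STREAM_SETS])
    genes = universe.genes
    perm = rng.permutation(n_total)
    a_idx = perm[:n_a]
    shared = a_idx[:k]
    b_only = perm[n_a : n_a + n_b - k]
    b_idx = np.concatenate([shared, b_only])
    set_a = GeneSet("A", "synthetic", tuple(genes[i] for i in np.sort(a_idx)))
    set_b = GeneSet("B", "synthetic", tuple(genes[i] for i in np.sort(b_idx)))
    return set_a, set_b, universe
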