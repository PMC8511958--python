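"""Monte-Carlo permutation test for TF-target enrichment in a gene set.

For every transcription factor in a ChIP-seq-derived target table, two test
statistics are evaluated on a query gene set: the number of the TF's targets
inside the query (the count statistic) and the sum of the peak scores of
those targets (the score statistic; non-targets contribute zero). The null
distribution is built from random draws of the same size as the query, taken
uniformly without replacement from the gene universe. One shared draw stream
is evaluated against every TF, so the null is identical for all of them and
the per-TF cost is a single matrix product. The permutation p-value for each
statistic is the proportion of draws whose statistic is at least the observed
one (ties count toward the p-value, which keeps the p-values valid under the
null).

Two p-value conventions are offered. The plain proportion ``b/n_perm`` can be
exactly zero when no draw reaches the observed statistic; the add-one form
``(b+1)/(n_perm+1)`` is strictly positive. When the number of distinct draws
``C(N, draw_size)`` is small enough, the test enumerates all of them and the
p-values are exact and independent of the seed (the convention does not apply:
an exact proportion needs no correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
from scipy.sparse import csr_matrix

from .adjust import bh_adjust, bonferroni
from .io import GeneSet, GeneUniverse, TFTargetTable

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationConfig",
    "TFEnrichmentRecord",
    "observed_stats",
    "permutation_draws",
    "tf_enrichment_test",
    "rank_report",
]

# draw batches are capped so the (batch x 2T) statistic block stays small
_MAX_BATCH_CELLS = 2**25


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the Monte-Carlo null.

    n_perm: number of random draws (default one million).
    seed: seed for the single named random generator; recorded in outputs.
    p_value_convention: "plain" (b/n_perm, exact zeros possible) or
        "addone" ((b+1)/(n_perm+1), strictly positive).
    enumeration_threshold: if C(N, draw_size) is at most this, every distinct
        draw is enumerated once and p-values are exact.
    """

    n_perm: int = 1_000_000
    seed: int = 0
    p_value_convention: str = "plain"
    enumeration_threshold: int = 100_000

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.p_value_convention not in ("plain", "addone"):
            raise ValueError(
                "p_value_convention must be 'plain' or 'addone', "
                f"got {self.p_value_convention!r}"
            )


@dataclass(frozen=True)
class TFEnrichmentRecord:
    """One TF's observed statistics and permutation p-values."""

    tf_id: str
    n_targets_total: int
    k_observed: int
    score_observed: float
    p_count: float
    p_score: float
    p_score_bh: float
    p_score_bonferroni: float
    n_perm: int
    seed: int
    exhaustive: bool = False
    p_count_bh: float | None = None
    p_count_bonferroni: float | None = None


def restrict_query(query: GeneSet, universe: GeneUniverse) -> np.ndarray:
    """Universe indices of the query members, dropping (with a warning) any
    member outside the universe. An empty result is an error."""
    idx = [universe.index[g] for g in query.members if g in universe]
    n_dropped = len(query.members) - len(idx)
    if n_dropped:
        logger.warning(
            "query %s: dropped %d members outside the universe",
            query.name,
            n_dropped,
        )
    if not idx:
        raise ValueError(f"empty query set after universe restriction: {query.name}")
    return np.sort(np.asarray(idx, dtype=np.int64))


def observed_stats(
    query: GeneSet, table: TFTargetTable
) -> dict[str, tuple[int, float]]:
    """Per-TF (k_observed, score_observed) for a query set.

    k is the size of the intersection of the query with the TF's targets;
    the score is the sum of the TF's peak scores over that intersection.
    """
    q_idx = restrict_query(query, table.universe)
    q_set = set(q_idx.tolist())
    out: dict[str, tuple[int, float]] = {}
    for tf in table.tf_ids:
        idx = table.target_indices(tf)
        sc = table.target_scores(tf)
        mask = np.fromiter((i in q_set for i in idx), dtype=bool, count=idx.size)
        out[tf] = (int(mask.sum()), float(sc[mask].sum()))
    return out


def _sample_batch(
    rng: np.random.Generator, n_rows: int, n_bg: int, draw_size: int
) -> np.ndarray:
    """Uniform without-replacement draws as an (n_rows, draw_size) array of
    sorted universe indices."""
    if draw_size == n_bg:
        return np.tile(np.arange(n_bg, dtype=np.int64), (n_rows, 1))
    if draw_size <= n_bg // 8:
        # rejection sampling: rows with a duplicate are redrawn whole, which
        # leaves the accepted rows uniform over distinct draws
        out = np.sort(rng.integers(0, n_bg, size=(n_rows, draw_size)), axis=1)
        bad = (np.diff(out, axis=1) == 0).any(axis=1)
        while bad.any():
            redraw = np.sort(
                rng.integers(0, n_bg, size=(int(bad.sum()), draw_size)), axis=1
            )
            out[bad] = redraw
            still = (np.diff(redraw, axis=1) == 0).any(axis=1)
            idx = np.flatnonzero(bad)
            bad[:] = False
            bad[idx[still]] = True
        return out
    # dense draws: random keys per gene, take the draw_size smallest
    rows = []
    step = max(1, _MAX_BATCH_CELLS // n_bg)
    done = 0
    while done < n_rows:
        m = min(step, n_rows - done)
        keys = rng.random((m, n_bg))
        idx = np.argpartition(keys, draw_size - 1, axis=1)[:, :draw_size]
        rows.append(np.sort(idx, axis=1).astype(np.int64))
        done += m
    return np.vstack(rows)


def _enumerate_all(n_bg: int, draw_size: int) -> np.ndarray:
    n = math.comb(n_bg, draw_size)
    flat = np.fromiter(
        (i for combo in combinations(range(n_bg), draw_size) for i in combo),
        dtype=np.int64,
        count=n * draw_size,
    )
    return flat.reshape(n, draw_size)


def _iter_draw_batches(
    n_bg: int, draw_size: int, config: PermutationConfig
) -> Iterator[np.ndarray]:
    """Batches of draws (sorted index rows); exhaustive when feasible."""
    if not (1 <= draw_size <= n_bg):
        raise ValueError(f"draw_size {draw_size} outside [1, {n_bg}]")
    if math.comb(n_bg, draw_size) <= config.enumeration_threshold:
        yield _enumerate_all(n_bg, draw_size)
        return
    rng = np.random.default_rng(config.seed)
    batch = max(1, min(config.n_perm, _MAX_BATCH_CELLS // max(draw_size, 1)))
    done = 0
    while done < config.n_perm:
        m = min(batch, config.n_perm - done)
        yield _sample_batch(rng, m, n_bg, draw_size)
        done += m


def is_exhaustive(
    n_bg: int, draw_size: int, config: PermutationConfig
) -> bool:
    return math.comb(n_bg, draw_size) <= config.enumeration_threshold


def permutation_draws(
    universe: GeneUniverse, draw_size: int, config: PermutationConfig
) -> Iterator[tuple[str, ...]]:
    """The shared null stream as gene-identifier tuples, reproducible from
    the seed (exhaustive when ``C(N, draw_size)`` is within the threshold)."""
    genes = universe.genes
    for batch in _iter_draw_batches(universe.size, draw_size, config):
        for row in batch:
            yield tuple(genes[i] for i in row)


def _row_csr(idx: np.ndarray, n_bg: int) -> csr_matrix:
    return csr_matrix(
        (
            np.ones(idx.size, dtype=np.float64),
            idx,
            np.asarray([0, idx.size], dtype=np.int64),
        ),
        shape=(1, n_bg),
    )


def tf_enrichment_test(
    query: GeneSet,
    table: TFTargetTable,
    universe: GeneUniverse | None = None,
    config: PermutationConfig | None = None,
    adjust_count: bool = False,
) -> list[TFEnrichmentRecord]:
    """Permutation test of TF-target enrichment for one query gene set.

    Returns one record per TF, sorted by ascending score p-value (ties broken
    by count p-value, then TF id). Score p-values are Bonferroni- and
    BH-adjusted over the family of all TFs in the table; ``adjust_count``
    additionally adjusts the count p-values.
    """
    if universe is None:
        universe = table.universe
    elif universe is not table.universe and universe.genes != table.universe.genes:
        raise ValueError("universe does not match the one the table was built on")
    config = config or PermutationConfig()
    if table.n_tfs == 0:
        raise ValueError("TF target table has no TFs")

    q_idx = restrict_query(query, universe)
    draw_size = q_idx.size
    n_bg = universe.size
    t = table.n_tfs
    m = table.stat_matrix()  # (N, 2T)

    obs = (_row_csr(q_idx, n_bg) @ m).ravel()
    k_obs = obs[:t]
    score_obs = obs[t:]

    exhaustive = is_exhaustive(n_bg, draw_size, config)
    if exhaustive:
        logger.info(
            "exhaustive enumeration: C(%d, %d) distinct draws", n_bg, draw_size
        )
    ge_count = np.zeros(t, dtype=np.int64)
    ge_score = np.zeros(t, dtype=np.int64)
    n_draws = 0
    for batch in _iter_draw_batches(n_bg, draw_size, config):
        b = batch.shape[0]
        d = csr_matrix(
            (
                np.ones(batch.size, dtype=np.float64),
                batch.ravel(),
                np.arange(0, batch.size + 1, draw_size, dtype=np.int64),
            ),
            shape=(b, n_bg),
        )
        stats = d @ m  # (b, 2T)
        ge_count += (stats[:, :t] >= k_obs).sum(axis=0)
        ge_score += (stats[:, t:] >= score_obs).sum(axis=0)
        n_draws += b

    if exhaustive or config.p_value_convention == "plain":
        p_count = ge_count / n_draws
        p_score = ge_score / n_draws
    else:
        p_count = (ge_count + 1) / (n_draws + 1)
        p_score = (ge_score + 1) / (n_draws + 1)

    p_score_bh = bh_adjust(p_score)
    p_score_bonf = bonferroni(p_score)
    p_count_bh = bh_adjust(p_count) if adjust_count else [None] * t
    p_count_bonf = bonferroni(p_count) if adjust_count else [None] * t

    records = [
        TFEnrichmentRecord(
            tf_id=tf,
            n_targets_total=table.n_targets(tf),
            k_observed=int(round(k_obs[j])),
            score_observed=float(score_obs[j]),
            p_count=float(p_count[j]),
            p_score=float(p_score[j]),
            p_score_bh=float(p_score_bh[j]),
            p_score_bonferroni=float(p_score_bonf[j]),
            n_perm=n_draws,
            seed=config.seed,
            exhaustive=exhaustive,
            p_count_bh=None if p_count_bh[j] is None else float(p_count_bh[j]),
            p_count_bonferroni=(
                None if p_count_bonf[j] is None else float(p_count_bonf[j])
            ),
        )
        for j, tf in enumerate(table.tf_ids)
    ]
    records.sort(key=lambda r: (r.p_score, r.p_count, r.tf_id))
    return records


def rank_report(records: Sequence[TFEnrichmentRecord]):
    """Records as a DataFrame in report column order (one row per TF)."""
    import pandas as pd

    if not records:
        raise ValueError("no records to report")
    rows = []
    for r in sorted(records, key=lambda r: (r.p_score, r.p_count, r.tf_id)):
        row = {
            "tf": r.tf_id,
            "total_tf_genes": r.n_targets_total,
            "tf_genes_in_set": r.k_observed,
            "score_in_set": r.score_observed,
            "number_p": r.p_count,
            "score_p": r.p_score,
            "bh_corrected_p": r.p_score_bh,
            "bonferroni_corrected_p": r.p_score_bonferroni,
            "n_perm": r.n_perm,
            "seed": r.seed,
        }
        if r.p_count_bh is not None:
            row["number_bh_corrected_p"] = r.p_count_bh
            row["number_bonferroni_corrected_p"] = r.p_count_bonferroni
        rows.append(row)
    return pd.DataFrame(rows)
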