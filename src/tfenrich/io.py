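"""Readers and writers for the plain-text formats the pipeline touches.

Three formats are supported: a gene-universe file (one identifier per line),
GMT gene-set files (tab-separated: name, description, members...), and a
TF-target TSV with columns ``tf_id``, ``gene_id``, ``score``.

Identifier matching is exact, case-sensitive string equality throughout; no
symbol-to-ID mapping is attempted. The universe is the single source of truth
for the statistical background: TF-target rows whose gene is not in the
declared universe are dropped (with a counted warning), never added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneUniverse",
    "GeneSet",
    "TFTargetTable",
    "read_universe",
    "write_universe",
    "read_gmt",
    "write_gmt",
    "read_tf_targets",
    "write_tf_targets",
]


@dataclass(frozen=True)
class GeneUniverse:
    """The finite background of gene identifiers all statistics condition on.

    Iteration order is deterministic (first-seen input order). ``index`` maps
    each gene to its integer position, the coordinate system used by the
    vectorized permutation engine.
    """

    genes: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty universe")
        idx: dict[str, int] = {}
        for i, g in enumerate(self.genes):
            if not g:
                raise ValueError("empty gene identifier in universe")
            if g in idx:
                raise ValueError(f"duplicate gene identifier in universe: {g!r}")
            idx[g] = i
        object.__setattr__(self, "index", idx)

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in self.index

    def __iter__(self):
        return iter(self.genes)

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "GeneUniverse":
        """Build a universe, collapsing duplicates to first occurrence."""
        seen: dict[str, None] = {}
        n_dup = 0
        for g in genes:
            if g in seen:
                n_dup += 1
            else:
                seen[g] = None
        if n_dup:
            logger.warning("universe: collapsed %d duplicate identifiers", n_dup)
        return cls(tuple(seen))


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_iterable(
        cls, name: str, members: Iterable[str], description: str = ""
    ) -> "GeneSet":
        """Build a set, collapsing duplicate members to first occurrence."""
        seen: dict[str, None] = {}
        n_dup = 0
        for g in members:
            if g in seen:
                n_dup += 1
            else:
                seen[g] = None
        if n_dup:
            logger.warning(
                "gene set %s: collapsed %d duplicate members", name, n_dup
            )
        return cls(name, description, tuple(seen))


class TFTargetTable:
    """Per-TF target genes with positive peak scores, on a fixed universe.

    Internally each TF is a pair of parallel arrays: sorted universe indices
    of its targets and the matching peak scores. Every target is guaranteed to
    be a member of the universe and every score strictly positive.
    """

    def __init__(
        self,
        universe: GeneUniverse,
        targets: Mapping[str, Mapping[str, float]],
    ) -> None:
        if not targets:
            raise ValueError("TF target table must contain at least one TF")
        self.universe = universe
        self.tf_ids: tuple[str, ...] = tuple(targets)
        self._idx: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}
        for tf, gene_scores in targets.items():
            idx = []
            for g, s in gene_scores.items():
                if g not in universe:
                    raise ValueError(f"target {g!r} of {tf!r} not in universe")
                s = float(s)
                if not np.isfinite(s) or s <= 0:
                    raise ValueError(f"non-positive score for ({tf!r}, {g!r})")
                idx.append((universe.index[g], s))
            idx.sort()
            arr = np.asarray([i for i, _ in idx], dtype=np.int64)
            sc = np.asarray([s for _, s in idx], dtype=np.float64)
            self._idx[tf] = arr
            self._scores[tf] = sc

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    def target_indices(self, tf_id: str) -> np.ndarray:
        return self._idx[tf_id]

    def target_scores(self, tf_id: str) -> np.ndarray:
        return self._scores[tf_id]

    def target_genes(self, tf_id: str) -> tuple[str, ...]:
        genes = self.universe.genes
        return tuple(genes[i] for i in self._idx[tf_id])

    def n_targets(self, tf_id: str) -> int:
        return int(self._idx[tf_id].size)

    def stat_matrix(self) -> np.ndarray:
        """Dense (N, 2T) matrix: columns 0..T-1 are 0/1 target indicators,
        columns T..2T-1 carry the peak scores. One matrix multiply against a
        draw-incidence matrix then yields both test statistics for all TFs.
        """
        n = self.universe.size
        t = self.n_tfs
        m = np.zeros((n, 2 * t), dtype=np.float64)
        for j, tf in enumerate(self.tf_ids):
            idx = self._idx[tf]
            m[idx, j] = 1.0
            m[idx, t + j] = self._scores[tf]
        return m


def read_universe(path: str | Path) -> GeneUniverse:
    """Read a gene universe: one identifier per line, blank lines skipped.

    Duplicate lines collapse to the first occurrence with a logged warning;
    an empty file is an error.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    tokens = [ln.strip() for ln in lines]
    tokens = [t for t in tokens if t]
    if not tokens:
        raise ValueError(f"empty universe: {path}")
    return GeneUniverse.from_iterable(tokens)


def write_universe(universe: GeneUniverse, path: str | Path) -> None:
    Path(path).write_text("\n".join(universe.genes) + "\n", encoding="utf-8")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>member...``. Lines with fewer than three
    fields are rejected with the offending line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, members...)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet.from_iterable(name, members, desc))
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT, one per line in input order (LF endings)."""
    if not sets:
        raise ValueError("no gene sets to write")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            if not gs.members:
                raise ValueError(f"gene set {gs.name!r} has no members")
            fh.write("\t".join((gs.name, gs.description, *gs.members)) + "\n")


def read_tf_targets(path: str | Path, universe: GeneUniverse) -> TFTargetTable:
    """Read a TF-target TSV with header ``tf_id<TAB>gene_id<TAB>score``.

    Rows whose gene is absent from the universe are dropped with a counted
    warning; duplicate (tf, gene) rows keep the maximum score. Non-numeric or
    non-positive scores are errors naming the row.
    """
    targets: dict[str, dict[str, float]] = {}
    n_dropped = 0
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["tf_id", "gene_id", "score"]:
            raise ValueError(
                f"{path}: expected header 'tf_id\\tgene_id\\tscore', got {header!r}"
            )
        for rowno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: row {rowno}: needs 3 columns")
            tf, gene, score_s = fields[0], fields[1], fields[2]
            try:
                score = float(score_s)
            except ValueError:
                raise ValueError(
                    f"{path}: row {rowno}: non-numeric score {score_s!r}"
                ) from None
            if not np.isfinite(score) or score <= 0:
                raise ValueError(
                    f"{path}: row {rowno}: score must be finite and > 0, "
                    f"got {score_s}"
                )
            if gene not in universe:
                n_dropped += 1
                continue
            bucket = targets.setdefault(tf, {})
            if gene in bucket:
                n_dup += 1
                bucket[gene] = max(bucket[gene], score)
            else:
                bucket[gene] = score
    if n_dropped:
        logger.warning(
            "read_tf_targets: dropped %d rows with genes outside the universe",
            n_dropped,
        )
    if n_dup:
        logger.warning(
            "read_tf_targets: %d duplicate (tf, gene) rows resolved to max score",
            n_dup,
        )
    table = TFTargetTable(universe, targets)
    table.n_dropped_rows = n_dropped  # type: ignore[attr-defined]
    return table


def write_tf_targets(table: TFTargetTable, path: str | Path) -> None:
    genes = table.universe.genes
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("tf_id\tgene_id\tscore\n")
        for tf in table.tf_ids:
            idx = table.target_indices(tf)
            sc = table.target_scores(tf)
            for i, s in zip(idx, sc):
                fh.write(f"{tf}\t{genes[i]}\t{float(s)!r}\n")
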