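# Methods

## The permutation test for TF-target enrichment

Let the universe be the set of N background genes a study could have
reported. A TF's evidence is a set of target genes T ⊆ universe with a
positive peak score s(g) per target (units are opaque; only their relative
magnitudes matter). For a query gene set Q of size n (restricted to the
universe before anything else is computed), two statistics are evaluated:

- count: k = |Q ∩ T|
- score: S = Σ_{g ∈ Q ∩ T} s(g)   (non-targets contribute 0)

The sum is used for the score statistic because it is monotone both in
membership and in score magnitude, and it degenerates to the count statistic
when all scores are 1 — a property the tests exploit as an internal
consistency oracle. A mean-based aggregation is deliberately not offered.

The null draws sets of size n uniformly **without replacement** from the
universe. One shared stream of draws (default 10⁶) is evaluated against
every TF: the null law per TF is the same as with independent streams, and
sharing makes the whole screen one sparse-by-dense matrix product per batch
of draws instead of T separate simulations. The only cost is cross-TF
dependence in the Monte-Carlo noise, which affects no per-TF p-value.

The p-value per statistic is the exceedance proportion with ties counted
(#draws ≥ observed)/n_perm, which is super-uniform (valid) under the null.
Two conventions are available:

- `plain` (default): b/n_perm — an observed statistic never reached by any
  draw reports exactly 0, matching how screen outputs are commonly printed;
- `addone`: (b+1)/(n_perm+1) — strictly positive, for downstream consumers
  that cannot accept 0.

When C(N, n) ≤ `enumeration_threshold` (default 100,000) every distinct
draw is enumerated exactly once; p-values are then exact rational
proportions, independent of the seed and of the convention. Because draws
are uniform without replacement, the count statistic is exactly
hypergeometric, which gives an external law to test the sampler against; the
test suite and acceptance script verify the Monte-Carlo count p-value against
the analytic tail within four standard errors on randomized configurations.

Floating-point tie handling: the observed score is computed through the same
sparse-row × matrix path, with identical index ordering, as every null draw,
so a draw equal to the query produces a bit-identical statistic and ties are
counted exactly rather than within a tolerance.

Records are reported sorted by ascending score p-value (ties: count p-value,
then TF id). Score p-values are Bonferroni- and BH-adjusted across the family
of all T TFs in the table; adjusting the count p-values as well is an option
(`adjust_count`), off by default since the score statistic is the primary
readout.

## Overlap statistics

For two sets of sizes nA, nB on a shared universe of N genes with observed
overlap k:

- expected overlap e = nA·nB/N (kept at full precision; reports round to 2
  decimals);
- direction and fold: "over" with fold k/e when k ≥ e (a tie is "over" with
  fold 1.0 by convention), "under" with the reciprocal form e/k when k < e,
  and an overlap of zero is flagged infinitely under-represented rather than
  erroring;
- p-value: the one-sided hypergeometric tail *in the direction of the
  deviation* — P(X ≥ k) for over, P(X ≤ k) for under. Direction is decided
  by comparing k with e, never by the p-value.

The tail is computed as exp(logsumexp of log-pmf terms), each log-pmf built
from three log-gamma binomial terms. Relative accuracy is ~1e-11 or better
down to the smallest normal doubles, verified against exact
integer/Fraction enumeration over every parameter combination with N ≤ 25
and spot-checked at N ≈ 14,000 in the 1e-14 and 1e-33 tail range. Tails that
underflow doubles report 0.0.

`overlap_table` additionally reports the family-wise Bonferroni threshold
α/m for its m rows (display-rounded to 4 decimals), the convention used when
a fixed list of comparisons is screened at a 5% family-wise error rate.
`venn_partition` gives exact region counts for 2–4 sets; counts over all
2^s − 1 membership patterns sum to the union size.

## Multiple-testing corrections

`bonferroni(p, m) = min(1, p·m)` and BH step-up
`adj_(j) = min_{j' ≥ j} min(1, p_(j')·m/j')` over ranks of the ascending
sort, mapped back to input order. The family size m is explicit and may
exceed the number of supplied p-values: the supplied values are then treated
as the m-family's smallest (ranks 1..len), with the unobserved remainder
assumed large enough not to lower any suffix minimum. This is the correct
reconstruction when only the top block of a screen is available, and it is
how the bundled screen blocks (m = 445) are re-adjusted in the tests. Ties
share the larger rank's divisor before the suffix minimum. BH adjusted
values are not idempotent (re-adjusting adjusted values changes them); what
is guaranteed, and tested, is that thresholding adjusted values at α
reproduces the classical step-up rejection set.

## Synthetic data

The generator emulates the structure of a real screen: a fixed universe,
T TFs whose target counts are uniform on a configured range, i.i.d.
log-normal peak scores (location 0, scale 1 by default — positive and
right-skewed, as ChIP peak scores typically are; no empirical score
distribution is claimed), and query sets assembled as
round(f·n) genes sampled from a planted TF's targets with weight
∝ score^b, plus (1−f)·n uniform fillers. The bias b separates score signal
from count signal: at b = 0 the planted genes are typical targets and only
the count statistic is loaded; at b > 0 high-scoring targets are
preferentially planted and the score statistic gains additional power.
Every generator is a pure function of (parameters, seed); outputs are
bitwise reproducible.

Defaults are a fixture profile — universe 5,000, 50 TFs with 500–2,500
targets, 100-gene queries — chosen so the statistical checks (200-replicate
null calibration, 20-replicate recovery) run in seconds while keeping the
target-density regime (targets ≈ 10–50% of the universe) of the full-scale
setting. `SyntheticSpec.full_scale()` switches to the full-size profile:
universe 13,964, 445 TFs, 500–9,000 targets, 45-gene queries.
`scripts/full_scale_smoke.py` runs that profile with 10⁶ draws (a few
minutes on one CPU; ~16 s per 10⁵ draws measured).

What the generator does **not** emulate: correlated target sets between TFs
beyond chance overlap, gene-specific propensities (GC content, gene length,
expression breadth), structured score distributions per TF, or noisy query
membership. Passing the planted-recovery and calibration checks therefore
demonstrates correctness of the statistics under their stated null, not
robustness to those real-data confounders.

## Numerical and design choices

- Draw sampling uses whole-row rejection of duplicate-containing index rows
  when n ≤ N/8 (accepted rows are exactly uniform over distinct draws) and
  random-key top-n selection otherwise; both paths are unit-tested for
  marginal uniformity.
- Identifier matching is exact and case-sensitive; no symbol mapping. Genes
  absent from the declared universe are dropped from TF tables and queries
  (warned, counted), never added: all nulls must condition on one background.
- Duplicate (tf, gene) rows resolve to the maximum score — a gene either is
  a target or is not, and its strongest peak represents it.
- A TF with zero in-universe targets has both statistics identically zero,
  so every draw ties and both p-values are 1.
- Empty queries (after universe restriction) and empty universes are errors,
  not silent no-ops.
- Report rounding: folds 2 decimals, thresholds 4 decimals, p-values
  3-significant-figure scientific; `--precision full` emits full doubles.

## Known limitations

- Peak-to-gene assignment is out of scope: the TF table is consumed as
  given. No BED/narrowPeak parsing, motif scanning, or distance rules.
- The score statistic is a sum; alternatives (mean, rank-weighted) are not
  implemented.
- With the plain convention at n_perm draws the smallest nonzero p-value is
  1/n_perm, and 0 means "below resolution", not zero; use `addone` or raise
  n_perm when exact small p-values matter.
- BH with partial families assumes the unsupplied p-values are large; if the
  supplied block is not actually the family's smallest values the adjustment
  is anti-conservative.
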