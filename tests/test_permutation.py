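import math
from itertools import islice

import numpy as np
import pytest

from tfenrich import (
    GeneSet,
    PermutationConfig,
    TFTargetTable,
    hypergeom_tail,
    make_universe,
    observed_stats,
    permutation_draws,
    rank_report,
    tf_enrichment_test,
)

SAMPLED = PermutationConfig(n_perm=10_000, seed=5, enumeration_threshold=0)


class TestObservedStats:
    def test_intersection_count_and_score_sum(self):
        u = make_universe(6)
        a, b, c, d, e, f = u.genes
        table = TFTargetTable(u, {"tfA": {b: 2.0, c: 3.0, d: 1.0}})
        q = GeneSet("q", "", (a, b, c))
        assert observed_stats(q, table)["tfA"] == (2, 5.0)

    def test_disjoint_query(self, tiny_universe, tiny_table):
        q = GeneSet("q", "", tiny_universe.genes[4:7])
        assert observed_stats(q, tiny_table)["tfA"] == (0, 0.0)

    def test_query_superset_of_targets(self, tiny_universe, tiny_table):
        q = GeneSet("q", "", tiny_universe.genes)
        k, s = observed_stats(q, tiny_table)["tfA"]
        assert k == 4 and s == pytest.approx(4.0)

    def test_off_universe_members_dropped(self, tiny_universe, tiny_table, caplog):
        q = GeneSet("q", "", (tiny_universe.genes[0], "not_a_gene"))
        with caplog.at_level("WARNING"):
            k, _ = observed_stats(q, tiny_table)["tfA"]
        assert k == 1 and "dropped 1" in caplog.text

    def test_fully_off_universe_query_is_error(self, tiny_table):
        q = GeneSet("q", "", ("nope1", "nope2"))
        with pytest.raises(ValueError, match="empty query"):
            observed_stats(q, tiny_table)


class TestPermutationDraws:
    def test_full_size_draw_is_whole_universe(self, tiny_universe):
        cfg = PermutationConfig(n_perm=3, seed=0, enumeration_threshold=0)
        draws = list(islice(permutation_draws(tiny_universe, 10, cfg), 3))
        assert all(d == tiny_universe.genes for d in draws)

    def test_single_gene_frequencies_uniform(self):
        u = make_universe(20)
        n_perm = 20_000
        cfg = PermutationConfig(n_perm=n_perm, seed=11, enumeration_threshold=0)
        counts = {}
        for (g,) in permutation_draws(u, 1, cfg):
            counts[g] = counts.get(g, 0) + 1
        p = 1 / 20
        se = math.sqrt(p * (1 - p) / n_perm)
        for g in u.genes:
            assert abs(counts.get(g, 0) / n_perm - p) < 4 * se

    def test_same_seed_same_stream(self, tiny_universe):
        cfg = PermutationConfig(n_perm=50, seed=123, enumeration_threshold=0)
        a = list(permutation_draws(tiny_universe, 4, cfg))
        b = list(permutation_draws(tiny_universe, 4, cfg))
        assert a == b

    def test_draws_are_distinct_genes(self, tiny_universe):
        cfg = PermutationConfig(n_perm=200, seed=7, enumeration_threshold=0)
        for d in permutation_draws(tiny_universe, 5, cfg):
            assert len(set(d)) == 5

    def test_oversized_draw_rejected(self, tiny_universe):
        cfg = PermutationConfig(n_perm=1, seed=0)
        with pytest.raises(ValueError):
            next(permutation_draws(tiny_universe, 11, cfg))

    def test_dense_draw_path_uniform(self):
        # draw_size > N/8 exercises the random-key path
        u = make_universe(10)
        n_perm = 20_000
        cfg = PermutationConfig(n_perm=n_perm, seed=3, enumeration_threshold=0)
        freq = np.zeros(10)
        for d in permutation_draws(u, 6, cfg):
            for g in d:
                freq[u.index[g]] += 1
        p = 6 / 10
        se = math.sqrt(p * (1 - p) / n_perm)
        assert np.all(np.abs(freq / n_perm - p) < 4 * se)


class TestEnrichmentTest:
    def test_exhaustive_enumeration_matches_counting_oracle(
        self, tiny_universe, tiny_table, tiny_query
    ):
        cfg = PermutationConfig(n_perm=1, seed=0, enumeration_threshold=120)
        (rec,) = tf_enrichment_test(tiny_query, tiny_table, config=cfg)
        assert rec.exhaustive and rec.n_perm == 120
        assert rec.k_observed == 2
        assert rec.p_count == 40 / 120
        # with unit scores the two statistics coincide
        assert rec.p_score == rec.p_count

    def test_exhaustive_p_is_seed_independent(
        self, tiny_universe, tiny_table, tiny_query
    ):
        ps = set()
        for seed in (1, 2, 3):
            cfg = PermutationConfig(n_perm=10, seed=seed, enumeration_threshold=200)
            (rec,) = tf_enrichment_test(tiny_query, tiny_table, config=cfg)
            ps.add((rec.p_count, rec.p_score))
        assert len(ps) == 1

    def test_targets_whole_universe_gives_p_one(self, tiny_universe, tiny_query):
        table = TFTargetTable(
            tiny_universe, {"tfAll": {g: 1.0 for g in tiny_universe.genes}}
        )
        (rec,) = tf_enrichment_test(tiny_query, table, config=SAMPLED)
        assert rec.k_observed == 3
        assert rec.p_count == 1.0 and rec.p_score == 1.0

    def test_zero_target_tf_gives_p_one(self, tiny_universe, tiny_query):
        table = TFTargetTable(
            tiny_universe,
            {"tfA": {tiny_universe.genes[0]: 1.0}, "tfEmpty": {}},
        )
        recs = {r.tf_id: r for r in tf_enrichment_test(tiny_query, table, config=SAMPLED)}
        assert recs["tfEmpty"].p_count == 1.0
        assert recs["tfEmpty"].p_score == 1.0

    def test_unit_scores_make_both_pvalues_equal_in_sampling_mode(
        self, tiny_universe, tiny_table, tiny_query
    ):
        (rec,) = tf_enrichment_test(tiny_query, tiny_table, config=SAMPLED)
        assert rec.p_score == rec.p_count

    def test_sampled_p_count_near_hypergeometric(
        self, tiny_universe, tiny_table, tiny_query
    ):
        (rec,) = tf_enrichment_test(tiny_query, tiny_table, config=SAMPLED)
        exact = hypergeom_tail(10, 4, 3, 2, "over")
        se = math.sqrt(exact * (1 - exact) / SAMPLED.n_perm)
        assert abs(rec.p_count - exact) < 4 * se

    def test_addone_convention(self, tiny_universe, tiny_table, tiny_query):
        plain = tf_enrichment_test(tiny_query, tiny_table, config=SAMPLED)[0]
        addone = tf_enrichment_test(
            tiny_query,
            tiny_table,
            config=PermutationConfig(
                n_perm=10_000, seed=5, enumeration_threshold=0,
                p_value_convention="addone",
            ),
        )[0]
        b = round(plain.p_count * plain.n_perm)
        assert addone.p_count == pytest.approx((b + 1) / (plain.n_perm + 1))
        assert addone.p_count > 0

    def test_adding_nontargets_keeps_stats_and_never_lowers_p(
        self, tiny_universe, tiny_table
    ):
        genes = tiny_universe.genes
        cfg = PermutationConfig(n_perm=1, seed=0, enumeration_threshold=10**6)
        q1 = GeneSet("q1", "", (genes[0], genes[1], genes[9]))
        (r1,) = tf_enrichment_test(q1, tiny_table, config=cfg)
        q2 = GeneSet("q2", "", (genes[0], genes[1], genes[9], genes[8]))
        (r2,) = tf_enrichment_test(q2, tiny_table, config=cfg)
        assert r2.k_observed == r1.k_observed
        assert r2.score_observed == r1.score_observed
        assert r2.p_count >= r1.p_count
        assert r2.p_score >= r1.p_score

    def test_adjusted_pvalues_dominate_raw(self, tiny_universe, tiny_query):
        rng = np.random.default_rng(0)
        table = TFTargetTable(
            tiny_universe,
            {
                f"tf{i}": {
                    g: float(s)
                    for g, s in zip(
                        rng.choice(tiny_universe.genes, 5, replace=False),
                        rng.lognormal(size=5),
                    )
                }
                for i in range(8)
            },
        )
        for rec in tf_enrichment_test(tiny_query, table, config=SAMPLED):
            assert rec.p_score_bonferroni >= rec.p_score
            assert rec.p_score_bh >= rec.p_score
            assert rec.p_score_bonferroni >= rec.p_score_bh - 1e-15

    def test_score_zero_iff_count_zero(self, tiny_universe, tiny_table):
        q = GeneSet("q", "", tiny_universe.genes[5:8])
        (rec,) = tf_enrichment_test(q, tiny_table, config=SAMPLED)
        assert rec.k_observed == 0 and rec.score_observed == 0.0

    def test_mismatched_universe_rejected(self, tiny_table, tiny_query):
        other = make_universe(12)
        with pytest.raises(ValueError, match="universe"):
            tf_enrichment_test(tiny_query, tiny_table, universe=other, config=SAMPLED)


class TestRankReport:
    def _record(self, tf, p_score, p_count):
        from tfenrich.permutation import TFEnrichmentRecord

        return TFEnrichmentRecord(
            tf_id=tf,
            n_targets_total=10,
            k_observed=1,
            score_observed=1.0,
            p_count=p_count,
            p_score=p_score,
            p_score_bh=p_score,
            p_score_bonferroni=p_score,
            n_perm=100,
            seed=0,
        )

    def test_sorted_by_score_p(self):
        df = rank_report([self._record("a", 0.01, 0.5), self._record("b", 0.001, 0.5)])
        assert df["tf"].tolist() == ["b", "a"]

    def test_tie_broken_by_count_p_then_tf(self):
        df = rank_report(
            [
                self._record("z", 0.01, 0.2),
                self._record("a", 0.01, 0.1),
                self._record("b", 0.01, 0.1),
            ]
        )
        assert df["tf"].tolist() == ["a", "b", "z"]

    def test_single_record_columns(self):
        df = rank_report([self._record("a", 0.5, 0.5)])
        assert df.columns.tolist() == [
            "tf",
            "total_tf_genes",
            "tf_genes_in_set",
            "score_in_set",
            "number_p",
            "score_p",
            "bh_corrected_p",
            "bonferroni_corrected_p",
            "n_perm",
            "seed",
        ]
        assert len(df) == 1

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            rank_report([])
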