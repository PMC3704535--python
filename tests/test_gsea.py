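import itertools

import numpy as np
import pandas as pd
import pytest

import subtypelink as sl
from subtypelink.gsea import _batch_es, metric_for_scale
from conftest import brute_force_walk_es


def _frame(rows, samples):
    return pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))], columns=samples
    )


class TestMetrics:
    def test_equal_classes_give_zero(self):
        values = _frame([[3.0, 3.0, 3.0, 3.0]], ["a", "b", "c", "d"])
        m = sl.signal_to_noise(values, [True, True, False, False])
        assert m.iloc[0] == 0.0

    def test_floor_engages_on_constant_classes(self):
        # A=[2,2], B=[1,1]: sd floors 0.2*|mu| give (2-1)/(0.4+0.2)
        values = _frame([[2.0, 2.0, 1.0, 1.0]], ["a", "b", "c", "d"])
        m = sl.signal_to_noise(values, [True, True, False, False])
        assert m.iloc[0] == pytest.approx(1.0 / 0.6)

    def test_all_zero_gene_uses_absolute_floor(self):
        values = _frame([[0.0, 0.0, 0.0, 0.0]], ["a", "b", "c", "d"])
        m = sl.signal_to_noise(values, [True, True, False, False])
        assert m.iloc[0] == 0.0  # 0/(0.2+0.2)

    def test_label_swap_negates_signal_to_noise(self):
        rng = np.random.default_rng(0)
        values = _frame(rng.normal(8, 1, size=(10, 6)).tolist(),
                        [f"s{i}" for i in range(6)])
        mask = np.array([True, True, True, False, False, False])
        a = sl.signal_to_noise(values, mask)
        b = sl.signal_to_noise(values, ~mask)
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_class_mean_difference(self):
        values = _frame([[1.0, 3.0, 0.0, 2.0]], ["a", "b", "c", "d"])
        m = sl.class_mean_difference(values, [True, True, False, False])
        assert m.iloc[0] == pytest.approx(1.0)
        swapped = sl.class_mean_difference(values, [False, False, True, True])
        assert swapped.iloc[0] == pytest.approx(-1.0)

    def test_scale_dialect_picks_the_metric(self):
        assert metric_for_scale("absolute") == "s2n"
        assert metric_for_scale("log_ratio") == "mean_diff"


class TestEnrichmentScore:
    def test_top_gene_unweighted(self):
        ranked = sl.RankedList(
            np.array(["g1", "g2", "g3", "g4"]), np.array([4.0, 3.0, 2.0, 1.0])
        )
        es, running = sl.enrichment_score(ranked, {"g1"}, weight_p=0.0)
        assert es == pytest.approx(1.0)
        np.testing.assert_allclose(
            running, [1.0, 1 - 1 / 3, 1 - 2 / 3, 0.0], atol=1e-12
        )

    def test_bottom_gene_unweighted_mirrored(self):
        ranked = sl.RankedList(
            np.array(["g1", "g2", "g3", "g4"]), np.array([4.0, 3.0, 2.0, 1.0])
        )
        es, _ = sl.enrichment_score(ranked, {"g4"}, weight_p=0.0)
        assert es == pytest.approx(-1.0)

    def test_unweighted_es_ignores_metric_magnitudes(self):
        ids = np.array(["g1", "g2", "g3", "g4", "g5"])
        a = sl.RankedList(ids, np.array([9.0, 5.0, 1.0, 0.5, 0.1]))
        b = sl.RankedList(ids, np.array([100.0, 4.0, 3.0, 2.0, 1.0]))
        for genes in ({"g2", "g4"}, {"g1"}, {"g3", "g5"}):
            assert sl.enrichment_score(a, genes, 0.0)[0] == pytest.approx(
                sl.enrichment_score(b, genes, 0.0)[0]
            )

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    def test_exhaustive_subsets_match_brute_force(self, weight_p):
        rng = np.random.default_rng(4)
        n = 7
        ids = np.array([f"g{i}" for i in range(n)])
        metric = np.round(rng.normal(size=n), 1)
        ranked = sl.rank_genes(pd.Series(metric, index=ids))
        for r in range(1, n):
            for combo in itertools.combinations(ids, r):
                es, _ = sl.enrichment_score(ranked, set(combo), weight_p)
                hit = [g in combo for g in ranked.gene_ids]
                want = brute_force_walk_es(list(ranked.metric), hit, weight_p)
                assert es == pytest.approx(want, abs=1e-12), (combo, weight_p)

    def test_batch_kernel_agrees_with_single_walk(self):
        rng = np.random.default_rng(5)
        n = 30
        ids = np.array([f"g{i:02d}" for i in range(n)])
        for _ in range(50):
            metric = np.round(rng.normal(size=n), 1)
            ranked = sl.rank_genes(pd.Series(metric, index=ids))
            k = int(rng.integers(1, n - 1))
            genes = frozenset(rng.choice(ids, size=k, replace=False))
            order = np.lexsort((ids, -metric))
            inv = np.argsort(order, kind="stable")[:, None]
            idx = np.nonzero(np.isin(ids, sorted(genes)))[0]
            for p in (0.0, 0.25, 1.0):
                es1, _ = sl.enrichment_score(ranked, genes, p)
                es2 = _batch_es(inv, metric[:, None], idx, p)[0]
                assert es1 == pytest.approx(es2, abs=1e-9)

    def test_whole_universe_is_degenerate(self):
        ranked = sl.RankedList(np.array(["g1", "g2"]), np.array([2.0, 1.0]))
        with pytest.raises(sl.DegenerateSetError):
            sl.enrichment_score(ranked, {"g1", "g2"})


def _small_cohort(seed=0, planted=None, scale="absolute", n_genes=120,
                  per_class=(10, 20)):
    """Cohort with two subtypes; optionally shift `planted` genes in 'a'."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    n = sum(per_class)
    base = 8.0 if scale == "absolute" else 0.0
    X = rng.normal(base, 1.0, size=(n_genes, n))
    samples = [f"s{i:02d}" for i in range(n)]
    labels = {
        s: ("a" if i < per_class[0] else "b") for i, s in enumerate(samples)
    }
    if planted:
        idx = [genes.index(g) for g in planted]
        X[np.ix_(idx, range(per_class[0]))] += 1.5
    return sl.ExpressionCohort(
        "small", pd.DataFrame(X, index=genes, columns=samples), labels,
        scale=scale,
    )


class TestPermutationTest:
    def test_identical_seed_reproduces_identical_tables(self):
        cohort = _small_cohort(seed=1)
        collection = sl.GeneSetCollection(
            {f"S{i}": frozenset(f"g{j:03d}" for j in range(i * 10, i * 10 + 8))
             for i in range(5)}
        )
        a = sl.permutation_test(cohort, "a", collection, n_perm=100, seed=3)
        b = sl.permutation_test(cohort, "a", collection, n_perm=100, seed=3)
        pd.testing.assert_frame_equal(a, b)
        c = sl.permutation_test(cohort, "a", collection, n_perm=100, seed=4)
        assert not np.allclose(a.p_nominal, c.p_nominal)

    def test_planted_set_detected_with_direction(self):
        planted = [f"g{j:03d}" for j in range(20)]
        cohort = _small_cohort(seed=2, planted=planted)
        sets = {"PLANTED": frozenset(planted)}
        sets.update(
            {f"S{i}": frozenset(f"g{j:03d}" for j in range(i * 10 + 30, i * 10 + 40))
             for i in range(5)}
        )
        table = sl.permutation_test(
            cohort, "a", sl.GeneSetCollection(sets), n_perm=200, seed=0
        )
        row = table[table.set_name == "PLANTED"].iloc[0]
        assert row.direction == "up"
        assert row.fdr_q < 0.25
        assert row.es > 0

    def test_small_subtype_is_skipped(self):
        cohort = _small_cohort(seed=3, per_class=(2, 28))
        collection = sl.GeneSetCollection(
            {"S": frozenset(f"g{j:03d}" for j in range(10))}
        )
        assert sl.permutation_test(cohort, "a", collection, n_perm=100) is None

    def test_log_ratio_cohort_uses_mean_difference(self):
        planted = [f"g{j:03d}" for j in range(15)]
        cohort = _small_cohort(seed=4, planted=planted, scale="log_ratio")
        sets = {"PLANTED": frozenset(planted),
                "OTHER": frozenset(f"g{j:03d}" for j in range(40, 52))}
        table = sl.permutation_test(
            cohort, "a", sl.GeneSetCollection(sets), n_perm=200, seed=0
        )
        row = table[table.set_name == "PLANTED"].iloc[0]
        assert row.direction == "up" and row.fdr_q < 0.25


class TestRetention:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["cohort_id", "subtype", "set_name", "es", "nes",
                     "p_nominal", "fdr_q", "direction"],
        )

    def test_set_significant_in_one_subtype_is_retained(self):
        table = self._table(
            [
                ("c", "a", "S1", 0.5, 1.5, 0.1, 0.30, "up"),
                ("c", "b", "S1", 0.4, 1.2, 0.2, 0.24, "up"),
            ]
        )
        kept = sl.retain_significant(table, 0.25)
        assert set(kept.set_name) == {"S1"}

    def test_boundary_q_is_dropped_strictly(self):
        table = self._table([("c", "a", "S1", 0.5, 1.5, 0.1, 0.25, "up")])
        assert sl.retain_significant(table, 0.25).empty

    def test_empty_table_passes_through(self):
        assert sl.retain_significant(self._table([])).empty


class TestRecurrence:
    def _filtered(self):
        rows = [
            ("c1", "a", "S1", 0.5, 1.5, 0.0, 0.01, "up"),
            ("c1", "b", "S1", 0.5, 1.5, 0.0, 0.01, "up"),
            ("c2", "a", "S1", -0.5, -1.5, 0.0, 0.01, "down"),
            ("c1", "a", "S2", 0.5, 1.5, 0.0, 0.01, "up"),
            ("c1", "b", "S2", 0.5, 1.5, 0.0, 0.02, "up"),
            ("c2", "a", "S3", 0.5, 1.5, 0.0, 0.01, "up"),
            ("c3", "a", "S3", 0.5, 1.5, 0.0, 0.01, "up"),
            ("c4", "a", "S3", 0.5, 1.5, 0.0, 0.01, "up"),
            ("c5", "a", "S3", 0.5, 1.5, 0.0, 0.01, "up"),
            ("c6", "a", "S3", 0.5, 1.5, 0.0, 0.01, "up"),
        ]
        return pd.DataFrame(
            rows,
            columns=["cohort_id", "subtype", "set_name", "es", "nes",
                     "p_nominal", "fdr_q", "direction"],
        )

    TISSUES = {"c1": "breast", "c2": "ovary", "c3": "liver",
               "c4": "lung", "c5": "brain", "c6": "npc"}

    def test_classification_rules(self):
        rec = sl.tabulate_recurrence(self._filtered(), self.TISSUES)
        rec = rec.set_index("set_name")
        # S2: 2 subtypes of one tissue -> tissue-specific
        assert rec.loc["S2", "class"] == "tissue_specific"
        assert rec.loc["S2", "n_tissues"] == 1
        # S1: 2 tissues -> intermediate
        assert rec.loc["S1", "class"] == "intermediate"
        assert rec.loc["S1", "n_subtypes"] == 3
        # S3: 5 tissues -> common
        assert rec.loc["S3", "class"] == "common"

    def test_most_recurrent_set_has_max_subtype_count(self):
        rec = sl.tabulate_recurrence(self._filtered(), self.TISSUES)
        top = rec.sort_values("n_subtypes", ascending=False).iloc[0]
        assert top.set_name == "S3" and top.n_subtypes == 5

    def test_unmapped_cohort_is_config_error(self):
        with pytest.raises(sl.ConfigError, match="c6"):
            sl.tabulate_recurrence(
                self._filtered(), {k: v for k, v in self.TISSUES.items()
                                   if k != "c6"}
            )
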