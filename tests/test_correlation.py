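import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import subtypelink as sl


def _pure_python_spearman(x, y):
    """Independent oracle: average ranks by hand, then the Pearson formula."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    return num / (dx * dy)


class TestSpearmanRho:
    def test_identical_vectors(self):
        assert sl.spearman_rho([1, 5, 3], [1, 5, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_reversed_vector(self):
        assert sl.spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(
            -1.0, abs=1e-12
        )

    def test_textbook_value(self):
        # n=4, sum of squared rank differences = 2:
        # 1 - 6*2/(4*15) = 0.8
        assert sl.spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(sl.UndefinedCorrelationError):
            sl.spearman_rho([1.0, 1.0, 1.0], [1, 2, 3])

    def test_matches_rank_formula_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(3, 21))
            x = np.round(rng.normal(size=n), 1)  # rounding forces ties
            y = np.round(rng.normal(size=n), 1)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert sl.spearman_rho(x, y) == pytest.approx(
                _pure_python_spearman(x, y), abs=1e-12
            )

    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        base = sl.spearman_rho(x, y)
        assert sl.spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert sl.spearman_rho(x, 3 * y + 7) == pytest.approx(base, abs=1e-12)


def _cohort(cid, values, labels):
    return sl.ExpressionCohort(
        cid,
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=list(labels),
        ),
        labels,
    )


class TestCrossCohortCorrelation:
    def test_self_map_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        labels = {f"s{i}": ("a" if i < 2 else "b") for i in range(4)}
        cohort = _cohort("c", rng.normal(size=(6, 4)), labels)
        cmap = sl.cross_cohort_correlation(cohort, cohort)
        rho = cmap.rho.to_numpy()
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0, atol=1e-12)

    def test_equal_sample_across_cohorts_has_rho_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 4))
        labels_a = {f"a{i}": ("x" if i < 2 else "y") for i in range(4)}
        labels_b = {f"b{i}": ("x" if i < 2 else "y") for i in range(4)}
        Y = rng.normal(size=(5, 4))
        Y[:, 0] = X[:, 0]
        a = _cohort("A", X, labels_a)
        b = _cohort("B", Y, labels_b)
        cmap = sl.cross_cohort_correlation(a, b)
        assert cmap.rho.loc["a0", "b0"] == pytest.approx(1.0)

    def test_matrix_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        labels_a = {f"a{i}": ("x" if i < 2 else "y") for i in range(4)}
        labels_b = {f"b{i}": ("x" if i < 2 else "y") for i in range(4)}
        a = _cohort("A", rng.normal(size=(5, 4)), labels_a)
        b = _cohort("B", rng.normal(size=(5, 4)), labels_b)
        cmap = sl.cross_cohort_correlation(a, b)
        for sa in cmap.rho.index:
            for sb in cmap.rho.columns:
                want = stats.spearmanr(
                    a.values[sa].to_numpy(), b.values[sb].to_numpy()
                ).statistic
                assert cmap.rho.loc[sa, sb] == pytest.approx(want, abs=1e-12)

    def test_too_few_common_features_is_error(self):
        labels = {f"s{i}": "a" for i in range(3)}
        a = _cohort("A", np.random.default_rng(0).normal(size=(5, 3)), labels)
        b = _cohort("B", np.random.default_rng(1).normal(size=(5, 3)), labels)
        with pytest.raises(sl.PipelineError, match="common features"):
            sl.cross_cohort_correlation(a, b, common_genes=["g0", "g1"])


class TestSubtypeMedian:
    def test_median_of_cross_pairs(self):
        # crafted map: one subtype per cohort, cross rho {0.1, 0.2, 0.3}
        labels = {"A": {"a0": "s", "a1": "s"}, "B": {f"b{i}": "t" for i in range(3)}}
        # self maps so every cohort pair is available
        self_a = sl.CorrelationMap(
            "A", "A",
            pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a0", "a1"],
                         columns=["a0", "a1"]),
            "transcriptional", ["s", "s"], ["s", "s"],
        )
        b_ids = ["b0", "b1", "b2"]
        self_b = sl.CorrelationMap(
            "B", "B",
            pd.DataFrame(np.eye(3), index=b_ids, columns=b_ids),
            "transcriptional", ["t"] * 3, ["t"] * 3,
        )
        # the A-B map needs every sample of A
        full = pd.DataFrame(
            [[0.1, 0.2, 0.3], [0.1, 0.2, 0.3]],
            index=["a0", "a1"], columns=["b0", "b1", "b2"],
        )
        cmap = sl.CorrelationMap("A", "B", full, "transcriptional",
                                 ["s", "s"], ["t"] * 3)
        sim = sl.subtype_median_correlation(
            {("A", "A"): self_a, ("A", "B"): cmap, ("B", "B"): self_b}, labels
        )
        frame = sim.to_frame()
        assert frame.loc["A.s", "B.t"] == pytest.approx(0.2)
        # within-subtype diagonal excludes self pairs: median of {0.5}
        assert frame.loc["A.s", "A.s"] == pytest.approx(0.5)

    def test_even_pair_count_median(self):
        full = pd.DataFrame(
            [[0.1, 0.3], [0.1, 0.3]], index=["a0", "a1"], columns=["b0", "b1"]
        )
        cmap = sl.CorrelationMap("A", "B", full, "transcriptional",
                                 ["s", "s"], ["t", "t"])
        eye2 = pd.DataFrame(np.eye(2), index=["a0", "a1"], columns=["a0", "a1"])
        eyeb = pd.DataFrame(np.eye(2), index=["b0", "b1"], columns=["b0", "b1"])
        maps = {
            ("A", "A"): sl.CorrelationMap("A", "A", eye2, "transcriptional",
                                          ["s"] * 2, ["s"] * 2),
            ("B", "B"): sl.CorrelationMap("B", "B", eyeb, "transcriptional",
                                          ["t"] * 2, ["t"] * 2),
            ("A", "B"): cmap,
        }
        labels = {"A": {"a0": "s", "a1": "s"}, "B": {"b0": "t", "b1": "t"}}
        sim = sl.subtype_median_correlation(maps, labels)
        assert sim.to_frame().loc["A.s", "B.t"] == pytest.approx(0.2)

    def test_profile_kinds_agree_on_planted_structure(self):
        # transcriptional and pathway similarity matrices should associate
        # positively on data with planted shared programs
        design = sl.default_design(seed=0, n_genes=600, n_samples=30,
                                   module_size=30)
        cohorts, _ = sl.generate_cohorts(design)
        collection = sl.generate_gene_sets(design, n_decoys=15, set_size=30)
        centered = [sl.median_center_genes(c) for c in cohorts]
        idx = sl.intersect_genes(centered, min_common=100)
        profiles = {
            c.cohort_id: sl.pathway_profile(c, collection) for c in centered
        }
        sim_t = sl.subtype_similarity(
            centered, "transcriptional", common_genes=idx.genes
        )
        sim_p = sl.subtype_similarity(centered, "pathway", profiles=profiles)
        rho = stats.spearmanr(
            sim_t.upper_triangle(), sim_p.upper_triangle()
        ).statistic
        assert rho > 0
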