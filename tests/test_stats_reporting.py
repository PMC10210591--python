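"""Group tests, correlation-distance clustering, PCA."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from gliascan.stats_reporting import (
    correlation_distance,
    dendrogram_to_newick,
    group_compare,
    hcluster,
    mann_whitney,
    pca,
    welch_t,
)


class TestMannWhitney:
    def test_exact_enumeration_small_case(self):
        # a=[1,2], b=[3,4]: U=0; 2 of the 6 assignments are as extreme
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_central_u_and_p_one(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)  # n_a*n_b/2 with midrank ties
        assert p == 1.0

    def test_asymptotic_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(0.8, 1.0, 12)
        u, p = mann_whitney(a, b)
        # permutation oracle on the U statistic
        from scipy.stats import rankdata

        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        na, m = len(a), len(a) * len(b)
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)[:, :na]
        u_perm = ranks[idx].sum(axis=1) - na * (na + 1) / 2
        p_perm = np.mean(np.abs(u_perm - m / 2) >= abs(u - m / 2) - 1e-9)
        assert p == pytest.approx(p_perm, abs=0.01)


class TestWelchT:
    def test_equal_groups_give_zero(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_textbook_case_matches_reference(self):
        # classic two-sample data; oracle: scipy's Welch implementation
        from scipy.stats import ttest_ind

        a = [27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6]
        b = [27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2]
        t, df, p = welch_t(a, b)
        ref = ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-6)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_constant_differing_groups_degenerate(self):
        t, df, p = welch_t([5.0, 5.0, 5.0], [7.0, 7.0, 7.0])
        assert abs(t) > 1e5 and p < 1e-6


class TestGroupCompare:
    def test_selects_tests_and_adds_bh_column(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "normal_var": rng.normal(10, 1, 12),
                "skewed_var": rng.exponential(1, 12) ** 3,
            },
            index=[f"g{i}" for i in range(12)],
        )
        groups = pd.Series(
            ["Y"] * 6 + ["N"] * 6, index=table.index
        )
        out = group_compare(table, groups)
        assert set(out["test"]) <= {"t", "mann-whitney"}
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()
        assert (out["p_bh"] >= out["p_value"] - 1e-12).all()


class TestCorrelationDistance:
    def test_self_distance_zero_anticorrelated_two(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [3.0, 2.0, 1.0]})
        d, flagged = correlation_distance(df)
        assert d.loc["x", "x"] == 0.0
        assert d.loc["x", "y"] == pytest.approx(2.0)
        assert flagged == []

    def test_matches_numpy_oracle(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        d, _ = correlation_distance(df, method="pearson")
        ref = 1.0 - np.corrcoef(df.to_numpy(), rowvar=False)
        assert np.allclose(d.to_numpy(), ref, atol=1e-12)

    def test_zero_variance_column_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        _, flagged = correlation_distance(df)
        assert flagged == ["flat"]


class TestHCluster:
    def test_two_points_single_merge(self):
        d = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]], index=list("ab"), columns=list("ab"))
        z = hcluster(d)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.7)

    def test_close_pair_merges_first(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        z = hcluster(d)
        assert sorted(z[0, :2]) == [0, 1]

    def test_ultrametric_recovered_exactly(self):
        # ((a,b):0.2,(c,d):0.5) as an ultrametric distance matrix
        m = np.array(
            [
                [0.0, 0.2, 0.5, 0.5],
                [0.2, 0.0, 0.5, 0.5],
                [0.5, 0.5, 0.0, 0.3],
                [0.5, 0.5, 0.3, 0.0],
            ]
        )
        d = pd.DataFrame(m, index=list("abcd"), columns=list("abcd"))
        z = hcluster(d, linkage="complete")
        assert sorted(np.round(z[:, 2], 10)) == [0.2, 0.3, 0.5]

    def test_newick_export_parses(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        newick = dendrogram_to_newick(hcluster(d), list("abc"))
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert {leaf.name for leaf in tree.get_terminals()} == set("abc")


class TestPCA:
    def test_rank_one_data_has_single_component(self):
        base = np.arange(6, dtype=float)
        df = pd.DataFrame({"a": base, "b": 2 * base, "c": -base})
        res = pca(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(15, 5)))
        res = pca(df)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        res = pca(df)
        # oracle: eigenvalues of the correlation matrix
        z = (df - df.mean()) / df.std(ddof=0)
        eigvals = np.sort(np.linalg.eigvalsh(z.T @ z))[::-1]
        assert np.allclose(
            res.explained_variance_ratio, eigvals / eigvals.sum(), atol=1e-10
        )

    def test_zero_variance_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0],
                           "c": [2.0, 1.0, 2.0]})
        res = pca(df)
        assert res.dropped_columns == ["b"]
        assert "b" not in res.loadings.index
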