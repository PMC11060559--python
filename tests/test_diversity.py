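"""Normalization, diversity indices, ordination and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mosvirome import (
    CountMatrix, DissimilarityMatrix,
    alpha_diversity, beta_dissimilarity, group_test, kruskal_wallis_test,
    mann_whitney_test, mean_between_group_dissimilarity, nmds, permanova,
    rarefaction_curve, spearman_association, tss_normalize,
)
from conftest import random_count_matrix


def rel_from(arr, libs=None):
    df = pd.DataFrame(np.asarray(arr, dtype=np.int64))
    df.columns = libs or [f"L{j}" for j in range(df.shape[1])]
    df.index = [f"t{i}" for i in range(df.shape[0])]
    return tss_normalize(CountMatrix(df))


class TestTss:
    def test_simple_column(self):
        rel = rel_from([[2], [3], [5]])
        assert list(rel.data.iloc[:, 0]) == pytest.approx([0.2, 0.3, 0.5])

    def test_zero_library_flagged(self):
        rel = rel_from([[0, 5], [0, 5]])
        assert rel.zero_libraries == ["L0"]
        assert (rel.data["L0"] == 0).all()

    def test_columns_sum_to_one(self, rng):
        rel = tss_normalize(random_count_matrix(rng, 30, 8))
        sums = rel.data.sum(axis=0)
        for lib in rel.libraries:
            if lib not in rel.zero_libraries:
                assert sums[lib] == pytest.approx(1.0, abs=1e-9)


class TestAlpha:
    def test_uniform_four_taxa(self):
        rel = rel_from([[10], [10], [10], [10]])
        row = alpha_diversity(rel).iloc[0]
        assert row["richness"] == 4
        assert row["shannon"] == pytest.approx(np.log(4), abs=1e-12)
        assert row["simpson"] == pytest.approx(0.75, abs=1e-12)

    def test_single_taxon(self):
        rel = rel_from([[10], [0]])
        row = alpha_diversity(rel).iloc[0]
        assert row["richness"] == 1 and row["shannon"] == 0 and row["simpson"] == 0

    def test_matches_direct_summation(self, rng):
        rel = tss_normalize(random_count_matrix(rng, 25, 5))
        table = alpha_diversity(rel)
        for lib in rel.libraries:
            p = rel.data[lib].to_numpy()
            p = p[p > 0]
            assert table.loc[lib, "shannon"] == pytest.approx(
                -sum(pi * np.log(pi) for pi in p), abs=1e-12)
            assert table.loc[lib, "simpson"] == pytest.approx(
                1 - sum(pi ** 2 for pi in p), abs=1e-12)


class TestBeta:
    def test_identical_columns_zero(self):
        rel = rel_from([[5, 5], [3, 3]])
        for metric in ("sorensen", "bray_curtis"):
            assert beta_dissimilarity(rel, metric).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        rel = rel_from([[5, 0], [0, 3]])
        for metric in ("sorensen", "bray_curtis"):
            assert beta_dissimilarity(rel, metric).values[0, 1] == pytest.approx(1.0)

    def test_sorensen_is_bray_curtis_on_binarized(self, rng):
        from mosvirome import RelAbundanceMatrix
        for _ in range(20):
            cm = random_count_matrix(rng, 15, 6)
            sor = beta_dissimilarity(tss_normalize(cm), "sorensen")
            binary = RelAbundanceMatrix((cm.data > 0).astype(float))
            bc_bin = beta_dissimilarity(binary, "bray_curtis")
            assert np.allclose(sor.values, bc_bin.values, atol=1e-12)

    def test_matrix_invariants(self, rng):
        D = beta_dissimilarity(tss_normalize(random_count_matrix(rng, 20, 9)))
        v = D.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0)
        assert v.min() >= 0 and v.max() <= 1

    def test_all_zero_pair_defined_as_zero(self):
        rel = rel_from([[0, 0, 4], [0, 0, 6]])
        D = beta_dissimilarity(rel, "bray_curtis")
        assert D.values[0, 1] == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.lists(st.integers(min_value=0, max_value=500), min_size=3, max_size=3),
        min_size=2, max_size=8))
    def test_property_sorensen_identity_on_arbitrary_counts(self, rows):
        """(b+c)/(2a+b+c) == Bray-Curtis of the binarized table, always."""
        from mosvirome import RelAbundanceMatrix
        rel = rel_from(rows)
        sor = beta_dissimilarity(rel, "sorensen").values
        bc_bin = beta_dissimilarity(
            RelAbundanceMatrix((rel.data > 0).astype(float)), "bray_curtis").values
        assert np.allclose(sor, bc_bin, atol=1e-12)
        assert np.allclose(sor, sor.T) and sor.min() >= 0 and sor.max() <= 1


class TestBetweenGroupMean:
    def test_hand_built_two_plus_two(self):
        ids = ["a1", "a2", "b1", "b2"]
        v = np.zeros((4, 4))
        pairs = {(0, 2): 0.4, (0, 3): 0.6, (1, 2): 0.8, (1, 3): 0.2,
                 (0, 1): 0.99, (2, 3): 0.97}
        for (i, j), d in pairs.items():
            v[i, j] = v[j, i] = d
        D = DissimilarityMatrix(v, ids, "bray_curtis")
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert mean_between_group_dissimilarity(D, groups) == pytest.approx(
            (0.4 + 0.6 + 0.8 + 0.2) / 4)

    def test_single_group_errors(self):
        D = DissimilarityMatrix(np.zeros((2, 2)), ["x", "y"], "sorensen")
        with pytest.raises(ValueError):
            mean_between_group_dissimilarity(D, {"x": "A", "y": "A"})

    def test_matches_pair_enumeration(self, rng):
        n = 8
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        v /= max(1.0, v.max())
        ids = [f"L{i}" for i in range(n)]
        labels = {i: ("A" if k < 3 else "B" if k < 6 else "C")
                  for k, i in enumerate(ids)}
        D = DissimilarityMatrix(v, ids, "bray_curtis")
        expected = np.mean([v[i, j] for i in range(n) for j in range(i + 1, n)
                            if labels[ids[i]] != labels[ids[j]]])
        assert mean_between_group_dissimilarity(D, labels) == pytest.approx(expected)


def _toy_distance(rng, n):
    pts = rng.random((n, 2))
    from scipy.spatial.distance import pdist, squareform
    v = squareform(pdist(pts))
    v /= v.max() * 1.01
    return DissimilarityMatrix(v, [f"L{i}" for i in range(n)], "bray_curtis")


class TestPermanova:
    def test_one_factor_pseudo_f_matches_brute_force(self, rng):
        D = _toy_distance(rng, 6)
        design = pd.DataFrame({"grp": ["x", "x", "x", "y", "y", "y"]},
                              index=D.ids)
        res = permanova(D, design, ["grp"], n_perm=99, seed=1)
        # brute force (Anderson 2001): SS_total and SS_within from raw distances
        d = D.values
        n = 6
        ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for members in ([0, 1, 2], [3, 4, 5]):
            m = len(members)
            ss_within += sum(d[i, j] ** 2 for i in members for j in members
                             if i < j) / m
        ss_among = ss_total - ss_within
        f_expected = (ss_among / 1) / (ss_within / 4)
        assert res.table.loc["grp", "pseudo_F"] == pytest.approx(f_expected, rel=1e-9)
        assert res.table.loc["grp", "sum_sq"] == pytest.approx(ss_among, rel=1e-9)

    def test_one_factor_matches_skbio(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova
        D = _toy_distance(rng, 9)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        design = pd.DataFrame({"grp": labels}, index=D.ids)
        mine = permanova(D, design, ["grp"], n_perm=99, seed=0)
        theirs = skbio_permanova(SkbioDM(D.values, ids=D.ids),
                                 grouping=labels, permutations=0)
        assert mine.table.loc["grp", "pseudo_F"] == pytest.approx(
            float(theirs["test statistic"]), rel=1e-9)

    def test_saturated_separation_floors_p(self, rng):
        # groups large enough that a random permutation essentially never
        # reproduces the exact partition (which would tie with F_obs)
        pts = np.vstack([rng.normal(0, 0.01, (8, 2)),
                         rng.normal(10, 0.01, (8, 2))])
        from scipy.spatial.distance import pdist, squareform
        v = squareform(pdist(pts))
        v /= v.max() * 1.01
        D = DissimilarityMatrix(v, [f"L{i}" for i in range(16)], "bray_curtis")
        design = pd.DataFrame({"grp": ["a"] * 8 + ["b"] * 8}, index=D.ids)
        res = permanova(D, design, ["grp"], n_perm=199, seed=3)
        assert res.table.loc["grp", "p_value"] == pytest.approx(1 / 200)

    def test_r_squared_partitions_to_one(self, rng):
        D = _toy_distance(rng, 12)
        design = pd.DataFrame({
            "grp": ["a", "b"] * 6,
            "site": ["s1"] * 4 + ["s2"] * 4 + ["s3"] * 4}, index=D.ids)
        res = permanova(D, design, ["grp", "site"], n_perm=99, seed=0)
        r2 = res.table.drop(index="Total")["R2"].sum()
        assert r2 == pytest.approx(1.0, abs=1e-9)
        p = res.table.loc["grp", "p_value"]
        assert 1 / 100 <= p <= 1

    def test_constant_factor_rejected(self, rng):
        D = _toy_distance(rng, 6)
        design = pd.DataFrame({"grp": ["x"] * 6}, index=D.ids)
        with pytest.raises(ValueError, match="constant"):
            permanova(D, design, ["grp"], n_perm=99, seed=0)

    def test_aliased_term_rejected(self, rng):
        D = _toy_distance(rng, 6)
        design = pd.DataFrame({"grp": ["x", "x", "x", "y", "y", "y"],
                               "dup": ["u", "u", "u", "v", "v", "v"]}, index=D.ids)
        with pytest.raises(ValueError, match="dup"):
            permanova(D, design, ["grp", "dup"], n_perm=99, seed=0)

    def test_seeded_reproducibility(self, rng):
        D = _toy_distance(rng, 8)
        design = pd.DataFrame({"grp": ["a", "b"] * 4}, index=D.ids)
        r1 = permanova(D, design, ["grp"], n_perm=199, seed=7)
        r2 = permanova(D, design, ["grp"], n_perm=199, seed=7)
        assert r1.table.equals(r2.table)


class TestNmds:
    def test_three_equidistant_points_embed_exactly(self):
        v = np.full((3, 3), 0.5)
        np.fill_diagonal(v, 0)
        D = DissimilarityMatrix(v, ["a", "b", "c"], "bray_curtis")
        res = nmds(D, k=2, n_restarts=4, seed=0)
        assert res.stress < 1e-3

    def test_planar_configuration_recovered(self, rng):
        D = _toy_distance(rng, 10)
        res = nmds(D, k=2, n_restarts=8, seed=0)
        assert res.stress < 0.01

    def test_deterministic_given_seed(self, rng):
        D = _toy_distance(rng, 8)
        a = nmds(D, seed=5, n_restarts=4)
        b = nmds(D, seed=5, n_restarts=4)
        assert a.stress == b.stress
        assert a.coordinates.equals(b.coordinates)


class TestRarefaction:
    def test_full_depth_gives_observed_richness(self):
        counts = [5, 3, 2, 0, 10]
        out = rarefaction_curve(counts, [20])
        assert out["expected_richness"].iloc[0] == pytest.approx(4.0)

    def test_depth_one_gives_one(self):
        out = rarefaction_curve([5, 3, 2], [1])
        assert out["expected_richness"].iloc[0] == pytest.approx(1.0)

    def test_monotone_and_bounded(self, rng):
        counts = rng.integers(0, 200, size=30)
        total = int(counts.sum())
        depths = np.unique(np.linspace(1, total, 15).astype(int))
        out = rarefaction_curve(counts, depths)
        r = out["expected_richness"].to_numpy()
        assert (np.diff(r) >= -1e-9).all()
        assert r.max() <= (counts > 0).sum() + 1e-9

    def test_resample_agrees_with_analytic(self, rng):
        counts = rng.integers(0, 80, size=12)
        total = int(counts.sum())
        depth = total // 2
        analytic = rarefaction_curve(counts, [depth])["expected_richness"].iloc[0]
        n_iter = 200
        res = rarefaction_curve(counts, [depth], mode="resample",
                                seed=1, n_iter=n_iter)
        # binomial-ish bound on the Monte-Carlo error
        se = (counts > 0).sum() / (2 * np.sqrt(n_iter))
        assert abs(res["expected_richness"].iloc[0] - analytic) < 2 * se + 0.2

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([5, 5], [11])


class TestRankTests:
    def test_identical_groups_p_one(self):
        values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        factor = pd.Series(["a", "a", "a", "b", "b", "b"])
        assert mann_whitney_test(values, factor).p_value == pytest.approx(1.0)

    def test_fully_separated_three_vs_three_exact(self):
        values = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        factor = pd.Series(["a", "a", "a", "b", "b", "b"])
        res = mann_whitney_test(values, factor)
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_spearman_of_monotone_pairing(self):
        res = spearman_association([1, 2, 3, 4], [10, 20, 30, 400])
        assert res.statistic == pytest.approx(1.0)

    def test_dispatch_by_level_count(self):
        values = pd.Series([1.0, 2, 3, 4, 5, 6])
        assert group_test(values, pd.Series(["a", "a", "b", "b", "c", "c"])).test \
            == "kruskal_wallis"
        assert group_test(values, pd.Series(["a", "a", "a", "b", "b", "b"])).test \
            == "mann_whitney"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_test(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))
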