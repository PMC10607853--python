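import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from assemblyscope import diversity
from assemblyscope.diversity import (
    DistanceMatrix,
    aggregate_taxonomy,
    alpha_diversity,
    bray_curtis,
    chao1,
    distance_decay,
    gini_simpson,
    gradient_regression,
    kruskal_wallis_by_group,
    pcoa,
    permanova,
    shannon,
    weighted_unifrac,
    within_group_similarity,
)
from conftest import make_table, random_table
from oracles import bray_curtis_brute, weighted_unifrac_brute


class TestAlphaDiversity:
    def test_uniform_four(self):
        assert shannon([25, 25, 25, 25]) == pytest.approx(np.log(4))
        assert gini_simpson([25, 25, 25, 25]) == pytest.approx(0.75)
        assert chao1([25, 25, 25, 25]) == pytest.approx(4.0)

    def test_chao1_bias_corrected(self):
        # S=4, F1=2, F2=0 -> 4 + 2*1/(2*1) = 5
        assert chao1([5, 3, 1, 1]) == pytest.approx(5.0)

    def test_single_taxon(self):
        assert shannon([7]) == 0.0
        assert gini_simpson([7]) == 0.0
        assert chao1([7]) == pytest.approx(1.0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_invariants_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            counts = rng.integers(0, 40, size=30)
            counts[rng.integers(30)] += 1  # non-empty
            frame = alpha_diversity(make_table(counts[None, :]))
            row = frame.iloc[0]
            assert row.chao1 >= row.observed_richness
            assert row.gini_simpson < 1
            assert row.shannon <= np.log(row.observed_richness) + 1e-12


class TestBrayCurtis:
    def test_identical_samples(self):
        dm = bray_curtis(make_table([[3, 4], [3, 4]]))
        assert dm.data[0, 1] == 0.0

    def test_disjoint_samples(self):
        dm = bray_curtis(make_table([[5, 0], [0, 5]]))
        assert dm.data[0, 1] == 1.0

    def test_hand_computed(self):
        dm = bray_curtis(make_table([[6, 2], [2, 2]]))
        assert dm.data[0, 1] == pytest.approx(1 / 3)

    def test_two_empty_samples_error(self):
        t = make_table([[0, 0], [0, 0], [1, 1]])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(t)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            t = random_table(rng, n_samples=8, n_taxa=15)
            dm = bray_curtis(t)
            assert np.abs(dm.data - bray_curtis_brute(t.counts)).max() < 1e-10


class TestWeightedUnifrac:
    def test_identical_samples(self, four_tip_tree):
        t = make_table([[1, 2, 3, 0], [1, 2, 3, 0]], taxon_ids=list("ABCD"))
        dm = weighted_unifrac(t, four_tip_tree)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_unnormalized(self, four_tip_tree):
        # A-only vs C-only: branches A, A-stem, C, C-stem each length 1
        t = make_table([[5, 0, 0, 0], [0, 0, 5, 0]], taxon_ids=list("ABCD"))
        dm = weighted_unifrac(t, four_tip_tree, normalized=False)
        assert dm.data[0, 1] == pytest.approx(4.0)

    def test_normalized_bounded(self, four_tip_tree):
        t = make_table([[5, 0, 0, 0], [0, 0, 5, 0]], taxon_ids=list("ABCD"))
        dm = weighted_unifrac(t, four_tip_tree, normalized=True)
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_column_permutation_invariant(self, four_tip_tree):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 9, size=(4, 4))
        t = make_table(counts, taxon_ids=list("ABCD"))
        perm = [2, 0, 3, 1]
        t2 = make_table(counts[:, perm], taxon_ids=[list("ABCD")[i] for i in perm])
        a = weighted_unifrac(t, four_tip_tree).data
        b = weighted_unifrac(t2, four_tip_tree).data
        assert np.allclose(a, b, atol=1e-12)

    def test_missing_taxon_errors(self, four_tip_tree):
        t = make_table([[1, 1]], taxon_ids=["A", "Z"])
        with pytest.raises(ValueError, match="missing"):
            weighted_unifrac(t, four_tip_tree)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_brute_force(self, normalized):
        from assemblyscope.synthetic import simulate_tree

        rng = np.random.default_rng(3)
        for rep in range(10):
            tree = simulate_tree(8, seed=100 + rep)
            ids = sorted(tree.tip_names)
            t = random_table(rng, n_samples=6, n_taxa=8, taxon_ids=ids)
            buf = io.StringIO()
            tree.tree.write(buf)
            got = weighted_unifrac(t, tree, normalized=normalized).data
            want = weighted_unifrac_brute(buf.getvalue(), t.counts, ids, normalized)
            assert np.abs(got - want).max() < 1e-10


class TestPcoa:
    def test_line_recovered(self):
        pts = np.array([0.0, 1.0, 2.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        dm = DistanceMatrix(d, ["a", "b", "c", "d"], "euclidean")
        res = pcoa(dm)
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)
        # coordinates collinear with input order
        assert np.all(np.diff(axis1) > 0) or np.all(np.diff(axis1) < 0)

    def test_distance_reconstruction(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(7)], "euclidean")
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.abs(d2 - d).max() < 1e-8

    def test_all_zero_distances(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"), "bray_curtis")
        res = pcoa(dm)
        assert res.coordinates.to_numpy().size == 0 or np.allclose(
            res.coordinates.to_numpy(), 0.0
        )

    def test_too_few_samples(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ["a", "b"], "x")
        with pytest.raises(ValueError):
            pcoa(dm)

    def test_eigenvalues_sorted(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, 9, 20)
        res = pcoa(bray_curtis(t))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() <= 1 + 1e-12


class TestPermanova:
    def _separated(self):
        # two groups of 6 on disjoint taxa; 6+6 keeps permutation ties
        # (relabelings reproducing the split) negligible
        rng = np.random.default_rng(10)
        counts = np.zeros((12, 4), dtype=int)
        counts[:6, :2] = rng.integers(5, 10, (6, 2))
        counts[6:, 2:] = rng.integers(5, 10, (6, 2))
        return bray_curtis(make_table(counts)), ["g1"] * 6 + ["g2"] * 6

    def test_perfect_separation(self):
        dm, groups = self._separated()
        res = permanova(dm, groups, n_permutations=99, seed=0)
        assert res["p_value"] == pytest.approx(1 / 100)
        assert res["R2"] > 0.9

    def test_statistic_independent_of_permutation_count(self):
        dm, groups = self._separated()
        a = permanova(dm, groups, n_permutations=99, seed=0)
        b = permanova(dm, groups, n_permutations=198, seed=1)
        assert a["pseudo_F"] == pytest.approx(b["pseudo_F"])
        assert a["R2"] == pytest.approx(b["R2"])

    def test_relabeling_within_groups_invariant(self):
        rng = np.random.default_rng(6)
        t = random_table(rng, 10, 12)
        dm = bray_curtis(t)
        groups = ["a"] * 5 + ["b"] * 5
        r1 = permanova(dm, groups, n_permutations=99, seed=3)["R2"]
        # swap sample order inside each group
        order = [2, 0, 1, 4, 3, 7, 5, 6, 9, 8]
        dm2 = DistanceMatrix(dm.data[np.ix_(order, order)],
                             [dm.sample_ids[i] for i in order], dm.metric)
        r2 = permanova(dm2, groups, n_permutations=99, seed=3)["R2"]
        assert r1 == pytest.approx(r2)

    def test_single_sample_group_errors(self):
        dm, _ = self._separated()
        with pytest.raises(ValueError, match="single"):
            permanova(dm, ["a"] * 11 + ["b"], n_permutations=99, seed=0)


class TestWithinGroupSimilarity:
    def test_identical_group(self):
        dm = bray_curtis(make_table([[3, 3], [3, 3], [1, 5]]))
        sims = within_group_similarity(dm, ["g", "g", "h2"] if False else
                                       {"S1": "g", "S2": "g", "S3": "g"})
        assert sims["g"][0] == pytest.approx(1.0)

    def test_matches_matrix_entries(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, 6, 10)
        dm = bray_curtis(t)
        sims = within_group_similarity(dm, ["a"] * 3 + ["b"] * 3)
        assert sims["a"] == pytest.approx(
            [1 - dm.data[0, 1], 1 - dm.data[0, 2], 1 - dm.data[1, 2]]
        )


class TestDistanceDecay:
    def test_exact_linear_fixture(self):
        altitudes = np.array([3118.0, 3363.0, 3550.0, 3945.0, 4343.0])
        d = np.abs(altitudes[:, None] - altitudes[None, :]) / 5000.0
        dm = DistanceMatrix(d, [f"s{i}" for i in range(5)], "bray_curtis")
        res = distance_decay(dm, altitudes)
        assert res.slope == pytest.approx(-1 / 5000)
        assert res.r_squared == pytest.approx(1.0)

    def test_null_slope_centered_on_zero(self):
        slopes = []
        altitudes = np.tile([3100.0, 3500.0, 3900.0, 4300.0], 3)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = random_table(rng, 12, 25)
            dm = bray_curtis(t)
            slopes.append(distance_decay(dm, altitudes).slope)
        tstat = np.mean(slopes) / (np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
        assert abs(tstat) < 4

    def test_equal_altitudes_error(self):
        dm = bray_curtis(make_table([[1, 2], [2, 1]]))
        with pytest.raises(ValueError):
            distance_decay(dm, [3000.0, 3000.0])


class TestGradientRegression:
    def test_exact_line(self):
        altitudes = np.array([3000.0, 3500.0, 4000.0, 4500.0])
        res = gradient_regression(2 * altitudes + 5, altitudes)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_slope_ci_coverage(self):
        covered = 0
        x = np.linspace(3000, 4800, 30)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=30)
            res = stats.linregress(x, y)
            lo = res.slope - 1.96 * res.stderr
            hi = res.slope + 1.96 * res.stderr
            if lo <= 0 <= hi:
                covered += 1
        assert covered >= 90

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            gradient_regression([1.0, 2.0, 3.0], [3000.0, 3000.0, 3000.0])


class TestAggregateTaxonomy:
    def _taxonomy(self):
        return pd.DataFrame(
            {"phylum": ["Asco", "Asco", "Basidio", "Mucor"]},
            index=["T1", "T2", "T3", "T4"],
        )

    def test_single_group(self):
        t = make_table([[3, 7], [5, 5]], taxon_ids=["T1", "T2"])
        out = aggregate_taxonomy(t, self._taxonomy(), "phylum", top_k=3)
        assert np.allclose(out["Asco"], 1.0)
        assert np.allclose(out["others"], 0.0)

    def test_relative_abundances(self):
        t = make_table([[30, 70]], taxon_ids=["T1", "T3"])
        out = aggregate_taxonomy(t, self._taxonomy(), "phylum", top_k=2)
        assert out.loc["S1", "Asco"] == pytest.approx(0.3)
        assert out.loc["S1", "Basidio"] == pytest.approx(0.7)

    def test_unknown_taxon_is_unclassified(self):
        t = make_table([[5, 5]], taxon_ids=["T1", "Tx"])
        out = aggregate_taxonomy(t, self._taxonomy(), "phylum", top_k=5)
        assert out.loc["S1", "unclassified"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        t = random_table(rng, 5, 4, taxon_ids=["T1", "T2", "T3", "T4"])
        out = aggregate_taxonomy(t, self._taxonomy(), "phylum", top_k=1)
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_unknown_rank_errors(self):
        t = make_table([[1]], taxon_ids=["T1"])
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxonomy(t, self._taxonomy(), "species", top_k=1)


class TestKruskalWallis:
    def test_identical_values(self):
        h, p = kruskal_wallis_by_group([2.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert h == 0.0
        assert p == 1.0

    def test_hand_ranked_example(self):
        h, p = kruskal_wallis_by_group(
            [1, 2, 3, 10, 11, 12], ["a", "a", "a", "b", "b", "b"]
        )
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        h, p = kruskal_wallis_by_group(x, groups)
        want = stats.kruskal(x[:4], x[4:8], x[8:])
        assert h == pytest.approx(want.statistic)
        assert p == pytest.approx(want.pvalue)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis_by_group([1.0, 2.0], ["a", "a"])
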