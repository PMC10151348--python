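"""Acoustic distance matrices, FMI dendrogram comparison, and the
Mantel-family tests (standard, EM under Brownian motion, phylogenetically
permuted)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import cophenet
from sklearn.metrics import fowlkes_mallows_score

from songphylo.phylo_signal import (
    MantelResult,
    bin_feature,
    build_distance_matrices,
    cluster_dendrogram,
    compare_effect_sizes,
    cut_clusters,
    em_mantel,
    fmi_test,
    histogram_distance,
    inertia_percent,
    mantel_standard,
    phylo_inertia,
    pp_mantel,
    two_step_signal,
)
from songphylo.trees import Phylogeny, simulate_bm_traits


def random_distance(k, seed):
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((k, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return d


def abs_diff_matrix(values, names):
    v = np.asarray(values, dtype=float)
    return pd.DataFrame(np.abs(v[:, None] - v[None, :]), index=names, columns=names)


class TestBinning:
    def test_grid_arithmetic_401_bins(self):
        # pooled data with mean 0, sd 1, range [-2, 2] -> (4.00 / 0.01) + 1 bins
        pooled = np.array([-2.0, 2.0, 0, 0, 0, 0, 0, 0])
        hists = bin_feature({"A": pooled[:4], "B": pooled[4:]})
        assert hists.shape[1] == 401

    def test_identical_samples_identical_histograms(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(200)
        hists = bin_feature({"A": v, "B": v.copy()})
        assert np.allclose(hists.loc["A"], hists.loc["B"])

    def test_histograms_sum_to_one(self):
        rng = np.random.default_rng(1)
        hists = bin_feature({"A": rng.standard_normal(100), "B": rng.standard_normal(300) + 1})
        assert np.allclose(hists.sum(axis=1), 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bin_feature({"A": np.ones(10), "B": np.ones(5)})


class TestHistogramDistance:
    def test_identities(self):
        a = np.array([0.5, 0.5])
        assert histogram_distance(a, a) == 0.0
        assert histogram_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)
        b = np.array([0.2, 0.8])
        assert histogram_distance(a, b) == histogram_distance(b, a)


class TestDistanceMatrices:
    def test_counts_and_normalization(self, small_table):
        cols = ["mean_freq", "duration", "spectral_entropy"]
        mats = build_distance_matrices(small_table, cols)
        assert set(mats) == set(cols)
        for m in mats.values():
            assert m.shape == (7, 7)
            assert m.to_numpy().max() == pytest.approx(1.0)
            assert np.allclose(m.to_numpy(), m.to_numpy().T)
            assert np.allclose(np.diag(m.to_numpy()), 0.0)

    def test_duplicated_species_zero_distance(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(60)
        t = pd.DataFrame({
            "species": np.repeat(["A", "B", "C"], 60),
            "x": np.concatenate([v, v, rng.standard_normal(60) + 3]),
        })
        mats = build_distance_matrices(t, ["x"])
        assert mats["x"].loc["A", "B"] == pytest.approx(0.0)


class TestDendrograms:
    def test_tight_pair_merges_first(self):
        d = pd.DataFrame(
            [[0, 0.1, 5], [0.1, 0, 5], [5, 5, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        link = cluster_dendrogram(d)
        assert sorted(link[0, :2]) == [0, 1]  # A and B first
        assert len(set(cut_clusters(link, 2))) == 2
        assert len(set(cut_clusters(link, 3))) == 3

    def test_complete_linkage_cophenetic_monotone(self):
        d = random_distance(6, seed=3)
        link = cluster_dendrogram(pd.DataFrame(d))
        assert (np.diff(link[:, 2]) >= -1e-12).all()
        coph = cophenet(link)
        assert coph.min() >= squeeze_min(d)


def squeeze_min(d):
    off = d[np.triu_indices(d.shape[0], 1)]
    return off.min() - 1e-12


class TestFMI:
    def test_identical_partitions(self):
        labels = np.array([1, 1, 2, 2, 3, 3, 3])
        res = fmi_test(labels, labels.copy(), k=3)
        assert res.fmi == pytest.approx(1.0)
        assert res.p < 0.05

    def test_orthogonal_two_by_two(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        res = fmi_test(a, b, k=2)
        assert res.fmi == pytest.approx(0.0)

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(1, 4, size=12)
            b = rng.integers(1, 4, size=12)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            res = fmi_test(a, b, k=3)
            assert res.fmi == pytest.approx(fowlkes_mallows_score(a, b), abs=1e-12)

    def test_bounds_on_random_partitions(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.integers(1, 4, size=10)
            b = rng.integers(1, 4, size=10)
            res = fmi_test(a, b, k=3)
            assert 0.0 <= res.fmi <= 1.0
            assert 0.0 < res.p <= 1.0

    def test_k_exceeding_leaves_rejected(self):
        with pytest.raises(ValueError):
            fmi_test(np.array([1, 2]), np.array([1, 2]), k=3)


class TestMantelStandard:
    def test_self_correlation(self):
        d = pd.DataFrame(random_distance(5, seed=6))
        res = mantel_standard(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_is_brute_force(self):
        a = random_distance(4, seed=7)
        b = random_distance(4, seed=8)
        res = mantel_standard(a, b, exact=True)
        # independent brute-force oracle over all 4! relabelings
        iu = np.triu_indices(4, 1)
        r_obs = stats.pearsonr(a[iu], b[iu]).statistic
        count = 0
        total = 0
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            r = stats.pearsonr(a[iu], b[np.ix_(p, p)][iu]).statistic
            total += 1
            if abs(r) >= abs(r_obs) - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total)
        assert res.n_replicates == 24

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel

        a = random_distance(7, seed=9)
        b = random_distance(7, seed=10)
        ours = mantel_standard(a, b, n_perm=999, seed=1)
        r_sk, p_sk, _ = mantel(
            DistanceMatrix(a), DistanceMatrix(b),
            method="pearson", permutations=999, alternative="two-sided",
        )
        assert ours.r == pytest.approx(float(r_sk), abs=1e-10)
        assert ours.p == pytest.approx(float(p_sk), abs=0.06)

    def test_invalid_tail(self):
        d = random_distance(4, seed=11)
        with pytest.raises(ValueError):
            mantel_standard(d, d, tail="less")


class TestEmMantel:
    def test_patristic_self_signal(self, tree7):
        res = em_mantel(tree7.patristic_matrix(), tree7, n_sim=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_label_mismatch_listed(self, tree7):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("XYZ"), columns=list("XYZ"))
        with pytest.raises(ValueError, match="mismatch"):
            em_mantel(d, tree7, n_sim=10)

    def test_scale_invariance_of_r(self, tree7):
        trait = simulate_bm_traits(tree7, 1.0, seed=12)
        d = abs_diff_matrix(trait.to_numpy(), list(trait.index))
        a = em_mantel(d, tree7, n_sim=50, seed=3)
        b = em_mantel(10.0 * d, tree7, n_sim=50, seed=3)
        assert a.r == pytest.approx(b.r)
        assert a.p == pytest.approx(b.p)


class TestPpMantel:
    def test_self_correlation(self, tree7):
        d = tree7.patristic_matrix()
        res = pp_mantel(d, d, tree7, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_large_k_matches_standard(self, tree7):
        trait = simulate_bm_traits(tree7, 1.0, seed=13)
        d_a = abs_diff_matrix(trait.to_numpy(), list(trait.index))
        d_b = tree7.patristic_matrix()
        pp = pp_mantel(d_a, d_b, tree7, k_influence=1e6, n_perm=2000, seed=4)
        std = mantel_standard(
            d_a.loc[tree7.tip_names, tree7.tip_names],
            d_b, n_perm=2000, seed=5, tail="greater",
        )
        assert pp.p == pytest.approx(std.p, abs=0.07)

    def test_star_tree_invariant_to_k(self):
        star = Phylogeny.from_newick("(a:1,b:1,c:1,d:1,e:1);")
        rng = np.random.default_rng(14)
        v = rng.standard_normal(5)
        w = rng.standard_normal(5)
        names = star.tip_names
        d_a = abs_diff_matrix(v, names)
        d_b = abs_diff_matrix(w, names)
        r1 = pp_mantel(d_a, d_b, star, k_influence=1.0, n_perm=500, seed=6)
        r2 = pp_mantel(d_a, d_b, star, k_influence=50.0, n_perm=500, seed=6)
        assert r1.p == pytest.approx(r2.p)

    def test_invalid_k(self, tree7):
        d = tree7.patristic_matrix()
        with pytest.raises(ValueError):
            pp_mantel(d, d, tree7, k_influence=0.0)


class TestTwoStep:
    def test_screened_out_feature_skips_em(self, tree7):
        rng = np.random.default_rng(15)
        names = tree7.tip_names
        noise = abs_diff_matrix(rng.standard_normal(7), names)
        planted = tree7.patristic_matrix()
        res = two_step_signal({"noise": noise, "planted": planted}, tree7,
                              n_perm=200, n_sim=200, seed=0)
        assert res.loc["planted", "significant"]
        assert res.loc["planted", "inertia"] == pytest.approx(res.loc["planted", "em_r"] ** 2)
        if res.loc["noise", "screened_out"]:
            assert np.isnan(res.loc["noise", "em_p"])

    def test_result_schema(self, tree7):
        res = two_step_signal({"pc1": tree7.patristic_matrix()}, tree7,
                              n_perm=100, n_sim=100, seed=1)
        assert {"mantel_r", "mantel_p", "mantel_q", "screened_out",
                "em_r", "em_p", "em_q", "inertia", "significant"} <= set(res.columns)


class TestInertiaAndEffects:
    def test_paper_rounding(self):
        assert inertia_percent(0.23) == 5
        assert inertia_percent(1.0) == 100
        assert inertia_percent(0.0) == 0
        assert phylo_inertia(0.75) == pytest.approx(0.5625)

    def _mr(self, r):
        return MantelResult(r=r, p=0.01, method="em_bm", n_replicates=100, tail="greater")

    def test_effect_flags(self):
        em = self._mr(0.75)
        assert compare_effect_sizes(em, [self._mr(0.21), self._mr(0.25)])["flag"] == "inertia-dominant"
        assert compare_effect_sizes(self._mr(0.2), [self._mr(0.5)])["flag"] == "trait-link-dominant"
        assert compare_effect_sizes(self._mr(0.3), [self._mr(0.3)])["flag"] == "tie"
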