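"""Prior-weighted bagging, permutation importance, elbow selection,
confusion statistics, model comparison, and resampling."""

import numpy as np
import pandas as pd
import pytest

from songphylo.classification import (
    ImportanceResult,
    class_priors_from_motifs,
    compare_models,
    confusion_stats,
    evaluate,
    permutation_importance,
    scut_resample,
    scut_target,
    select_features,
    train_forest,
    undersample,
)


def make_table(class_sizes, n_features=4, shift=0.0, seed=0, features=None):
    """Gaussian blobs per class; shift controls class separation."""
    rng = np.random.default_rng(seed)
    features = features or [f"f{i}" for i in range(n_features)]
    blocks = []
    for c, (name, n) in enumerate(class_sizes.items()):
        x = rng.standard_normal((n, len(features))) + shift * c
        df = pd.DataFrame(x, columns=features)
        df.insert(0, "species", name)
        df.insert(1, "bird", "b01")
        df.insert(2, "motif", [f"m{i // 5:04d}" for i in range(n)])
        df.insert(3, "syllable", np.arange(n))
        blocks.append(df)
    return pd.concat(blocks, ignore_index=True), features


class TestPriors:
    def test_uniform_when_equal(self):
        t, _ = make_table({c: 50 for c in "ABCDEFG"})
        priors = class_priors_from_motifs(t)
        assert np.allclose(priors, 1 / 7)

    def test_hand_normalization(self):
        rows = []
        for i in range(4):   # species A: 10 syllables per motif
            rows += [{"species": "A", "bird": "b", "motif": f"m{i}", "syllable": j} for j in range(10)]
        for i in range(4):   # species B: 5 per motif
            rows += [{"species": "B", "bird": "b", "motif": f"m{i}", "syllable": j} for j in range(5)]
        priors = class_priors_from_motifs(pd.DataFrame(rows))
        assert priors["A"] == pytest.approx(2 / 3)
        assert priors["B"] == pytest.approx(1 / 3)
        assert priors.sum() == pytest.approx(1.0)


class TestForest:
    def test_separable_classes_high_oob_accuracy(self):
        t, feats = make_table({"A": 100, "B": 100}, shift=8.0, seed=1)
        model = train_forest(t, feats, n_trees=50, seed=0)
        assert 1.0 - model.oob_error > 0.99

    def test_shuffled_labels_chance_accuracy(self):
        t, feats = make_table({c: 80 for c in "ABCDEFG"}, shift=8.0, seed=2)
        rng = np.random.default_rng(3)
        t["species"] = rng.permutation(t["species"].to_numpy())
        model = train_forest(t, feats, n_trees=60, seed=0)
        acc = 1.0 - model.oob_error
        assert acc < 1 / 7 + 0.08  # at or near the max prior

    def test_deterministic(self):
        t, feats = make_table({"A": 60, "B": 60}, shift=2.0, seed=4)
        a = train_forest(t, feats, n_trees=30, seed=5)
        b = train_forest(t, feats, n_trees=30, seed=5)
        assert np.array_equal(a.oob_predictions, b.oob_predictions)

    def test_invalid_inputs(self):
        t, feats = make_table({"A": 30}, seed=5)
        with pytest.raises(ValueError):
            train_forest(t, feats, n_trees=5)
        t2, feats2 = make_table({"A": 30, "B": 30}, seed=6)
        t2.loc[0, feats2[0]] = np.nan
        with pytest.raises(ValueError, match="impute"):
            train_forest(t2, feats2, n_trees=5)


class TestImportance:
    def test_null_feature_near_zero_delta(self):
        t, feats = make_table({"A": 60, "B": 60}, shift=0.0, seed=7)
        imp = permutation_importance(t, feats, n_trees=20, iterations=10, seed=0)
        de = imp.delta_errors["f0"]
        se = de.std(ddof=1) / np.sqrt(len(de))
        assert abs(de.mean()) < 3 * max(se, 1e-6)

    def test_planted_feature_ranks_first(self):
        rng = np.random.default_rng(8)
        n = 120
        x = rng.standard_normal((n, 6))
        y = np.repeat(["A", "B"], n // 2)
        x[:, 2] = np.where(y == "A", -3.0, 3.0) + 0.3 * rng.standard_normal(n)
        t = pd.DataFrame(x, columns=[f"f{i}" for i in range(6)])
        t.insert(0, "species", y)
        t.insert(1, "bird", "b01")
        t.insert(2, "motif", "m0001")
        t.insert(3, "syllable", np.arange(n))
        imp = permutation_importance(t, [f"f{i}" for i in range(6)],
                                     n_trees=25, iterations=10, seed=1)
        firsts = (imp.delta_errors.idxmax(axis=1) == "f2").mean()
        assert firsts >= 0.9
        assert imp.rank_order[0] == "f2"

    def test_importance_sharing_between_duplicates(self):
        rng = np.random.default_rng(9)
        n = 160
        sig = np.where(np.repeat([0, 1], n // 2) == 0, -2.5, 2.5) + 0.4 * rng.standard_normal(n)
        base = {"species": np.repeat(["A", "B"], n // 2), "bird": "b01",
                "motif": "m0001", "syllable": np.arange(n)}
        solo = pd.DataFrame({**base, "sig": sig, "noise": rng.standard_normal(n)})
        dup = solo.copy()
        dup["sig_copy"] = sig + 1e-9 * rng.standard_normal(n)
        imp_solo = permutation_importance(solo, ["sig", "noise"], n_trees=40, iterations=6, seed=2)
        imp_dup = permutation_importance(dup, ["sig", "sig_copy", "noise"], n_trees=40, iterations=6, seed=2)
        assert imp_dup.mean_delta["sig"] < imp_solo.mean_delta["sig"]

    def test_zero_variance_feature_warns(self):
        t, feats = make_table({"A": 30, "B": 30}, shift=3.0, seed=10)
        t["f0"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            permutation_importance(t, feats, n_trees=10, iterations=2, seed=0)


class TestSelection:
    def _imp(self, scores, names=None):
        names = names or [f"f{i}" for i in range(len(scores))]
        mean = pd.Series(scores, index=names).sort_values(ascending=False)
        return ImportanceResult(
            delta_errors=pd.DataFrame([scores], columns=names),
            mean_delta=mean, rank_order=list(mean.index),
        )

    def test_largest_gap_elbow(self):
        imp = self._imp([10.0, 9.0, 8.0, 1.0, 0.9, 0.8])
        assert select_features(imp) == ["f0", "f1", "f2"]

    def test_all_equal_falls_back_to_all(self):
        imp = self._imp([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="no elbow"):
            assert set(select_features(imp)) == {"f0", "f1", "f2"}


class TestConfusion:
    def test_perfect_classifier(self):
        t, feats = make_table({"A": 80, "B": 80}, shift=10.0, seed=11)
        model = train_forest(t, feats, n_trees=50, seed=0)
        stats = evaluate(model)
        assert stats.weighted_f1 == pytest.approx(1.0)
        assert np.allclose(np.diag(stats.row_percent), 100.0)

    def test_hand_confusion_oracle(self):
        counts = pd.DataFrame([[8, 2], [1, 9]], index=["A", "B"], columns=["A", "B"])
        stats = confusion_stats(counts)
        prec_a, rec_a = 8 / 9, 8 / 10
        f1_a = 2 * prec_a * rec_a / (prec_a + rec_a)
        prec_b, rec_b = 9 / 11, 9 / 10
        f1_b = 2 * prec_b * rec_b / (prec_b + rec_b)
        assert stats.f1_per_species["A"] == pytest.approx(f1_a)
        assert stats.f1_per_species["B"] == pytest.approx(f1_b)
        assert stats.weighted_f1 == pytest.approx(0.5 * f1_a + 0.5 * f1_b)
        assert np.allclose(stats.row_percent.sum(axis=1), 100.0)
        assert stats.misclassification.loc["A", "B"] == pytest.approx(0.2)

    def test_weighted_equals_mean_when_balanced(self):
        counts = pd.DataFrame([[7, 3], [4, 6]], index=["A", "B"], columns=["A", "B"])
        stats = confusion_stats(counts)
        assert stats.weighted_f1 == pytest.approx(stats.f1_per_species.mean())


class TestCompare:
    def test_identical_lists(self):
        t, df, p = compare_models([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_df_for_seven_species(self):
        _, df, _ = compare_models(np.linspace(0.5, 0.9, 7), np.linspace(0.4, 0.95, 7))
        assert df == 12

    def test_textbook_closed_form(self):
        t, df, _ = compare_models([1, 2, 3], [4, 5, 6])
        # pooled variance 1, t = (2 - 5) / sqrt(1 * (1/3 + 1/3))
        assert t == pytest.approx(-3.0 / np.sqrt(2 / 3))
        assert df == 4


class TestResampling:
    def test_undersample_to_minimum(self):
        t, _ = make_table({"A": 100, "B": 50, "C": 50}, seed=12)
        out = undersample(t, seed=0)
        assert (out.groupby("species").size() == 50).all()
        keys = out[["species", "syllable"]].apply(tuple, axis=1)
        assert keys.is_unique

    def test_paper_shaped_counts_to_207(self):
        sizes = {"BF": 3993, "CB": 883, "DF": 4322, "GW": 1765, "LF": 2821, "RF": 207, "ZF": 1090}
        t, _ = make_table(sizes, n_features=1, seed=13)
        out = undersample(t, seed=1)
        assert (out.groupby("species").size() == 207).all()

    def test_scut_target_arithmetic(self):
        assert scut_target(15081, 7) == 2154
        assert scut_target(21, 7) == 3

    def test_scut_balances_counts(self):
        t, feats = make_table({"A": 60, "B": 20, "C": 10}, seed=14)
        out = scut_resample(t, seed=0, feature_names=feats)
        assert (out.groupby("species").size() == 30).all()

    def test_scut_balanced_table_unchanged(self):
        t, feats = make_table({"A": 30, "B": 30}, seed=15)
        out = scut_resample(t, seed=0, feature_names=feats)
        assert (out.groupby("species").size() == 30).all()
        assert len(out) == len(t)

    def test_smote_points_inside_class_hull_box(self):
        t, feats = make_table({"A": 90, "B": 6}, seed=16)
        out = scut_resample(t, seed=0, feature_names=feats)
        synth = out[(out["species"] == "B") & (out["bird"] == "smote")]
        orig = t[t["species"] == "B"][feats]
        assert len(synth) > 0
        for f in feats:
            assert (synth[f] >= orig[f].min() - 1e-12).all()
            assert (synth[f] <= orig[f].max() + 1e-12).all()

    def test_singleton_class_below_target_rejected(self):
        t, feats = make_table({"A": 50, "B": 1}, seed=17)
        with pytest.raises(ValueError, match="SMOTE"):
            scut_resample(t, seed=0, feature_names=feats)
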