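"""Bagged-forest species classification with motif-based class priors,
out-of-bag evaluation, permutation-importance feature selection, and
class-imbalance resampling (undersampling and SCUT/SMOTE).

The forest is plain Breiman bagging over CART trees, but each tree's bootstrap
draws rows with probabilities proportional to the class prior divided by the
class count, so training reflects the priors (here, the mean number of
syllables per motif per species) rather than the sampling effort. Evaluation
uses out-of-bag (OOB) votes: for each row, only trees whose bootstrap excluded
the row vote (the "remaining one-third" under bootstrap sampling).

Feature importance is Breiman's permutation importance: per tree, the increase
in OOB error when one feature's values are permuted ("delta error"), averaged
over trees, with the whole procedure repeated over iterations with fresh
seeds. The selected subset is everything left of the inflection point — the
largest consecutive gap — of the rank-ordered mean delta-error curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .acoustic_features import FEATURE_NAMES, ID_COLUMNS

__all__ = [
    "ForestModel",
    "ImportanceResult",
    "ConfusionStats",
    "class_priors_from_motifs",
    "train_forest",
    "permutation_importance",
    "select_features",
    "evaluate",
    "compare_models",
    "undersample",
    "scut_resample",
]


@dataclass
class ForestModel:
    """A fitted bagged forest with OOB vote bookkeeping."""

    trees: list
    classes: np.ndarray
    features: list[str]
    priors: pd.Series
    oob_votes: np.ndarray        # rows x classes
    y: np.ndarray                # encoded labels
    seed: int

    @property
    def oob_predictions(self) -> np.ndarray:
        """OOB-majority class per row; rows never OOB fall back to the prior."""
        votes = self.oob_votes.copy()
        never = votes.sum(axis=1) == 0
        if never.any():
            votes[never] = self.priors.loc[self.classes].to_numpy()
        return self.classes[np.argmax(votes, axis=1)]

    @property
    def oob_error(self) -> float:
        return float(np.mean(self.oob_predictions != self.classes[self.y]))


@dataclass
class ImportanceResult:
    """Per-feature delta-error distributions over importance iterations."""

    delta_errors: pd.DataFrame   # iterations x features
    mean_delta: pd.Series        # descending
    rank_order: list[str]
    selected: list[str] = field(default_factory=list)


@dataclass
class ConfusionStats:
    counts: pd.DataFrame            # species x species, rows = true
    row_percent: pd.DataFrame       # rows sum to 100
    misclassification: pd.DataFrame # R[X, Y] = proportion of X labeled Y (off-diag)
    f1_per_species: pd.Series
    weighted_f1: float


def class_priors_from_motifs(table: pd.DataFrame) -> pd.Series:
    """Prior(s) proportional to the mean number of syllables per motif of
    species s, normalized to sum to 1."""
    per_motif = table.groupby(["species", "bird", "motif"], sort=False).size()
    means = per_motif.groupby("species", sort=False).mean()
    return means / means.sum()


def _bootstrap_probs(y: np.ndarray, classes: np.ndarray, priors: pd.Series) -> np.ndarray:
    counts = np.bincount(y, minlength=len(classes)).astype(float)
    pri = priors.loc[classes].to_numpy(dtype=float)
    w = pri[y] / counts[y]
    return w / w.sum()


def train_forest(
    table: pd.DataFrame,
    features: list[str] | None = None,
    priors: pd.Series | None = None,
    n_trees: int = 1000,
    seed: int = 0,
    max_features: str | int | None = "sqrt",
) -> ForestModel:
    """Fit the prior-weighted bagged forest; deterministic given ``seed``.

    ``max_features='sqrt'`` is the classification default; importance runs use
    ``max_features=None`` (every feature available at every split).
    """
    features = list(features) if features is not None else FEATURE_NAMES
    x = table[features].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values in chosen features; impute first")
    labels = table["species"].to_numpy()
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if priors is None:
        priors = pd.Series(1.0 / len(classes), index=classes)
    rng = np.random.default_rng(int(seed))
    n = len(y)
    p = _bootstrap_probs(y, classes, priors)
    trees = []
    oob_votes = np.zeros((n, len(classes)))
    for _ in range(n_trees):
        idx = rng.choice(n, size=n, replace=True, p=p)
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(x[idx], y[idx])
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        if oob.any():
            pred = tree.predict(x[oob])
            oob_votes[np.flatnonzero(oob), pred] += 1.0
        trees.append((tree, oob))
    return ForestModel(
        trees=trees, classes=classes, features=features, priors=priors,
        oob_votes=oob_votes, y=y, seed=seed,
    )


def permutation_importance(
    table: pd.DataFrame,
    features: list[str] | None = None,
    n_trees: int = 1000,
    iterations: int = 100,
    seed: int = 0,
) -> ImportanceResult:
    """Delta error per feature: OOB error after permuting the feature minus
    baseline OOB error, averaged over trees; repeated ``iterations`` times
    with fresh forests (equal class sampling probabilities, all features
    available per split)."""
    features = list(features) if features is not None else FEATURE_NAMES
    x_all = table[features].to_numpy(dtype=float)
    labels = table["species"].to_numpy()
    classes, y = np.unique(labels, return_inverse=True)
    rng = np.random.default_rng(int(seed))
    zero_var = [f for j, f in enumerate(features) if np.std(x_all[:, j]) == 0]
    if zero_var:
        warnings.warn(f"zero-variance feature(s) {zero_var}: delta error will be ~0")
    rows = []
    equal_priors = pd.Series(1.0 / len(classes), index=classes)
    for _ in range(iterations):
        model = train_forest(
            table, features, priors=equal_priors, n_trees=n_trees,
            seed=int(rng.integers(2**31 - 1)), max_features=None,
        )
        deltas = np.zeros(len(features))
        n_used = np.zeros(len(features))
        for tree, oob in model.trees:
            m = int(oob.sum())
            if m == 0:
                continue
            x_oob = x_all[oob]
            y_oob = y[oob]
            base_err = np.mean(tree.predict(x_oob) != y_oob)
            perm = rng.permutation(m)
            for j in range(len(features)):
                x_perm = x_oob.copy()
                x_perm[:, j] = x_perm[perm, j]
                deltas[j] += np.mean(tree.predict(x_perm) != y_oob) - base_err
                n_used[j] += 1
        rows.append(deltas / np.maximum(n_used, 1))
    de = pd.DataFrame(rows, columns=features)
    mean_delta = de.mean(axis=0).sort_values(ascending=False)
    return ImportanceResult(
        delta_errors=de,
        mean_delta=mean_delta,
        rank_order=list(mean_delta.index),
    )


def select_features(importance: ImportanceResult) -> list[str]:
    """Features before the inflection point: the index maximizing the drop
    between consecutive rank-ordered mean delta errors (largest-gap elbow).
    All-equal scores fall back to all features with a warning."""
    means = importance.mean_delta.to_numpy()
    if means.size < 2 or np.allclose(means, means[0]):
        warnings.warn("no elbow in importance scores; selecting all features")
        selected = list(importance.rank_order)
    else:
        gaps = means[:-1] - means[1:]
        cut = int(np.argmax(gaps)) + 1
        selected = list(importance.rank_order[:cut])
    importance.selected = selected
    return selected


def evaluate(model: ForestModel, table: pd.DataFrame | None = None) -> ConfusionStats:
    """OOB confusion statistics: counts, row percentages, misclassification
    indices R (R[X, Y] = proportion of X's syllables labeled Y), per-species
    F1 and class-size-weighted F1."""
    true = model.classes[model.y]
    pred = model.oob_predictions
    classes = list(model.classes)
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, q in zip(true, pred):
        counts[idx[t], idx[q]] += 1
    return confusion_stats(pd.DataFrame(counts, index=classes, columns=classes))


def compare_models(f1_a, f1_b) -> tuple[float, int, float]:
    """Two-tailed independent-samples Student t test (pooled variance) on two
    per-species F1 lists: (t, df, p). Two 7-species lists give df = 12."""
    a = np.asarray(list(f1_a), dtype=float)
    b = np.asarray(list(f1_b), dtype=float)
    res = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return float(res.statistic), df, float(res.pvalue)


def confusion_stats(counts: pd.DataFrame) -> ConfusionStats:
    """Confusion statistics from a counts matrix (rows = true species)."""
    cm = counts.to_numpy(dtype=float)
    classes = list(counts.index)
    row_tot = cm.sum(axis=1, keepdims=True)
    row_pct = 100.0 * cm / np.maximum(row_tot, 1)
    miscls = cm / np.maximum(row_tot, 1)
    f1 = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        prec = tp / max(cm[:, i].sum(), 1e-300)
        rec = tp / max(cm[i, :].sum(), 1e-300)
        f1[c] = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    f1 = pd.Series(f1)
    weights = cm.sum(axis=1) / cm.sum()
    return ConfusionStats(
        counts=counts,
        row_percent=pd.DataFrame(row_pct, index=classes, columns=classes),
        misclassification=pd.DataFrame(miscls, index=classes, columns=classes),
        f1_per_species=f1,
        weighted_f1=float((f1.to_numpy() * weights).sum()),
    )


def scut_target(n_total: int, n_classes: int) -> int:
    """The SCUT balanced per-class sample size: floor(total / classes)."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    return n_total // n_classes


def undersample(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Downsample every class without replacement to the minimum class size."""
    rng = np.random.default_rng(int(seed))
    target = table.groupby("species", sort=False).size().min()
    parts = []
    for _, block in table.groupby("species", sort=False):
        take = rng.choice(len(block), size=target, replace=False)
        parts.append(block.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)


def _smote_points(x: np.ndarray, n_new: int, k_nn: int, rng) -> np.ndarray:
    """SMOTE: each synthetic point lies on the segment between a random
    original point and one of its k nearest same-class neighbors."""
    k = min(k_nn, len(x) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, nbrs = nn.kneighbors(x)
    picks = rng.integers(0, len(x), size=n_new)
    nbr_pick = nbrs[picks, rng.integers(1, k + 1, size=n_new)]
    u = rng.random((n_new, 1))
    return x[picks] + u * (x[nbr_pick] - x[picks])


def scut_resample(
    table: pd.DataFrame,
    seed: int = 0,
    k_nn: int = 5,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """SCUT resampling to a common per-class target of floor(total / k).

    Classes above target are undersampled by iteratively removing the member
    with the smallest mean distance to its same-class nearest neighbors;
    classes below target are oversampled by SMOTE. Synthetic rows carry the
    species label with bird/motif set to 'smote'.
    """
    features = list(feature_names) if feature_names is not None else FEATURE_NAMES
    classes = table["species"].unique()
    target = len(table) // len(classes)
    rng = np.random.default_rng(int(seed))
    parts = []
    for c in classes:
        block = table[table["species"] == c]
        n = len(block)
        if n == target:
            parts.append(block)
        elif n > target:
            x = block[features].to_numpy(dtype=float)
            keep = np.ones(n, dtype=bool)
            k = min(k_nn, n - 1)
            for _ in range(n - target):
                live = np.flatnonzero(keep)
                xs = x[live]
                kk = min(k, len(xs) - 1)
                nn = NearestNeighbors(n_neighbors=kk + 1).fit(xs)
                dist, _ = nn.kneighbors(xs)
                drop = live[int(np.argmin(dist[:, 1:].mean(axis=1)))]
                keep[drop] = False
            parts.append(block.iloc[np.flatnonzero(keep)])
        else:
            if n < 2:
                raise ValueError(f"class {c!r} has {n} member(s); SMOTE needs >= 2")
            x = block[features].to_numpy(dtype=float)
            synth = _smote_points(x, target - n, k_nn, rng)
            sdf = pd.DataFrame(synth, columns=features)
            sdf.insert(0, "species", c)
            sdf.insert(1, "bird", "smote")
            sdf.insert(2, "motif", "smote")
            sdf.insert(3, "syllable", np.arange(len(sdf)))
            parts.append(pd.concat([block, sdf.reindex(columns=block.columns)], ignore_index=True))
    return pd.concat(parts, ignore_index=True)
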