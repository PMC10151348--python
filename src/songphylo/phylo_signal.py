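"""Phylogenetic-signal analyses on species-level acoustic distances.

Species are compared through binned feature distributions: each feature is
z-scored over the pooled data, binned on a shared 0.01-increment grid, and the
pairwise **acoustic distance** is the sum of squared differences between the
species' relative-frequency histograms, max-normalized to [0, 1].

Three complementary analyses ask whether those distances track the phylogeny:

* **FMI** — cut the acoustic dendrogram and the phylogeny at k clusters and
  score partition agreement with the Fowlkes-Mallows index, with the
  closed-form permutation-null mean and variance giving a one-tailed p;
* **standard Mantel** — permutation test of the matrix correlation between
  acoustic and patristic distances (the screening step);
* **EM-Mantel** — the same correlation referred to a null distribution of
  Mantel r values obtained by simulating univariate Brownian-motion traits on
  the tree (one-tailed: is the observed alignment at least as strong as
  Brownian trait evolution would produce?). The squared EM-Mantel r is the
  feature's **phylogenetic inertia**.

**ppMantel** correlates two trait distance matrices (e.g. a song component
versus body mass) under phylogenetically weighted permutations, so close
relatives exchange labels more readily than distant ones; the influence
parameter k interpolates from strongest control (k = 1) to uniform
permutations (k -> infinity).

All permutation/simulation p-values use the add-one correction
p = (1 + #extreme) / (1 + replicates) and are therefore in (0, 1].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .trees import Phylogeny, bm_trait_replicates

__all__ = [
    "MantelResult",
    "FMIResult",
    "bin_feature",
    "histogram_distance",
    "build_distance_matrices",
    "cluster_dendrogram",
    "cut_clusters",
    "fmi_test",
    "mantel_standard",
    "em_mantel",
    "pp_mantel",
    "two_step_signal",
    "phylo_inertia",
    "compare_effect_sizes",
]


@dataclass
class MantelResult:
    r: float
    p: float
    method: str              # "standard" | "em_bm" | "phylo_perm"
    n_replicates: int
    tail: str                # "two-sided" | "greater"


@dataclass
class FMIResult:
    fmi: float
    k_clusters: int
    expectation: float
    variance: float
    z: float
    p: float                 # one-tailed upper


# ---------------------------------------------------------------- distances


def bin_feature(
    values_per_species: dict[str, np.ndarray], increment: float = 0.01
) -> pd.DataFrame:
    """Z-score the pooled values and histogram each species on a shared grid.

    The grid has round(range / increment) + 1 points spanning the pooled
    minimum to maximum; bins are centered on the grid points and histograms
    are normalized to relative frequencies (species sample sizes differ by
    ~20x, so raw counts would measure sampling effort, not acoustics).
    """
    names = list(values_per_species)
    pooled = np.concatenate([np.asarray(values_per_species[s], dtype=float) for s in names])
    mu, sd = pooled.mean(), pooled.std()
    if sd == 0:
        raise ValueError("zero-variance pooled feature; cannot bin")
    zs = {s: (np.asarray(values_per_species[s], dtype=float) - mu) / sd for s in names}
    lo = min(z.min() for z in zs.values())
    hi = max(z.max() for z in zs.values())
    n_bins = int(round((hi - lo) / increment)) + 1
    edges = lo - increment / 2 + increment * np.arange(n_bins + 1)
    hists = {}
    for s in names:
        h, _ = np.histogram(zs[s], bins=edges)
        hists[s] = h / h.sum()
    return pd.DataFrame(hists).T  # species x bins


def histogram_distance(hist_a: np.ndarray, hist_b: np.ndarray) -> float:
    """Sum of squared differences between two histograms."""
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    return float(np.sum((a - b) ** 2))


def build_distance_matrices(
    table: pd.DataFrame,
    columns: list[str],
    increment: float = 0.01,
    normalize: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-column species-by-species SSD distance matrices.

    ``table`` needs a 'species' column plus the value columns (raw features
    and/or PC scores). Each matrix is max-normalized to [0, 1].
    """
    species = list(table["species"].unique())
    out = {}
    for col in columns:
        groups = {s: table.loc[table["species"] == s, col].dropna().to_numpy() for s in species}
        hists = bin_feature(groups, increment)
        k = len(species)
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                d[i, j] = d[j, i] = histogram_distance(
                    hists.loc[species[i]].to_numpy(), hists.loc[species[j]].to_numpy()
                )
        if normalize and d.max() > 0:
            d = d / d.max()
        out[col] = pd.DataFrame(d, index=species, columns=species)
    return out


# ------------------------------------------------------------- dendrograms


def cluster_dendrogram(matrix: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """Agglomerative clustering of a distance matrix; returns the scipy
    linkage array (leaf order = matrix label order)."""
    return linkage(squareform(matrix.to_numpy(), checks=False), method=method)


def cut_clusters(dendro: np.ndarray, k: int) -> np.ndarray:
    """Cluster labels from cutting a linkage at k clusters."""
    return fcluster(dendro, t=k, criterion="maxclust")


def _as_labels(partition, k: int) -> np.ndarray:
    arr = np.asarray(partition)
    if arr.ndim == 2 and arr.shape[1] == 4:  # scipy linkage
        return cut_clusters(arr, k)
    return arr.astype(int)


def fmi_test(dendro_a, dendro_b, k: int = 3) -> FMIResult:
    """Fowlkes-Mallows comparison of two partitions (linkages cut at k, or
    label vectors).

    FMI = T_k / sqrt(P_k Q_k) from the cluster contingency table; the
    permutation-null expectation and variance use the Fowlkes-Mallows closed
    forms, and the one-tailed upper p comes from the normal approximation.
    """
    la = _as_labels(dendro_a, k)
    lb = _as_labels(dendro_b, k)
    n = la.size
    if lb.size != n:
        raise ValueError("partitions must cover the same leaves")
    if k > n:
        raise ValueError("k cannot exceed the number of leaves")
    cont = pd.crosstab(la, lb).to_numpy().astype(float)
    tk = (cont**2).sum() - n
    r = cont.sum(axis=1)
    c = cont.sum(axis=0)
    pk = (r**2).sum() - n
    qk = (c**2).sum() - n
    if pk <= 0 or qk <= 0:
        # one of the partitions is all-singletons at this cut
        return FMIResult(fmi=0.0, k_clusters=k, expectation=0.0, variance=0.0, z=0.0, p=1.0)
    fmi = tk / math.sqrt(pk * qk)
    e = math.sqrt(pk * qk) / (n * (n - 1))
    pk_p = (r * (r - 1) * (r - 2)).sum()
    qk_p = (c * (c - 1) * (c - 2)).sum()
    var = (
        2.0 / (n * (n - 1))
        + 4.0 * pk_p * qk_p / (n * (n - 1) * (n - 2) * pk * qk)
        + (pk - 2 - 4 * pk_p / pk) * (qk - 2 - 4 * qk_p / qk) / (n * (n - 1) * (n - 2) * (n - 3))
        - pk * qk / (n**2 * (n - 1) ** 2)
    )
    var = max(var, 0.0)
    if var > 0:
        z = (fmi - e) / math.sqrt(var)
        p = float(stats.norm.sf(z))
    else:
        z = math.inf if fmi > e else 0.0
        p = 0.0 if fmi > e else 1.0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return FMIResult(fmi=float(fmi), k_clusters=k, expectation=float(e), variance=float(var), z=float(z), p=p)


# ------------------------------------------------------------ Mantel family


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


def _align(d: pd.DataFrame, order: list[str]) -> np.ndarray:
    missing = [s for s in order if s not in d.index]
    extra = [s for s in d.index if s not in order]
    if missing or extra:
        raise ValueError(f"label mismatch: matrix lacks {missing}, tree lacks {extra}")
    return d.loc[order, order].to_numpy()


def _pearson_rows(rows: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with ``ref``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    fc = ref - ref.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (fc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (rc @ fc) / denom, 0.0)


def mantel_standard(
    d_a: pd.DataFrame | np.ndarray,
    d_b: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "two-sided",
    exact: bool = False,
) -> MantelResult:
    """Standard Mantel test: Pearson correlation of the off-diagonal upper
    triangles, null by simultaneous row/column permutation of one matrix.

    ``exact=True`` enumerates all k! relabelings (small k only); the p-value
    is then the exact fraction of permutations at least as extreme (the
    identity permutation makes it strictly positive).
    """
    a = d_a.to_numpy() if isinstance(d_a, pd.DataFrame) else np.asarray(d_a, dtype=float)
    b = d_b.to_numpy() if isinstance(d_b, pd.DataFrame) else np.asarray(d_b, dtype=float)
    k = a.shape[0]
    iu = np.triu_indices(k, 1)
    av = a[iu]
    r_obs = float(stats.pearsonr(av, b[iu]).statistic)
    if exact:
        perms = np.array(list(itertools.permutations(range(k))))
    else:
        rng = np.random.default_rng(int(seed))
        perms = np.array([rng.permutation(k) for _ in range(n_perm)])
    vals = b[perms[:, iu[0]], perms[:, iu[1]]]
    r_null = _pearson_rows(vals, av)
    eps = 1e-12
    if tail == "two-sided":
        extreme = np.abs(r_null) >= abs(r_obs) - eps
    elif tail == "greater":
        extreme = r_null >= r_obs - eps
    else:
        raise ValueError("tail must be 'two-sided' or 'greater'")
    if exact:
        p = float(extreme.mean())
        n_rep = len(perms)
    else:
        p = float((1 + extreme.sum()) / (1 + len(perms)))
        n_rep = len(perms)
    return MantelResult(r=r_obs, p=p, method="standard", n_replicates=n_rep, tail=tail)


def em_mantel(
    d_acoustic: pd.DataFrame,
    tree: Phylogeny,
    n_sim: int = 1000,
    seed: int = 0,
) -> MantelResult:
    """Evolutionary-model Mantel test under Brownian motion.

    Observed statistic: Mantel correlation between the acoustic distances and
    the patristic distances. Null distribution: the same correlation computed
    for ``n_sim`` univariate BM traits simulated on the tree (trait distance =
    absolute difference; Mantel r is scale-free so the BM rate is fixed at 1).
    One-tailed: p = (1 + #{null r >= observed r}) / (1 + n_sim).
    """
    order = tree.tip_names
    a = _align(d_acoustic, order)
    patristic = tree.patristic_matrix().to_numpy()
    k = len(order)
    iu = np.triu_indices(k, 1)
    pv = patristic[iu]
    r_obs = float(stats.pearsonr(a[iu], pv).statistic)
    rng = np.random.default_rng(int(seed))
    traits = bm_trait_replicates(tree, n_sim, 1.0, rng).to_numpy()
    null_d = np.abs(traits[:, iu[0]] - traits[:, iu[1]])
    r_null = _pearson_rows(null_d, pv)
    p = float((1 + np.sum(r_null >= r_obs - 1e-12)) / (1 + n_sim))
    return MantelResult(r=r_obs, p=p, method="em_bm", n_replicates=n_sim, tail="greater")


def _phylo_permutations(
    prox: np.ndarray, k_influence: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Phylogenetically weighted permutations via chains of weighted swaps.

    Each permutation composes k^2 transpositions; the pair (i, j) is chosen
    with probability proportional to prox[i, j]^(1/k_influence). As
    k_influence -> infinity the weights flatten and the chain mixes to the
    uniform distribution over permutations.
    """
    k = prox.shape[0]
    iu = np.triu_indices(k, 1)
    w = prox[iu] ** (1.0 / k_influence)
    if not np.isfinite(w).all() or w.sum() <= 0:
        raise ValueError("degenerate proximity weights")
    w = w / w.sum()
    n_swaps = k * k
    pairs_i, pairs_j = iu
    perms = np.tile(np.arange(k), (n_perm, 1))
    choices = rng.choice(len(w), size=(n_perm, n_swaps), p=w)
    for t in range(n_swaps):
        ii = pairs_i[choices[:, t]]
        jj = pairs_j[choices[:, t]]
        rows = np.arange(n_perm)
        tmp = perms[rows, ii].copy()
        perms[rows, ii] = perms[rows, jj]
        perms[rows, jj] = tmp
    return perms


def pp_mantel(
    d_a: pd.DataFrame,
    d_b: pd.DataFrame,
    tree: Phylogeny,
    k_influence: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> MantelResult:
    """Mantel test with phylogenetic permutations.

    Proximity between two tips is the inverse of their patristic distance, so
    at the strongest influence (k = 1) close relatives are far more likely to
    exchange labels while isolated species mostly keep their own; at
    k -> infinity all pairs swap equally and the test approaches the standard
    Mantel. One-tailed upper p with the add-one correction.
    """
    if k_influence <= 0:
        raise ValueError("k_influence must be positive")
    order = tree.tip_names
    a = _align(d_a, order)
    b = _align(d_b, order)
    patristic = tree.patristic_matrix().to_numpy()
    with np.errstate(divide="ignore"):
        prox = np.where(patristic > 0, 1.0 / np.maximum(patristic, 1e-12), 0.0)
    k = len(order)
    iu = np.triu_indices(k, 1)
    av = a[iu]
    r_obs = float(stats.pearsonr(av, b[iu]).statistic)
    rng = np.random.default_rng(int(seed))
    perms = _phylo_permutations(prox, k_influence, n_perm, rng)
    vals = b[perms[:, iu[0]], perms[:, iu[1]]]
    r_null = _pearson_rows(vals, av)
    p = float((1 + np.sum(r_null >= r_obs - 1e-12)) / (1 + n_perm))
    return MantelResult(r=r_obs, p=p, method="phylo_perm", n_replicates=n_perm, tail="greater")


def two_step_signal(
    matrices: dict[str, pd.DataFrame],
    tree: Phylogeny,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-step phylogenetic-signal testing with FDR control.

    Step 1 screens every feature with the standard Mantel test against the
    patristic distances (two-sided), Benjamini-Hochberg corrected across the
    family. Step 2 runs the one-tailed EM-Mantel only on the features that
    survive screening, again BH-corrected within that subset. A feature is
    flagged ``significant`` when it survives both steps; its phylogenetic
    inertia is the squared EM-Mantel r.
    """
    names = list(matrices)
    patristic = tree.patristic_matrix()
    rng = np.random.default_rng(int(seed))
    step1 = []
    for name in names:
        a = _align(matrices[name], tree.tip_names)
        res = mantel_standard(
            a, patristic.to_numpy(), n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        step1.append(res)
    p1 = np.array([r.p for r in step1])
    q1 = multipletests(p1, method="fdr_bh")[1]
    screened_in = q1 < alpha
    rows = []
    em_results: dict[str, MantelResult] = {}
    for i, name in enumerate(names):
        if screened_in[i]:
            em_results[name] = em_mantel(
                matrices[name], tree, n_sim=n_sim, seed=int(rng.integers(2**31 - 1))
            )
    em_names = list(em_results)
    if em_names:
        q2 = multipletests([em_results[n].p for n in em_names], method="fdr_bh")[1]
        q2 = dict(zip(em_names, q2))
    else:
        q2 = {}
    for i, name in enumerate(names):
        em = em_results.get(name)
        rows.append({
            "feature": name,
            "mantel_r": step1[i].r,
            "mantel_p": step1[i].p,
            "mantel_q": q1[i],
            "screened_out": not screened_in[i],
            "em_r": em.r if em else np.nan,
            "em_p": em.p if em else np.nan,
            "em_q": q2.get(name, np.nan),
            "inertia": em.r**2 if em else np.nan,
            "significant": bool(screened_in[i] and em and q2.get(name, 1.0) < alpha),
        })
    return pd.DataFrame(rows).set_index("feature")


def phylo_inertia(result: MantelResult | float) -> float:
    """Phylogenetic inertia: the squared Mantel correlation (proportion)."""
    r = result.r if isinstance(result, MantelResult) else float(result)
    return r**2


def inertia_percent(result: MantelResult | float) -> int:
    """Inertia as a percentage rounded to the nearest integer (display form)."""
    return int(round(100.0 * phylo_inertia(result)))


def compare_effect_sizes(em: MantelResult, pp: dict[str, MantelResult] | list) -> dict:
    """Compare the EM-Mantel effect size against ppMantel effect sizes.

    A larger |r| for the EM-Mantel than for every ppMantel flags the trait as
    inertia-dominant (phylogeny explains the feature better than the compared
    trait links); a smaller one flags a direct trait link; equality is a tie.
    """
    if isinstance(pp, dict):
        pp_items = list(pp.items())
    else:
        pp_items = [(f"pp{i}", r) for i, r in enumerate(pp)]
    em_abs = abs(em.r)
    comps = {name: abs(r.r) for name, r in pp_items}
    if all(em_abs > v for v in comps.values()):
        flag = "inertia-dominant"
    elif all(em_abs < v for v in comps.values()):
        flag = "trait-link-dominant"
    elif all(em_abs == v for v in comps.values()):
        flag = "tie"
    else:
        flag = "mixed"
    return {"em_abs_r": em_abs, "pp_abs_r": comps, "flag": flag}
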